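"""Trial declaration: prognostic factors, outcome, intervention and the
relationship set, plus automatic questionnaire generation.

A trial over k prognostic factors and one behavioural outcome spans k+1
surveyed concepts. When fully connected, every ordered non-self pair of
those concepts is an active relationship, giving k(k+1) relationships.
The intervention is a separate, non-surveyed concept whose edges to its
target factors are fixed design inputs (sign +1 or -1), not questionnaire
items.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

from .errors import ValidationError

#: Default ordered strength vocabulary, weakest first.
DEFAULT_TERMS: tuple[str, ...] = (
    "very weak", "weak", "moderate", "strong", "very strong",
)

#: Sentinel answer for "I don't know"; excluded from fuzzy aggregation.
UNSURE: str = "Unsure"

_CENTROID_GRID = 2001  # integration grid for membership centroids


@dataclass(frozen=True)
class TriangularMembership:
    """Triangular fuzzy membership function on the strength axis [0, 1]."""

    left: float
    peak: float
    right: float

    def __post_init__(self) -> None:
        if not (self.left <= self.peak <= self.right and self.left < self.right):
            raise ValidationError(
                f"degenerate triangle ({self.left}, {self.peak}, {self.right})"
            )

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        up = np.where(
            self.peak > self.left,
            (x - self.left) / max(self.peak - self.left, 1e-300),
            1.0,
        )
        down = np.where(
            self.right > self.peak,
            (self.right - x) / max(self.right - self.peak, 1e-300),
            1.0,
        )
        return np.clip(np.minimum(up, down), 0.0, 1.0)


@dataclass(frozen=True)
class LinguisticScale:
    """An ordered vocabulary of strength terms with fuzzy memberships.

    Parameters
    ----------
    terms
        Strength labels, ordered from weakest to strongest.
    membership
        Term -> membership function over the strength axis [0, 1]. Any
        non-negative callable with positive area is accepted; overlapping
        supports are allowed.
    unsure_token
        The sentinel answer excluded from aggregation.
    """

    terms: tuple[str, ...]
    membership: Mapping[str, Callable[[np.ndarray], np.ndarray]]
    unsure_token: str = UNSURE
    _centroids: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.terms) < 2:
            raise ValidationError("a linguistic scale needs at least two terms")
        if len(set(self.terms)) != len(self.terms):
            raise ValidationError("duplicate linguistic terms")
        if self.unsure_token in self.terms:
            raise ValidationError("unsure token must not be a strength term")
        missing = [t for t in self.terms if t not in self.membership]
        if missing:
            raise ValidationError(f"terms without membership function: {missing}")
        x = np.linspace(0.0, 1.0, _CENTROID_GRID)
        peaks = []
        for t in self.terms:
            mu = np.asarray(self.membership[t](x), dtype=float)
            if np.any(mu < 0):
                raise ValidationError(f"membership of {t!r} is negative somewhere")
            area = np.trapezoid(mu, x)
            if not area > 0:
                raise ValidationError(f"membership of {t!r} has zero area on [0, 1]")
            peaks.append(x[int(np.argmax(mu))])
            self._centroids[t] = float(np.trapezoid(x * mu, x) / area)
        if not all(a < b for a, b in zip(peaks, peaks[1:])):
            raise ValidationError("term peaks must strictly increase with term order")

    def centroid(self, term: str) -> float:
        """Centroid (centre of gravity) of a term's membership on [0, 1]."""
        try:
            return self._centroids[term]
        except KeyError:
            raise ValidationError(f"unknown term {term!r}") from None

    @property
    def max_centroid(self) -> float:
        return max(self._centroids.values())


def default_scale(n_terms: int = 5, unsure_token: str = UNSURE) -> LinguisticScale:
    """Evenly spaced symmetric triangular scale on [0, 1].

    Peaks sit at (2i+1)/(2 n_terms); half-widths are 1/n_terms but never
    reach past the axis boundaries, so each triangle stays symmetric and
    its centroid coincides with its peak. Adjacent supports overlap, which
    reflects that the reality described by one term partly includes that
    of its neighbours.
    """
    if n_terms == 5:
        terms = DEFAULT_TERMS
    else:
        terms = tuple(f"level {i + 1}" for i in range(n_terms))
    membership = {}
    for i, term in enumerate(terms):
        peak = (2 * i + 1) / (2 * n_terms)
        half = min(1.0 / n_terms, peak, 1.0 - peak)
        membership[term] = TriangularMembership(peak - half, peak, peak + half)
    return LinguisticScale(terms=terms, membership=membership,
                           unsure_token=unsure_token)


@dataclass(frozen=True)
class TrialDesign:
    """A declared trial: factors, outcome, intervention and relationships.

    ``active_relationships`` are ordered (source, target) pairs over the
    k+1 surveyed concepts (factors plus outcome), never self-pairs.
    """

    factor_names: tuple[str, ...]
    outcome_name: str
    intervention_targets: Mapping[str, int]
    active_relationships: frozenset[tuple[str, str]]

    @property
    def concepts(self) -> tuple[str, ...]:
        """Surveyed concepts: the k factors followed by the outcome."""
        return self.factor_names + (self.outcome_name,)

    @property
    def k(self) -> int:
        return len(self.factor_names)


def create_trial(
    factor_names: list[str] | tuple[str, ...],
    outcome_name: str,
    intervention_targets: Mapping[str, int],
) -> TrialDesign:
    """Declare a fully connected trial design.

    All k(k+1) ordered non-self relationships over the k factors and the
    outcome start active; use :func:`prune_relationship` to encode
    structural assumptions.
    """
    factors = tuple(factor_names)
    if any(not f or not str(f).strip() for f in factors) or not outcome_name:
        raise ValidationError("concept labels must be non-empty")
    labels = factors + (outcome_name,)
    if len(set(labels)) != len(labels):
        raise ValidationError("duplicate concept labels")
    if len(labels) < 2:
        raise ValidationError("need at least two concepts (one factor plus outcome)")
    if outcome_name in factors:
        raise ValidationError("outcome must be distinct from the factors")
    targets = dict(intervention_targets)
    unknown = [t for t in targets if t not in factors]
    if unknown:
        raise ValidationError(f"intervention targets not declared as factors: {unknown}")
    bad = {t: s for t, s in targets.items() if s not in (+1, -1)}
    if bad:
        raise ValidationError(f"intervention signs must be +1 or -1, got {bad}")
    rels = frozenset(
        (a, b) for a in labels for b in labels if a != b
    )
    return TrialDesign(
        factor_names=factors,
        outcome_name=outcome_name,
        intervention_targets=targets,
        active_relationships=rels,
    )


def prune_relationship(design: TrialDesign, source: str, target: str) -> TrialDesign:
    """Return a copy of ``design`` with one relationship deactivated."""
    pair = (source, target)
    if pair not in design.active_relationships:
        raise ValidationError(f"relationship {source!r} -> {target!r} is not active")
    return TrialDesign(
        factor_names=design.factor_names,
        outcome_name=design.outcome_name,
        intervention_targets=dict(design.intervention_targets),
        active_relationships=design.active_relationships - {pair},
    )


@dataclass(frozen=True)
class QuestionnaireItem:
    item_id: str
    kind: str              # "relationship" | "factor"
    source: str
    target: str            # empty for factor items
    choices: tuple[str, ...]


@dataclass(frozen=True)
class QuestionnaireSpec:
    items: tuple[QuestionnaireItem, ...]

    @property
    def relationship_items(self) -> tuple[QuestionnaireItem, ...]:
        return tuple(i for i in self.items if i.kind == "relationship")

    @property
    def factor_items(self) -> tuple[QuestionnaireItem, ...]:
        return tuple(i for i in self.items if i.kind == "factor")


def generate_questionnaire(design: TrialDesign, scale: LinguisticScale) -> QuestionnaireSpec:
    """Auto-generate the baseline questionnaire for a trial.

    One item per active relationship (every strength term in both
    directions, plus the unsure token) and one self-rating item per
    surveyed concept. Item order is deterministic: relationship items
    lexicographic by (source, target), then factor items in declared
    concept order.
    """
    if not design.concepts or len(design.concepts) < 2:
        raise ValidationError("empty or degenerate design")
    rel_choices = tuple(
        f"{term} {sgn}" for term in scale.terms for sgn in ("increase", "decrease")
    ) + (scale.unsure_token,)
    items: list[QuestionnaireItem] = []
    for n, (src, tgt) in enumerate(sorted(design.active_relationships), start=1):
        items.append(QuestionnaireItem(
            item_id=f"R{n:04d}", kind="relationship", source=src, target=tgt,
            choices=rel_choices,
        ))
    for n, concept in enumerate(design.concepts, start=1):
        items.append(QuestionnaireItem(
            item_id=f"F{n:04d}", kind="factor", source=concept, target="",
            choices=("value in [0, 1]",),
        ))
    return QuestionnaireSpec(items=tuple(items))
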