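"""Fuzzy aggregation of linguistic answers into signed edge weights.

Each participant rates each active relationship with a strength term and
a direction (increase/decrease), or answers Unsure. Per relationship, the
fraction of non-Unsure respondents endorsing a given (term, direction)
is that pair's confidence factor; the edge weight is the confidence-
weighted sum of direction-signed term centroids. Opposite directions
therefore partially cancel instead of being settled by majority vote,
preserving individual nuance.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .design import LinguisticScale, TrialDesign
from .engine import INTERVENTION, WeightMatrix
from .errors import ValidationError


@dataclass(frozen=True, slots=True)
class RelationshipAnswer:
    """One participant's rating of one directed relationship.

    ``term`` is a strength term of the scale, the scale's unsure token,
    or None for a missing answer. ``direction`` (+1 increase, -1
    decrease) accompanies a strength term and is ignored otherwise.
    """

    participant_id: str
    source: str
    target: str
    term: Optional[str]
    direction: Optional[int] = None


@dataclass(frozen=True)
class TermTally:
    """Endorsement counts for one relationship.

    ``counts`` maps (term, direction) to the number of endorsements;
    ``total_responses`` is the number of non-Unsure, non-missing answers
    and is the denominator of every confidence factor.
    """

    counts: dict[tuple[str, int], int]
    total_responses: int

    @property
    def confidence(self) -> dict[tuple[str, int], float]:
        """Confidence factor per (term, direction); sums to 1 when non-empty."""
        if self.total_responses == 0:
            return {}
        return {k: c / self.total_responses for k, c in self.counts.items()}


def tally_terms(answers: Iterable[RelationshipAnswer], scale: LinguisticScale) -> TermTally:
    """Tally the (term, direction) endorsements for one relationship.

    Unsure and missing answers are excluded from both the numerator and
    the denominator, so the remaining confidence factors still sum to 1.
    """
    answers = list(answers)
    pairs = {(a.source, a.target) for a in answers}
    if len(pairs) > 1:
        raise ValidationError(f"answers mix several relationships: {sorted(pairs)}")
    counts: Counter[tuple[str, int]] = Counter()
    for a in answers:
        if a.term is None or a.term == scale.unsure_token:
            continue
        if a.term not in scale.terms:
            raise ValidationError(f"unknown term {a.term!r}")
        if a.direction not in (+1, -1):
            raise ValidationError(
                f"strength answer {a.term!r} needs direction +1 or -1"
            )
        counts[(a.term, a.direction)] += 1
    return TermTally(counts=dict(counts), total_responses=sum(counts.values()))


def defuzzify_edge(tally: TermTally, scale: LinguisticScale) -> float:
    """Collapse a tally into a signed edge weight in [-1, 1].

    weight = sum over (term, direction) of confidence * direction *
    centroid(term). A relationship answered only with Unsure (empty
    tally) gets weight 0: the edge is effectively absent.
    """
    return float(sum(
        conf * direction * scale.centroid(term)
        for (term, direction), conf in tally.confidence.items()
    ))


def build_weight_matrix(
    design: TrialDesign,
    answers: Iterable[RelationshipAnswer],
    scale: LinguisticScale,
) -> WeightMatrix:
    """Aggregate all participants' answers into the FCM weight matrix.

    The matrix spans k+2 concepts: the k factors, the outcome, and the
    intervention. Factor/outcome entries are defuzzified from the
    answers; inactive pairs and self-pairs are 0; the intervention row
    carries the fixed +/-1 target signs declared in the design.
    """
    answers = list(answers)
    if not answers:
        raise ValidationError("no answers: cannot build a weight matrix")
    concepts = design.concepts + (INTERVENTION,)
    index = {c: i for i, c in enumerate(concepts)}
    grouped: dict[tuple[str, str], list[RelationshipAnswer]] = {}
    for a in answers:
        pair = (a.source, a.target)
        if pair not in design.active_relationships:
            raise ValidationError(
                f"answer for pruned or unknown relationship {pair[0]!r} -> {pair[1]!r}"
            )
        grouped.setdefault(pair, []).append(a)
    m = len(concepts)
    W = np.zeros((m, m))
    for (src, tgt), group in grouped.items():
        W[index[src], index[tgt]] = defuzzify_edge(tally_terms(group, scale), scale)
    ii = index[INTERVENTION]
    for target, sign in design.intervention_targets.items():
        W[ii, index[target]] = float(sign)
    return WeightMatrix(
        weights=W,
        concepts=concepts,
        outcome=design.outcome_name,
        intervention=INTERVENTION,
    )
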