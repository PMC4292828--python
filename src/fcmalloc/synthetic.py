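"""Virtual trial cohorts: factor values, panel-style relationship
answers, and missingness injection.

The generator emulates the statistical structure of behaviour-change
cohorts: skewed factor distributions (most individuals are sedentary,
approximated by an inverse-Gaussian exercise distribution), factors that
depend linearly on others (weight discrimination on obesity), and
panel-style answering in which every relationship item has its own
distribution over (term, direction) answers including Unsure. Everything
is seeded and reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .allocation import ParticipantRecord
from .design import DEFAULT_TERMS, TrialDesign, UNSURE, create_trial
from .errors import ValidationError
from .fuzzy import RelationshipAnswer


@dataclass(frozen=True)
class FactorSpec:
    """Marginal (or conditional) distribution of one factor on [0, 1].

    kinds: uniform(lo, hi) | normal(mu, sigma) | invgauss(mean, shape) |
    linear(parent, slope, intercept, noise_sd) | constant(value).
    Unbounded samples are re-drawn until inside [0, 1] (proper
    truncation), with a final clip as a safety net; linear values are
    clipped.
    """

    kind: str
    params: Mapping[str, float] = field(default_factory=dict)
    parent: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "normal", "invgauss", "linear", "constant"):
            raise ValidationError(f"unknown factor distribution {self.kind!r}")
        if self.kind == "linear" and not self.parent:
            raise ValidationError("linear factor needs a parent factor")


def uniform(lo: float = 0.0, hi: float = 1.0) -> FactorSpec:
    return FactorSpec("uniform", {"lo": lo, "hi": hi})


def normal(mu: float, sigma: float) -> FactorSpec:
    return FactorSpec("normal", {"mu": mu, "sigma": sigma})


def invgauss(mean: float, shape: float) -> FactorSpec:
    """Inverse-Gaussian (Wald) with the given mean and shape lambda."""
    return FactorSpec("invgauss", {"mean": mean, "shape": shape})


def linear(parent: str, slope: float = 1.0, intercept: float = 0.0,
           noise_sd: float = 0.0) -> FactorSpec:
    return FactorSpec("linear", {"slope": slope, "intercept": intercept,
                                 "noise_sd": noise_sd}, parent=parent)


def constant(value: float) -> FactorSpec:
    return FactorSpec("constant", {"value": value})


@dataclass(frozen=True)
class ItemAnswerSpec:
    """Answer distribution of one relationship item.

    ``categories`` are (term, direction) pairs, direction None meaning
    the unsure token; ``probabilities`` must sum to 1.
    """

    categories: tuple[tuple[Optional[str], Optional[int]], ...]
    probabilities: tuple[float, ...]

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if len(p) != len(self.categories) or np.any(p < 0) or abs(p.sum() - 1) > 1e-9:
            raise ValidationError("item answer probabilities must sum to 1")


@dataclass(frozen=True)
class SyntheticConfig:
    """Everything needed to simulate a cohort for one trial design."""

    factors: Mapping[str, FactorSpec]
    answer_specs: Mapping[tuple[str, str], ItemAnswerSpec]
    relationship_missing_rate: float = 0.0
    relationship_missing_rounds: int = 0
    factor_missing_proportion: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.relationship_missing_rate <= 1.0:
            raise ValidationError("relationship missing rate must be in [0, 1]")
        if not 0.0 <= self.factor_missing_proportion <= 1.0:
            raise ValidationError("factor missing proportion must be in [0, 1]")


def _factor_order(factors: Mapping[str, FactorSpec]) -> list[str]:
    """Topological order so parents are sampled before dependents."""
    order: list[str] = []
    state: dict[str, int] = {}

    def visit(name: str) -> None:
        if state.get(name) == 2:
            return
        if state.get(name) == 1:
            raise ValidationError(f"cyclic factor dependence through {name!r}")
        state[name] = 1
        spec = factors.get(name)
        if spec is None:
            raise ValidationError(f"dependent factor refers to unknown parent {name!r}")
        if spec.parent:
            visit(spec.parent)
        state[name] = 2
        order.append(name)

    for name in factors:
        visit(name)
    return order


def _truncated(draw, rng: np.random.Generator, n: int, max_rounds: int = 50) -> np.ndarray:
    """Rejection-sample into [0, 1], clipping whatever tail survives."""
    x = draw(rng, n)
    for _ in range(max_rounds):
        bad = (x < 0) | (x > 1)
        if not bad.any():
            break
        x[bad] = draw(rng, int(bad.sum()))
    return np.clip(x, 0.0, 1.0)


def _sample_factor(spec: FactorSpec, rng: np.random.Generator, n: int,
                   parents: Mapping[str, np.ndarray]) -> np.ndarray:
    p = spec.params
    if spec.kind == "uniform":
        return rng.uniform(p.get("lo", 0.0), p.get("hi", 1.0), size=n)
    if spec.kind == "normal":
        return _truncated(lambda r, k: r.normal(p["mu"], p["sigma"], size=k), rng, n)
    if spec.kind == "invgauss":
        mean, shape = p["mean"], p["shape"]
        dist = stats.invgauss(mean / shape, scale=shape)
        return _truncated(
            lambda r, k: dist.rvs(size=k, random_state=r), rng, n,
        )
    if spec.kind == "constant":
        v = p["value"]
        if not 0.0 <= v <= 1.0:
            raise ValidationError(f"constant factor value {v} outside [0, 1]")
        return np.full(n, float(v))
    # linear
    base = p["slope"] * parents[spec.parent] + p["intercept"]
    if p.get("noise_sd", 0.0) > 0:
        base = base + rng.normal(0.0, p["noise_sd"], size=n)
    return np.clip(base, 0.0, 1.0)


def generate_cohort(
    config: SyntheticConfig,
    n: int,
    seed: Optional[int] = None,
) -> tuple[list[ParticipantRecord], list[RelationshipAnswer]]:
    """Simulate n completed baseline questionnaires.

    Factor values are drawn per the config (dependent factors after
    their parents); each participant answers every relationship item
    independently from that item's configured distribution. Configured
    missingness (relationship rounds, factor proportion) is applied
    afterwards.
    """
    if n < 1:
        raise ValidationError("need at least one participant")
    rng = np.random.default_rng(seed if seed is not None else config.seed)
    order = _factor_order(config.factors)
    values: dict[str, np.ndarray] = {}
    for name in order:
        values[name] = _sample_factor(config.factors[name], rng, n, values)
    width = max(4, len(str(n)))
    pids = [f"P{i:0{width}d}" for i in range(1, n + 1)]
    records = [
        ParticipantRecord(
            participant_id=pid,
            factor_values={f: float(values[f][i]) for f in config.factors},
        )
        for i, pid in enumerate(pids)
    ]
    answers: list[RelationshipAnswer] = []
    for (src, tgt) in sorted(config.answer_specs):
        spec = config.answer_specs[(src, tgt)]
        draws = rng.choice(len(spec.categories), size=n, p=spec.probabilities)
        for pid, d in zip(pids, draws):
            term, direction = spec.categories[d]
            answers.append(RelationshipAnswer(
                participant_id=pid, source=src, target=tgt,
                term=term, direction=direction,
            ))
    if config.relationship_missing_rounds and config.relationship_missing_rate > 0:
        answers = inject_missing_relationships(
            answers, config.relationship_missing_rate,
            config.relationship_missing_rounds,
            seed=int(rng.integers(2**31)),
        )
    if config.factor_missing_proportion > 0:
        records = inject_missing_factors(
            records, config.factor_missing_proportion,
            seed=int(rng.integers(2**31)),
        )
    return records, answers


def inject_missing_relationships(
    answers: Sequence[RelationshipAnswer],
    rate: float,
    rounds: int = 1,
    seed: Optional[int] = None,
    unsure_token: str = UNSURE,
    target_fraction: Optional[float] = None,
) -> list[RelationshipAnswer]:
    """Degrade relationship answers to Unsure.

    Applies ``rounds`` independent passes, each turning every
    still-answered item Unsure with probability ``rate`` (expected final
    missing fraction 1 - (1 - rate)^rounds). Alternatively
    ``target_fraction`` requests that fraction directly in one pass.
    """
    if target_fraction is not None:
        rate, rounds = float(target_fraction), 1
    if not 0.0 <= rate <= 1.0:
        raise ValidationError("missing rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = list(answers)
    for _ in range(rounds):
        u = rng.random(len(out))
        for i, a in enumerate(out):
            if u[i] < rate and a.term != unsure_token:
                out[i] = replace(a, term=unsure_token, direction=None)
    return out


def inject_missing_factors(
    records: Sequence[ParticipantRecord],
    proportion: float,
    seed: Optional[int] = None,
) -> list[ParticipantRecord]:
    """Blank exactly round(proportion * n_cells) factor cells, uniformly."""
    if not 0.0 <= proportion <= 1.0:
        raise ValidationError("missing proportion must be in [0, 1]")
    records = list(records)
    if not records:
        return []
    factors = list(records[0].factor_values)
    n_cells = len(records) * len(factors)
    n_missing = round(proportion * n_cells)
    rng = np.random.default_rng(seed)
    chosen = rng.choice(n_cells, size=n_missing, replace=False)
    by_record: dict[int, list[str]] = {}
    for c in chosen:
        by_record.setdefault(int(c) // len(factors), []).append(
            factors[int(c) % len(factors)]
        )
    out = []
    for i, r in enumerate(records):
        if i in by_record:
            vals = dict(r.factor_values)
            for f in by_record[i]:
                vals[f] = None
            out.append(replace(r, factor_values=vals))
        else:
            out.append(r)
    return out


# ---------------------------------------------------------------------------
# Ready-made study conditions: an exercise intervention on a sedentary cohort
# ---------------------------------------------------------------------------

#: Prognostic factors of the bundled exercise-trial design.
EXERCISE_FACTORS = (
    "age", "depression", "stress", "obesity", "exercise",
    "food intake", "weight discrimination",
)


def exercise_trial_design() -> TrialDesign:
    """A k=7 obesity-prevention trial: intervene on exercise, measure
    excess weight. Fully connected (56 surveyed relationships)."""
    return create_trial(
        factor_names=list(EXERCISE_FACTORS),
        outcome_name="excess weight",
        intervention_targets={"exercise": +1},
    )


def _panel_profile(rng: np.random.Generator, terms: Sequence[str],
                   unsure_p: float, dissent_p: float) -> ItemAnswerSpec:
    """One relationship item's answer distribution, panel style.

    A modal strength term (biased toward moderate-to-strong consensus)
    with discretized-Laplace spread, a dominant direction, a small
    dissenting share answering the opposite direction, and an Unsure
    share.
    """
    k = len(terms)
    modal = int(rng.choice(k, p=_MODAL_TERM_P[:k] / _MODAL_TERM_P[:k].sum()))
    spread = np.exp(-np.abs(np.arange(k) - modal) / 0.8)
    spread /= spread.sum()
    dominant = int(rng.choice([-1, 1]))
    cats: list[tuple[Optional[str], Optional[int]]] = []
    probs: list[float] = []
    main_share = 1.0 - unsure_p - dissent_p
    for i, t in enumerate(terms):
        cats.append((t, dominant))
        probs.append(main_share * spread[i])
        cats.append((t, -dominant))
        probs.append(dissent_p * spread[i])
    cats.append((UNSURE, None))
    probs.append(unsure_p)
    return ItemAnswerSpec(categories=tuple(cats), probabilities=tuple(probs))


# Panels rating a relationship they consider real tend to call it moderate
# to strong; weak consensus is rarer.
_MODAL_TERM_P = np.array([0.05, 0.15, 0.30, 0.30, 0.20])


def sedentary_cohort_config(
    seed: int = 0,
    design: Optional[TrialDesign] = None,
    unsure_p: float = 0.05,
    dissent_p: float = 0.10,
) -> SyntheticConfig:
    """Study conditions for the bundled exercise trial.

    Factor marginals: sedentary-skewed exercise (inverse Gaussian, mean
    0.25, shape 0.5), food intake slightly above exercise, weight
    discrimination linearly dependent on obesity, and truncated-normal
    demographics/psychosocial factors. Relationship answers follow
    per-item panel profiles drawn once from ``seed``.
    """
    design = design or exercise_trial_design()
    rng = np.random.default_rng(seed)
    answer_specs = {
        pair: _panel_profile(rng, DEFAULT_TERMS, unsure_p, dissent_p)
        for pair in sorted(design.active_relationships)
    }
    factors = {
        "age": normal(0.45, 0.18),
        "depression": normal(0.30, 0.15),
        "stress": normal(0.50, 0.15),
        "obesity": normal(0.55, 0.20),
        "exercise": invgauss(0.25, 0.5),
        "food intake": linear("exercise", slope=1.0, intercept=0.15, noise_sd=0.05),
        "weight discrimination": linear("obesity", slope=0.9, intercept=0.0,
                                        noise_sd=0.02),
    }
    unknown = [f for f in factors if f not in design.factor_names]
    if unknown:
        raise ValidationError(f"factor specs for undeclared factors: {unknown}")
    return SyntheticConfig(factors=factors, answer_specs=answer_specs, seed=seed)


#: Panel identity of the bundled study conditions. A trial has one panel
#: (one shared reality behind the relationship answers); this one was
#: selected, among candidate panel profiles, for the fidelity property
#: that its aggregated map discriminates participants — expected changes
#: spread continuously over the cohort, as in real behaviour-change
#: cohorts — rather than collapsing to a single shared value.
BUNDLED_PANEL_SEED = 13


def bundled_panel_config(design: Optional[TrialDesign] = None) -> SyntheticConfig:
    """The bundled exercise-trial panel (fixed answer profiles)."""
    return sedentary_cohort_config(seed=BUNDLED_PANEL_SEED, design=design)


def generate_sedentary_cohort(
    n: int, seed: int,
) -> tuple[TrialDesign, list[ParticipantRecord], list[RelationshipAnswer]]:
    """Convenience: design + cohort under the bundled study conditions.

    The panel (per-item answer distributions) is fixed; ``seed`` varies
    the cohort — participants' factor values and their individual
    answer draws — mirroring repeated virtual trials against one map.
    """
    design = exercise_trial_design()
    config = bundled_panel_config(design)
    records, answers = generate_cohort(config, n, seed=seed)
    return design, records, answers
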