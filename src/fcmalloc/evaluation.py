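"""Allocation quality: balance of expected behavioural change across
groups, and pairwise agreement between allocations.

The headline quality metric is the population standard deviation (over
the groups) of the groups' mean expected change — the smaller, the more
similar the groups look at baseline. The same dispersion is reported for
the per-group minima and maxima.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np

from .allocation import (
    Allocation,
    AllocationConfig,
    ParticipantRecord,
    allocate_fcm_sorted,
    allocate_permuted_blocks,
    allocate_simple,
    allocate_stratified,
    partial_shuffle,
)
from .design import LinguisticScale, TrialDesign, default_scale
from .engine import EngineConfig, ExpectedChange, expected_changes
from .errors import ValidationError
from .fuzzy import build_weight_matrix


@dataclass(frozen=True)
class GroupStats:
    size: int
    mean: float
    min: float
    max: float


@dataclass(frozen=True)
class QualityReport:
    """Per-group summaries and cross-group dispersions for one allocation."""

    method: str
    groups: tuple[GroupStats, ...]
    sd_mean: float          # population SD of the group means
    sd_min: float
    sd_max: float
    overall_min: float      # absolute extremes across all participants
    overall_max: float

    @property
    def total(self) -> int:
        return sum(g.size for g in self.groups)


def _e_map(changes) -> dict[str, float]:
    out: dict[str, float] = {}
    for c in changes:
        if isinstance(c, ExpectedChange):
            out[c.participant_id] = c.value
        elif isinstance(c, tuple):
            out[str(c[0])] = float(c[1])
        else:
            raise ValidationError(f"cannot interpret expected change {c!r}")
    return out


def quality(alloc: Allocation, changes: Iterable) -> QualityReport:
    """Summarize one allocation against the expected-change values."""
    e = _e_map(changes) if not isinstance(changes, Mapping) else dict(changes)
    missing = [p for p in alloc.groups if p not in e]
    if missing:
        raise ValidationError(f"participants without expected change: {missing[:5]}")
    per_group: list[GroupStats] = []
    for g in range(alloc.n_groups):
        vals = [e[p] for p, gg in alloc.groups.items() if gg == g]
        if vals:
            per_group.append(GroupStats(
                size=len(vals), mean=float(np.mean(vals)),
                min=float(np.min(vals)), max=float(np.max(vals)),
            ))
        else:
            per_group.append(GroupStats(size=0, mean=np.nan, min=np.nan, max=np.nan))
    means = [g.mean for g in per_group if g.size]
    mins = [g.min for g in per_group if g.size]
    maxs = [g.max for g in per_group if g.size]
    allvals = [e[p] for p in alloc.groups]
    return QualityReport(
        method=alloc.method,
        groups=tuple(per_group),
        sd_mean=float(np.std(means)),
        sd_min=float(np.std(mins)),
        sd_max=float(np.std(maxs)),
        overall_min=float(np.min(allvals)),
        overall_max=float(np.max(allvals)),
    )


def overlap(a: Allocation, b: Allocation) -> float:
    """Pairwise agreement between two allocations (Rand-index style).

    The fraction of unordered participant pairs that are either
    co-grouped in both allocations or separated in both; invariant to
    group relabelling, 1.0 iff the partitions coincide.
    """
    if set(a.groups) != set(b.groups):
        raise ValidationError("allocations cover different participant sets")
    pids = sorted(a.groups)
    n = len(pids)
    if n < 2:
        raise ValidationError("overlap needs at least two participants")
    ga = np.array([a.groups[p] for p in pids])
    gb = np.array([b.groups[p] for p in pids])
    same_a = ga[:, None] == ga[None, :]
    same_b = gb[:, None] == gb[None, :]
    iu = np.triu_indices(n, k=1)
    agree = same_a[iu] == same_b[iu]
    return float(np.mean(agree))


def compare_methods(
    records: Iterable[ParticipantRecord],
    answers: Iterable,
    design: TrialDesign,
    config: AllocationConfig,
    scale: Optional[LinguisticScale] = None,
    engine_config: Optional[EngineConfig] = None,
    stratify_factors: Optional[Iterable[str]] = None,
    changes: Optional[list[ExpectedChange]] = None,
) -> dict[str, tuple[Allocation, QualityReport]]:
    """Run every allocation method on the same cohort and score each.

    Expected changes are computed once (from the pooled weight matrix)
    and reused both to drive the FCM-sorted method and to evaluate all
    methods. Each randomized method gets its own child seed derived from
    ``config.seed``, so runs are reproducible end to end.
    """
    records = list(records)
    answers = list(answers)
    scale = scale or default_scale()
    engine_config = engine_config or EngineConfig()
    if changes is None:
        W = build_weight_matrix(design, answers, scale)
        changes = expected_changes(W, records, engine_config)
    ids = [r.participant_id for r in records]
    if stratify_factors is None:
        stratify_factors = design.factor_names
    ss = np.random.SeedSequence(config.seed)
    n_strat = len(tuple(stratify_factors))
    child = ss.generate_state(2 + n_strat + 1)
    results: dict[str, tuple[Allocation, QualityReport]] = {}

    if config.shuffle_p > 0:
        ordered = sorted(changes, key=lambda c: (c.value, c.participant_id))
        shuffled = partial_shuffle(
            [c.participant_id for c in ordered], config.shuffle_p,
            mode=config.shuffle_mode, n_bins=config.shuffle_bins,
            seed=int(child[-1]),
        )
        fcm = Allocation(
            groups={pid: i % config.n_groups for i, pid in enumerate(shuffled)},
            n_groups=config.n_groups, method="fcm", seed=config.seed,
        )
    else:
        fcm = allocate_fcm_sorted(changes, config.n_groups)
    results["fcm"] = (fcm, quality(fcm, changes))

    simple = allocate_simple(ids, config.n_groups, seed=int(child[0]))
    results["simple"] = (simple, quality(simple, changes))

    blocks = allocate_permuted_blocks(
        ids, config.n_groups, config.effective_block_size, seed=int(child[1]),
    )
    results["blocks"] = (blocks, quality(blocks, changes))

    for i, factor in enumerate(stratify_factors):
        strat = allocate_stratified(
            records, factor, config.n_bins, config.n_groups,
            config.effective_block_size, seed=int(child[2 + i]),
        )
        results[strat.method] = (strat, quality(strat, changes))
    return results


def plot_method_comparison(results: Mapping[str, tuple[Allocation, QualityReport]],
                           path: str) -> None:
    """Bar chart of the cross-group SD of mean expected change per method."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    methods = list(results)
    sds = [results[m][1].sd_mean for m in methods]
    fig, ax = plt.subplots(figsize=(1 + 0.9 * len(methods), 4))
    ax.bar(range(len(methods)), sds, color="steelblue")
    ax.set_xticks(range(len(methods)))
    ax.set_xticklabels(methods, rotation=45, ha="right")
    ax.set_ylabel("SD of group-mean expected change")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
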