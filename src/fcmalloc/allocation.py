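"""Participant-to-group allocation.

Implements the FCM-sorted protocol (sort participants by expected
behavioural change, deal them cyclically over the groups) alongside the
standard baseline methods — simple randomization, random permuted
blocks, and stratification — plus sequential/batch allocation, partial
re-randomization of the sorted sequence, and factor imputation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .design import LinguisticScale, TrialDesign, default_scale
from .engine import EngineConfig, ExpectedChange, expected_changes
from .errors import ValidationError


@dataclass(frozen=True)
class ParticipantRecord:
    """One participant's normalized prognostic-factor values.

    ``factor_values`` maps concept label -> value in [0, 1], or None for
    a missing answer.
    """

    participant_id: str
    factor_values: Mapping[str, Optional[float]]

    def __post_init__(self) -> None:
        for k, v in self.factor_values.items():
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValidationError(
                    f"factor {k!r} of {self.participant_id!r}: {v} outside [0, 1]"
                )


@dataclass(frozen=True)
class AllocationConfig:
    """Knobs shared by the allocation methods.

    block_size must be a positive multiple of n_groups; shuffle_p is the
    proportion of individuals whose positions are swapped after sorting;
    n_sequences is the number s of recruitment waves (batch size is
    ceil(sample / s)).
    """

    n_groups: int = 4
    block_size: Optional[int] = None          # default: 2 * n_groups
    stratify_on: Optional[str] = None
    n_bins: int = 4
    shuffle_p: float = 0.0
    shuffle_mode: str = "uniform"             # uniform | distance | binned
    shuffle_bins: int = 10
    n_sequences: int = 1
    imputation: str = "none"                  # mean | normal | constant | none
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_groups < 2:
            raise ValidationError("need at least two groups")
        bs = self.block_size
        if bs is not None and (bs <= 0 or bs % self.n_groups != 0):
            raise ValidationError("block_size must be a positive multiple of n_groups")
        if not 0.0 <= self.shuffle_p <= 1.0:
            raise ValidationError("shuffle proportion must be in [0, 1]")
        if self.shuffle_mode not in ("uniform", "distance", "binned"):
            raise ValidationError(f"unknown shuffle mode {self.shuffle_mode!r}")
        if self.n_sequences < 1:
            raise ValidationError("need at least one recruitment sequence")
        if self.imputation not in ("mean", "normal", "constant", "none"):
            raise ValidationError(f"unknown imputation strategy {self.imputation!r}")

    @property
    def effective_block_size(self) -> int:
        return self.block_size if self.block_size is not None else 2 * self.n_groups


@dataclass(frozen=True)
class Allocation:
    """A complete participant -> group assignment."""

    groups: Mapping[str, int]
    n_groups: int
    method: str
    seed: Optional[int] = None
    batch: Optional[Mapping[str, int]] = None   # sequential provenance

    def __post_init__(self) -> None:
        bad = {p: g for p, g in self.groups.items()
               if not 0 <= g < self.n_groups}
        if bad:
            raise ValidationError(f"group indices out of range: {bad}")

    def group_members(self, g: int) -> list[str]:
        return [p for p, gg in self.groups.items() if gg == g]

    def sizes(self) -> list[int]:
        out = [0] * self.n_groups
        for g in self.groups.values():
            out[g] += 1
        return out


def _as_e_list(changes: Iterable[ExpectedChange | tuple[str, float]]) -> list[tuple[str, float]]:
    out = []
    for c in changes:
        if isinstance(c, ExpectedChange):
            out.append((c.participant_id, c.value))
        else:
            pid, e = c
            out.append((str(pid), float(e)))
    return out


def allocate_fcm_sorted(
    changes: Iterable[ExpectedChange | tuple[str, float]],
    n_groups: int,
) -> Allocation:
    """Deterministic FCM-sorted allocation.

    Participants are sorted ascending by expected change E (ties broken
    by participant id, stable) and the i-th participant in sorted order
    goes to group i mod n_groups, so group sizes differ by at most 1.
    """
    pairs = _as_e_list(changes)
    if n_groups < 2:
        raise ValidationError("need at least two groups")
    if len(pairs) < n_groups:
        raise ValidationError(
            f"{len(pairs)} participants cannot fill {n_groups} groups"
        )
    ordered = sorted(pairs, key=lambda t: (t[1], t[0]))
    return Allocation(
        groups={pid: i % n_groups for i, (pid, _) in enumerate(ordered)},
        n_groups=n_groups,
        method="fcm",
    )


def allocate_simple(ids: Sequence[str], n_groups: int, seed: Optional[int] = None) -> Allocation:
    """Simple randomization: independent uniform group per participant."""
    if n_groups < 2:
        raise ValidationError("need at least two groups")
    ids = list(ids)
    if not ids:
        raise ValidationError("no participants to allocate")
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, n_groups, size=len(ids))
    return Allocation(
        groups={pid: int(g) for pid, g in zip(ids, draws)},
        n_groups=n_groups, method="simple", seed=seed,
    )


def enumerate_block_sequences(block_size: int, n_groups: int) -> list[tuple[int, ...]]:
    """All distinct within-block assignment orders.

    A block holds block_size/n_groups slots per group; the result lists
    every distinct ordering (a multiset permutation), e.g. 6 sequences
    for blocks of 4 over 2 groups.
    """
    if block_size <= 0 or n_groups < 2 or block_size % n_groups != 0:
        raise ValidationError("block_size must be a positive multiple of n_groups")
    per = block_size // n_groups
    base = []
    for g in range(n_groups):
        base.extend([g] * per)

    def _perms(pool: list[int]) -> Iterable[tuple[int, ...]]:
        if not pool:
            yield ()
            return
        for g in sorted(set(pool)):
            rest = pool.copy()
            rest.remove(g)
            for tail in _perms(rest):
                yield (g,) + tail

    return list(_perms(base))


def allocate_permuted_blocks(
    ids: Sequence[str],
    n_groups: int,
    block_size: int,
    seed: Optional[int] = None,
) -> Allocation:
    """Random permuted blocks of fixed size.

    Participants are taken in the given order; each full block is a
    uniformly drawn ordering of the balanced block multiset, and a final
    partial block is a uniformly drawn prefix of one.
    """
    if block_size <= 0 or n_groups < 2 or block_size % n_groups != 0:
        raise ValidationError("block_size must be a positive multiple of n_groups")
    ids = list(ids)
    if not ids:
        raise ValidationError("no participants to allocate")
    rng = np.random.default_rng(seed)
    per = block_size // n_groups
    base = np.repeat(np.arange(n_groups), per)
    assigned: dict[str, int] = {}
    for start in range(0, len(ids), block_size):
        block_ids = ids[start:start + block_size]
        order = rng.permutation(base)
        for pid, g in zip(block_ids, order):
            assigned[pid] = int(g)
    return Allocation(groups=assigned, n_groups=n_groups,
                      method="blocks", seed=seed)


def _quantile_strata(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Stratum index per value via quantile binning (non-empty strata)."""
    if n_bins < 1:
        raise ValidationError("need at least one stratum")
    edges = np.unique(np.quantile(values, np.linspace(0, 1, n_bins + 1)[1:-1]))
    return np.searchsorted(edges, values, side="left")


def allocate_stratified(
    records: Iterable[ParticipantRecord],
    factor: str,
    n_bins: int,
    n_groups: int,
    block_size: int,
    seed: Optional[int] = None,
) -> Allocation:
    """Stratification on one factor with permuted blocks per stratum.

    Records are partitioned into up to n_bins strata by quantiles of the
    factor value (a constant factor collapses to one stratum), and the
    permuted-block scheme runs independently inside each stratum.
    """
    records = list(records)
    if not records:
        raise ValidationError("no participants to allocate")
    vals = []
    for r in records:
        v = r.factor_values.get(factor)
        if v is None:
            raise ValidationError(
                f"participant {r.participant_id!r} has no value for "
                f"stratification factor {factor!r}; impute first"
            )
        vals.append(v)
    strata = _quantile_strata(np.asarray(vals, dtype=float), n_bins)
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(int(strata.max()) + 1)
    assigned: dict[str, int] = {}
    for s in range(int(strata.max()) + 1):
        members = [r.participant_id for r, si in zip(records, strata) if si == s]
        if not members:
            continue
        sub = allocate_permuted_blocks(
            members, n_groups, block_size, seed=int(child_seeds[s]),
        )
        assigned.update(sub.groups)
    return Allocation(groups=assigned, n_groups=n_groups,
                      method=f"stratified:{factor}", seed=seed)


def apply_swaps(sequence: Sequence, pairs: Iterable[tuple[int, int]]) -> list:
    """Return a copy of ``sequence`` with the given position pairs swapped."""
    out = list(sequence)
    for i, j in pairs:
        out[i], out[j] = out[j], out[i]
    return out


def partial_shuffle(
    sorted_ids: Sequence,
    p: float,
    mode: str = "uniform",
    n_bins: int = 10,
    seed: Optional[int] = None,
) -> list:
    """Inject randomness into the sorted allocation sequence.

    uniform
        round(p*N/2) disjoint swaps of uniformly chosen position pairs,
        so about a fraction p of individuals change position.
    distance
        Same number of swaps, but the partner position is drawn with
        probability decaying as 1/(1 + d) in sequence distance d, so
        nearby individuals (similar expected change) swap preferentially.
    binned
        The sequence is cut into n_bins contiguous bins and permuted
        uniformly within each bin, fully preventing distant swaps.

    p = 0 is always the identity.
    """
    if not 0.0 <= p <= 1.0:
        raise ValidationError("shuffle proportion must be in [0, 1]")
    seq = list(sorted_ids)
    n = len(seq)
    if p == 0.0 or n < 2:
        return seq
    rng = np.random.default_rng(seed)
    if mode == "binned":
        if n_bins < 1:
            raise ValidationError("need at least one bin")
        out: list = []
        for chunk in np.array_split(np.arange(n), min(n_bins, n)):
            perm = rng.permutation(chunk)
            out.extend(seq[i] for i in perm)
        return out
    n_swaps = round(p * n / 2)
    if n_swaps == 0:
        return seq
    if mode == "uniform":
        chosen = rng.choice(n, size=min(2 * n_swaps, n - (n % 2)), replace=False)
        pairs = [(int(chosen[2 * i]), int(chosen[2 * i + 1]))
                 for i in range(len(chosen) // 2)]
        return apply_swaps(seq, pairs)
    if mode == "distance":
        free = list(range(n))
        pairs = []
        for _ in range(n_swaps):
            if len(free) < 2:
                break
            i = free.pop(rng.integers(len(free)))
            d = np.abs(np.array(free) - i)
            w = 1.0 / (1.0 + d)
            j = free.pop(int(rng.choice(len(free), p=w / w.sum())))
            pairs.append((i, j))
        return apply_swaps(seq, pairs)
    raise ValidationError(f"unknown shuffle mode {mode!r}")


def impute(
    records: Iterable[ParticipantRecord],
    strategy: str,
    seed: Optional[int] = None,
    constant: float = 0.5,
) -> list[ParticipantRecord]:
    """Fill missing factor values.

    mean
        Observed mean of that factor across the cohort.
    normal
        Draw from a normal fitted to the observed values, clipped to
        [0, 1].
    constant
        Replace by ``constant`` (default 0.5, the scale midpoint).

    Non-missing values are never altered.
    """
    records = list(records)
    if strategy not in ("mean", "normal", "constant"):
        raise ValidationError(f"unknown imputation strategy {strategy!r}")
    factors = sorted({f for r in records for f in r.factor_values})
    observed = {f: [r.factor_values[f] for r in records
                    if r.factor_values.get(f) is not None]
                for f in factors}
    if strategy in ("mean", "normal"):
        empty = [f for f in factors
                 if any(r.factor_values.get(f) is None for r in records)
                 and not observed[f]]
        if empty:
            raise ValidationError(
                f"cannot fit {strategy!r} imputation: factors with no "
                f"observed values: {empty}"
            )
    rng = np.random.default_rng(seed)
    stats = {f: (float(np.mean(v)), float(np.std(v))) if v else (None, None)
             for f, v in observed.items()}
    out = []
    for r in records:
        vals = dict(r.factor_values)
        changed = False
        for f, v in vals.items():
            if v is not None:
                continue
            if strategy == "constant":
                vals[f] = float(constant)
            elif strategy == "mean":
                vals[f] = stats[f][0]
            else:
                mu, sd = stats[f]
                vals[f] = float(np.clip(rng.normal(mu, sd), 0.0, 1.0))
            changed = True
        out.append(replace(r, factor_values=vals) if changed else r)
    return out


def allocate_sequential(
    batches: Sequence[tuple[Sequence[ParticipantRecord], Sequence]],
    design: TrialDesign,
    config: AllocationConfig,
    scale: Optional[LinguisticScale] = None,
    engine_config: Optional[EngineConfig] = None,
) -> Allocation:
    """Sequential (batch) FCM-sorted allocation over recruitment waves.

    For wave t the weight matrix is rebuilt from the answers of waves
    1..t (cumulative), expected changes are computed for wave-t
    participants only, and they are sorted and dealt cyclically with the
    group cycle continuing from the number already allocated, so global
    sizes stay balanced. Earlier assignments are never revisited; a
    single batch reproduces :func:`allocate_fcm_sorted` exactly.
    """
    from .fuzzy import build_weight_matrix  # deferred: avoids module cycle

    if not batches:
        raise ValidationError("no recruitment batches")
    scale = scale or default_scale()
    engine_config = engine_config or EngineConfig()
    assigned: dict[str, int] = {}
    provenance: dict[str, int] = {}
    cumulative_answers: list = []
    offset = 0
    for t, (records, answers) in enumerate(batches):
        records = list(records)
        answers = list(answers)
        if not records or not answers:
            raise ValidationError(f"batch {t} is empty")
        cumulative_answers.extend(answers)
        W = build_weight_matrix(design, cumulative_answers, scale)
        changes = expected_changes(W, records, engine_config)
        ordered = sorted(changes, key=lambda c: (c.value, c.participant_id))
        for i, c in enumerate(ordered):
            if c.participant_id in assigned:
                raise ValidationError(
                    f"participant {c.participant_id!r} appears in two batches"
                )
            assigned[c.participant_id] = (offset + i) % config.n_groups
            provenance[c.participant_id] = t
        offset += len(ordered)
    return Allocation(
        groups=assigned, n_groups=config.n_groups, method="fcm-sequential",
        seed=config.seed, batch=provenance,
    )


def split_batches(
    records: Sequence[ParticipantRecord],
    answers: Sequence,
    n_sequences: int,
) -> list[tuple[list[ParticipantRecord], list]]:
    """Cut a cohort into s recruitment waves of size ceil(n / s).

    Participants keep their given (recruitment) order; each wave carries
    the relationship answers of its own participants.
    """
    if n_sequences < 1:
        raise ValidationError("need at least one sequence")
    records = list(records)
    n = len(records)
    b = -(-n // n_sequences)  # ceil
    by_pid: dict[str, list] = {}
    for a in answers:
        by_pid.setdefault(a.participant_id, []).append(a)
    out = []
    for start in range(0, n, b):
        chunk = records[start:start + b]
        chunk_answers = [a for r in chunk for a in by_pid.get(r.participant_id, [])]
        out.append((chunk, chunk_answers))
    return out
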