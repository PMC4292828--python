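"""FCM simulation: iterate concept values to a stable state and compute
each participant's expected behavioural change under the intervention.

The update rule is the standard simultaneous (Kosko-style) one,

    V_j(t+1) = f( sum_i W_ij V_i(t) )        f(x) = tanh(lambda x),

optionally with a self-memory term V_j(t) added inside the sum. The
intervention concept is clamped every iteration — 1 for the run with the
intervention, 0 for the run without — and a participant's expected
change E_i is the difference of the stabilized outcome values between
the two runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np

from .errors import ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .allocation import ParticipantRecord

#: Label of the automatically added intervention concept.
INTERVENTION = "intervention"


@dataclass(frozen=True)
class WeightMatrix:
    """Signed FCM edge weights W_ij from source concept i to target j."""

    weights: np.ndarray
    concepts: tuple[str, ...]
    outcome: str
    intervention: str

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", W)
        m = len(self.concepts)
        if W.shape != (m, m):
            raise ValidationError(f"weight matrix shape {W.shape} != ({m}, {m})")
        if np.any(np.abs(W) > 1 + 1e-12):
            raise ValidationError("edge weights must lie in [-1, 1]")
        if np.any(np.diag(W) != 0):
            raise ValidationError("self-weights (diagonal) must be 0")
        for label in (self.outcome, self.intervention):
            if label not in self.concepts:
                raise ValidationError(f"concept {label!r} not in matrix")

    def index(self, label: str) -> int:
        try:
            return self.concepts.index(label)
        except ValueError:
            raise ValidationError(f"unknown concept {label!r}") from None

    @property
    def outcome_index(self) -> int:
        return self.index(self.outcome)

    @property
    def intervention_index(self) -> int:
        return self.index(self.intervention)


@dataclass(frozen=True)
class EngineConfig:
    """Numerical settings of the FCM simulation.

    slope
        Steepness lambda of the tanh transfer function (dimensionless).
    tol
        Convergence tolerance epsilon on the max absolute concept change.
    max_iter
        Iteration cap; runs hitting it are flagged non-converged and
        reported as the mean over the final ``tail_window`` iterations.
    self_memory
        Add V_j(t) inside the update sum (alternative FCM convention).
    """

    slope: float = 1.0
    tol: float = 1e-5
    max_iter: int = 100
    self_memory: bool = False
    tail_window: int = 10

    def __post_init__(self) -> None:
        if not (self.slope > 0 and self.tol > 0 and self.max_iter >= 1
                and self.tail_window >= 1):
            raise ValidationError("invalid engine configuration")


@dataclass
class FCMState:
    """Concept values of one simulation, with convergence bookkeeping."""

    values: np.ndarray
    iteration: int = 0
    converged: bool = False


@dataclass(frozen=True)
class ExpectedChange:
    """Per-participant simulated outcome difference (with - without)."""

    participant_id: str
    value: float
    converged_with: bool = True
    converged_without: bool = True


def transfer(x, config: EngineConfig = EngineConfig()):
    """tanh transfer function bounding concept values in (-1, 1)."""
    return np.tanh(config.slope * np.asarray(x, dtype=float))


def _clamp_arrays(W: WeightMatrix, clamped: Mapping[str, float]):
    idx = np.array([W.index(lbl) for lbl in clamped], dtype=int)
    vals = np.array([float(v) for v in clamped.values()])
    return idx, vals


def step(
    W: WeightMatrix,
    state: FCMState,
    clamped: Mapping[str, float],
    config: EngineConfig = EngineConfig(),
) -> FCMState:
    """One synchronous update of all non-clamped concepts."""
    v = np.asarray(state.values, dtype=float)
    if v.shape != (len(W.concepts),):
        raise ValidationError("state dimension does not match the weight matrix")
    ci, cv = _clamp_arrays(W, clamped)
    x = v @ W.weights
    if config.self_memory:
        x = x + v
    nxt = np.tanh(config.slope * x)
    if ci.size:
        nxt[ci] = cv
    return FCMState(values=nxt, iteration=state.iteration + 1, converged=False)


def simulate_batch(
    W: WeightMatrix,
    initial: np.ndarray,
    clamped: Mapping[str, float],
    config: EngineConfig = EngineConfig(),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Iterate many independent initial states at once.

    Parameters
    ----------
    initial
        Array (n, m) of initial concept values, one row per run.

    Returns
    -------
    values : (n, m) stabilized states. Rows that converged are frozen at
        their first sub-tolerance step; rows that did not are the mean
        over the final ``tail_window`` iterations.
    converged : (n,) bool flags.
    iterations : (n,) iteration of convergence (max_iter if none).
    """
    V = np.array(initial, dtype=float)
    if V.ndim != 2 or V.shape[1] != len(W.concepts):
        raise ValidationError("initial state batch must be (n_runs, n_concepts)")
    n = V.shape[0]
    ci, cv = _clamp_arrays(W, clamped)
    if ci.size:
        V[:, ci] = cv
    frozen = np.zeros(n, dtype=bool)
    iters = np.full(n, config.max_iter, dtype=int)
    tail: list[np.ndarray] = []
    Wm = W.weights
    for it in range(1, config.max_iter + 1):
        x = V @ Wm
        if config.self_memory:
            x = x + V
        nxt = np.tanh(config.slope * x)
        if ci.size:
            nxt[:, ci] = cv
        delta = np.abs(nxt - V).max(axis=1)
        nxt[frozen] = V[frozen]
        newly = (~frozen) & (delta < config.tol)
        iters[newly] = it
        frozen |= newly
        V = nxt
        if not np.all(np.isfinite(V)):  # pragma: no cover - tanh forbids this
            raise FloatingPointError("non-finite concept value during simulation")
        tail.append(V.copy())
        if len(tail) > config.tail_window:
            tail.pop(0)
        if frozen.all():
            break
    if not frozen.all():
        tail_mean = np.mean(tail, axis=0)
        V[~frozen] = tail_mean[~frozen]
    return V, frozen, iters


def simulate(
    W: WeightMatrix,
    initial: FCMState | Sequence[float] | np.ndarray,
    clamped: Mapping[str, float],
    config: EngineConfig = EngineConfig(),
    return_trajectory: bool = False,
):
    """Iterate one initial state until stable (or max_iter).

    Returns the final :class:`FCMState`; with ``return_trajectory=True``
    also the list of intermediate value vectors.
    """
    v0 = initial.values if isinstance(initial, FCMState) else np.asarray(initial, float)
    if not return_trajectory:
        vals, conv, iters = simulate_batch(W, v0[None, :], clamped, config)
        return FCMState(values=vals[0], iteration=int(iters[0]), converged=bool(conv[0]))
    state = FCMState(values=np.asarray(v0, dtype=float).copy())
    ci, cv = _clamp_arrays(W, clamped)
    if ci.size:
        state.values[ci] = cv
    traj = [state.values.copy()]
    for _ in range(config.max_iter):
        nxt = step(W, state, clamped, config)
        delta = float(np.abs(nxt.values - state.values).max())
        state = nxt
        traj.append(state.values.copy())
        if delta < config.tol:
            state.converged = True
            break
    if not state.converged:
        c = min(config.tail_window, len(traj))
        state.values = np.mean(traj[-c:], axis=0)
    return state, traj


def _initial_batch(W: WeightMatrix, records: Iterable["ParticipantRecord"]) -> np.ndarray:
    records = list(records)
    m = len(W.concepts)
    oi, ii = W.outcome_index, W.intervention_index
    V = np.zeros((len(records), m))
    for r, rec in enumerate(records):
        for j, concept in enumerate(W.concepts):
            if j in (oi, ii):
                continue  # outcome starts unknown (0); intervention is clamped
            val = rec.factor_values.get(concept)
            if val is None:
                raise ValidationError(
                    f"participant {rec.participant_id!r} is missing factor "
                    f"{concept!r}; impute before simulating"
                )
            if not 0.0 <= val <= 1.0:
                raise ValidationError(
                    f"factor value {concept!r}={val} of "
                    f"{rec.participant_id!r} outside [0, 1]"
                )
            V[r, j] = val
    return V


def expected_changes(
    W: WeightMatrix,
    records: Iterable["ParticipantRecord"],
    config: EngineConfig = EngineConfig(),
) -> list[ExpectedChange]:
    """Expected behavioural change E_i for a whole cohort (vectorized).

    For each participant the FCM is run twice from their factor values —
    intervention clamped at 1, then at 0 — and E_i is the difference of
    the stabilized outcome values.
    """
    records = list(records)
    V0 = _initial_batch(W, records)
    oi = W.outcome_index
    on, conv_on, _ = simulate_batch(W, V0, {W.intervention: 1.0}, config)
    off, conv_off, _ = simulate_batch(W, V0, {W.intervention: 0.0}, config)
    return [
        ExpectedChange(
            participant_id=rec.participant_id,
            value=float(on[r, oi] - off[r, oi]),
            converged_with=bool(conv_on[r]),
            converged_without=bool(conv_off[r]),
        )
        for r, rec in enumerate(records)
    ]


def expected_change(
    W: WeightMatrix,
    record: "ParticipantRecord",
    config: EngineConfig = EngineConfig(),
) -> ExpectedChange:
    """Expected behavioural change for a single participant."""
    return expected_changes(W, [record], config)[0]
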