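"""Surrogate isometric elbow-flexion mechanics.

The task is isometric at a fixed posture (45° shoulder flexion, 90° elbow
flexion, supinated forearm), so muscle-tendon dynamics collapse and joint
torque is a static linear map of activations:

    T(t) = sum_i fmax_i * a_i(t) * r_i

The inverse problem (find excitations that track a torque target) is the
classic muscle-redundancy problem, solved per time step by minimum-norm
static optimization:

    minimize sum_i a_i^2   s.t.   sum_i c_i a_i = T,  0 <= a_i <= 1,

with c_i = fmax_i * r_i over the flexors and the extensors pinned at a
configurable co-activation floor.  The interior solution is a_i = T c_i /
sum_j c_j^2; channels that hit the upper bound are clamped (largest
activation ratio first, deterministic name order on ties) and the remainder
re-solved.  A step is infeasible — the convergence flag drops — when the
target exceeds the flexion-strength ceiling sum_i c_i.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .anthropometry import ScaledElbowModel, GROUP_ORDER

__all__ = [
    "TorqueTarget",
    "ActivationTrace",
    "TorqueTrace",
    "build_target_profile",
    "forward_torque",
    "solve_activations",
    "solve_activation_matrix",
]


@dataclass(frozen=True)
class TorqueTarget:
    """Ramp-and-hold torque profile: linear ramp, plateau, extension hold."""

    peak: float                  # N·m
    ramp_start: float = 10.0     # N·m
    ramp_duration: float = 1.5   # s
    plateau_duration: float = 1.5  # s
    extended_duration: float = 30.0  # s, total trial length

    def __post_init__(self) -> None:
        if not (self.peak >= self.ramp_start > 0):
            raise ValueError("require peak >= ramp_start > 0")
        if min(self.ramp_duration, self.plateau_duration,
               self.extended_duration) <= 0:
            raise ValueError("durations must be positive")


@dataclass(frozen=True)
class TimeSeries:
    times: np.ndarray
    values: np.ndarray  # (n,) or (n, channels)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if t.ndim != 1 or len(t) != len(v):
            raise ValueError("times and values must have equal length")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_channels(self) -> int:
        return 1 if self.values.ndim == 1 else self.values.shape[1]

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])


class ActivationTrace(TimeSeries):
    """Per-actuator (or per-group) activations in [0, 1] over time."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if np.any(self.values < -1e-12) or np.any(self.values > 1 + 1e-12):
            raise ValueError("activations must lie in [0, 1]")


class TorqueTrace(TimeSeries):
    """Elbow-flexion torque (N·m) over time."""


def build_target_profile(target: TorqueTarget, dt: float) -> TorqueTrace:
    """Sample the ramp-plateau-hold profile on a uniform grid of step dt."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    times = np.arange(0.0, target.extended_duration + dt / 2, dt)
    ramp = target.ramp_start + (target.peak - target.ramp_start) * np.clip(
        times / target.ramp_duration, 0.0, 1.0)
    return TorqueTrace(times, ramp)


def _activation_matrix(model: ScaledElbowModel,
                       act: ActivationTrace) -> np.ndarray:
    """Expand a 4-group or 7-actuator trace to per-actuator columns (n, 7)."""
    vals = np.atleast_2d(act.values.T).T  # (n, c)
    if vals.shape[1] == len(model.actuators):
        return vals
    if vals.shape[1] == len(GROUP_ORDER):
        cols = {g: vals[:, i] for i, g in enumerate(GROUP_ORDER)}
        return np.column_stack([cols[a.group] for a in model.actuators])
    raise ValueError(
        f"expected {len(GROUP_ORDER)} or {len(model.actuators)} activation "
        f"channels, got {vals.shape[1]}")


def forward_torque(model: ScaledElbowModel, act: ActivationTrace) -> TorqueTrace:
    """Isometric forward map: T(t) = Σ fmax_i a_i(t) r_i at the fixed posture."""
    a7 = _activation_matrix(model, act)
    c = np.array([a.torque_capacity for a in model.actuators])
    return TorqueTrace(act.times, a7 @ c)


def solve_activation_matrix(capacities: np.ndarray, targets: np.ndarray,
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized min-norm redundancy solve over many targets at once.

    Parameters
    ----------
    capacities : (k,) positive torque capacities c_i of the free channels.
    targets : (n,) nonnegative torque targets.

    Returns
    -------
    activations : (n, k) array, each row the min-norm solution clipped to
        [0, 1] with clamp-and-redistribute.
    feasible : (n,) bool, False where the target exceeds Σ c_i.
    """
    c = np.asarray(capacities, dtype=float)
    T = np.asarray(targets, dtype=float)
    if np.any(T < 0):
        raise ValueError("target torque must be nonnegative")
    n, k = len(T), len(c)
    a = np.zeros((n, k))
    feasible = T <= c.sum() + 1e-9
    free = np.ones((n, k), dtype=bool)
    resid = T.copy()
    # Each pass clamps at least one channel per still-violating row; the
    # interior formula is a_i = T c_i / Σ_free c_j^2.
    for _ in range(k):
        denom = np.where(free, c**2, 0.0).sum(axis=1)
        lam = np.divide(resid, denom, out=np.zeros(n), where=denom > 0)
        a = np.where(free, lam[:, None] * c[None, :], a)
        over = (a > 1.0) & free
        rows = over.any(axis=1)
        if not rows.any():
            break
        # clamp the single worst channel per row (largest interior value →
        # largest c_i; ties resolved by column order, i.e. actuator order)
        worst = np.argmax(np.where(over, a, -np.inf), axis=1)
        idx = np.flatnonzero(rows)
        a[idx, worst[idx]] = 1.0
        free[idx, worst[idx]] = False
        clamped_torque = (np.where(~free[idx], a[idx], 0.0) * c).sum(axis=1)
        resid[idx] = np.maximum(T[idx] - clamped_torque, 0.0)
    return np.clip(a, 0.0, 1.0), feasible


def solve_activations(model: ScaledElbowModel, target: TorqueTrace,
                      coactivation_floor: float = 0.0,
                      ) -> tuple[ActivationTrace, bool]:
    """Static-optimization inverse: activations tracking a torque target.

    Flexors receive the per-step minimum-norm solution; extensors sit at
    ``coactivation_floor`` and their (negative) torque contribution is
    compensated by the flexors.  Returns the 7-channel activation trace and
    a convergence flag that is False iff any step's compensated target
    exceeds the flexion-strength ceiling.
    """
    if not 0.0 <= coactivation_floor <= 1.0:
        raise ValueError("coactivation_floor must lie in [0, 1]")
    if np.any(target.values < 0):
        raise ValueError("target torque must be nonnegative")
    flex_idx = [i for i, a in enumerate(model.actuators) if a.group != "TRI"]
    ext_idx = [i for i, a in enumerate(model.actuators) if a.group == "TRI"]
    c_flex = np.array([model.actuators[i].torque_capacity for i in flex_idx])
    c_ext = np.array([model.actuators[i].torque_capacity for i in ext_idx])
    ext_torque = coactivation_floor * c_ext.sum()  # negative or zero
    eff_target = np.asarray(target.values, dtype=float) - ext_torque
    a_flex, feasible = solve_activation_matrix(c_flex, eff_target)
    out = np.zeros((len(target.values), len(model.actuators)))
    out[:, flex_idx] = a_flex
    out[:, ext_idx] = coactivation_floor
    return ActivationTrace(target.times, out), bool(feasible.all())
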