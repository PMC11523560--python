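"""Three-compartment motor-unit fatigue model.

A muscle's motor-unit pool is partitioned into rested (MR), active (MA) and
fatigued (MF) fractions.  A bang-bang drive C moves rested units into the
active pool to track a target load TL (the commanded activation in [0, 1]),
while active units fatigue at rate F and fatigued units recover at rate R:

    dMR/dt = -C(t) + R * MF
    dMA/dt =  C(t) - F * MA
    dMF/dt =  F * MA - R * MF

    C = LD * (TL - MA)   if MA < TL and MR >= TL - MA
    C = LD * MR          if MA < TL and MR <  TL - MA   (rested-limited)
    C = LR * (MA - TL)   if MA >= TL                     (deactivation)

F and R default to 0.00912 and 0.00094 per second, a parameterization for
elbow musculature; with these rates a sustained 80 % load exhausts in
roughly 27 s and the steady-state active fraction under full drive is
R/(F+R) ≈ 0.093.  LD/LR are fast relative to F and R, so their exact values
barely matter; they default to 10 s⁻¹.  Integration is forward Euler.

The fatigued excitation a muscle can express is taken to be MA(t): the
commanded load is the target, the achieved active fraction is the output.
A multiplicative residual-capacity mode (output = TL * (1 - MF)) is kept
behind a flag for sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .elbow import ActivationTrace

__all__ = ["FatigueParams", "FatigueState", "drive", "integrate",
           "integrate_states", "apply_fatigue"]


@dataclass(frozen=True)
class FatigueParams:
    F: float = 0.00912   # fatigue rate, 1/s
    R: float = 0.00094   # recovery rate, 1/s
    LD: float = 10.0     # activation drive rate, 1/s
    LR: float = 10.0     # deactivation drive rate, 1/s

    def __post_init__(self) -> None:
        if min(self.F, self.R, self.LD, self.LR) <= 0:
            raise ValueError("all fatigue rates must be strictly positive")

    @property
    def steady_state_active(self) -> float:
        """Limit of MA under sustained full drive: R / (F + R)."""
        return self.R / (self.F + self.R)


@dataclass(frozen=True)
class FatigueState:
    MR: float
    MA: float
    MF: float

    def __post_init__(self) -> None:
        for name in ("MR", "MA", "MF"):
            v = getattr(self, name)
            if not -1e-9 <= v <= 1 + 1e-9:
                raise ValueError(f"{name} outside [0, 1]: {v}")
        if abs(self.MR + self.MA + self.MF - 1.0) > 1e-9:
            raise ValueError("compartments must sum to 1")


REST = FatigueState(1.0, 0.0, 0.0)


def drive(state: FatigueState, TL: float, params: FatigueParams) -> float:
    """Piecewise motor-unit recruitment drive C (fraction per second).

    Positive when recruiting rested units toward the target load (limited
    by the rested pool), negative when de-recruiting excess active units
    back to rest (MA above target); zero at the target.
    """
    if not 0.0 <= TL <= 1.0:
        raise ValueError("target load TL must lie in [0, 1]")
    gap = TL - state.MA
    if gap > 0:
        if state.MR >= gap:
            return params.LD * gap
        return params.LD * state.MR
    return params.LR * gap


def integrate_states(initial: np.ndarray, TL: np.ndarray,
                     params: FatigueParams, dt: float) -> np.ndarray:
    """Forward-Euler integration, vectorized over independent muscles.

    Parameters
    ----------
    initial : (k, 3) array of [MR, MA, MF] rows.
    TL : (n, k) target-load trajectory, values in [0, 1].
    dt : time step in seconds; requires dt*max(LD, LR) < 1 for stability.

    Returns
    -------
    (n, k, 3) compartment trajectories; element [t] is the state at time
    t*dt after t Euler steps (element [0] is the initial state).
    """
    if dt * max(params.LD, params.LR) >= 1:
        raise ValueError("unstable step: require dt*max(LD, LR) < 1")
    TL = np.asarray(TL, dtype=float)
    if np.any(TL < -1e-12) or np.any(TL > 1 + 1e-12):
        raise ValueError("target loads must lie in [0, 1]")
    n, k = TL.shape
    out = np.empty((n, k, 3))
    MR, MA, MF = (initial[:, i].astype(float).copy() for i in range(3))
    F, R, LD, LR = params.F, params.R, params.LD, params.LR
    for t in range(n):
        out[t, :, 0], out[t, :, 1], out[t, :, 2] = MR, MA, MF
        if t == n - 1:
            break
        tl = TL[t]
        gap = tl - MA
        # recruitment when below target (limited by the rested pool);
        # negative drive (de-recruitment back to rest) when above target
        C = np.where(gap > 0, LD * np.minimum(gap, MR), LR * gap)
        dMR = -C + R * MF
        dMA = C - F * MA
        dMF = F * MA - R * MF
        MR = MR + dt * dMR
        MA = MA + dt * dMA
        MF = MF + dt * dMF
    return out


def integrate(initial: FatigueState, TL_trace: ActivationTrace,
              params: FatigueParams, dt: float | None = None,
              ) -> list[FatigueState]:
    """Integrate one muscle's compartments along a single-channel TL trace."""
    vals = np.asarray(TL_trace.values, dtype=float)
    if vals.ndim != 1:
        raise ValueError("integrate expects a single-channel trace")
    if dt is None:
        dt = float(np.diff(TL_trace.times).mean())
    traj = integrate_states(
        np.array([[initial.MR, initial.MA, initial.MF]]), vals[:, None],
        params, dt)
    return [FatigueState(float(row[0, 0]), float(row[0, 1]), float(row[0, 2]))
            for row in traj]


def apply_fatigue(excitations: ActivationTrace, params: FatigueParams,
                  dt: float = 0.01, mode: str = "active_fraction",
                  ) -> ActivationTrace:
    """Convert pre-fatigue excitations to fatigued excitations per channel.

    Channels are independent muscles starting from rest.  In the default
    ``active_fraction`` mode the output is MA(t); in ``residual_capacity``
    mode it is TL(t) * (1 - MF(t)).
    """
    vals = np.atleast_2d(excitations.values.T).T  # (n, k)
    times = excitations.times
    native_dt = float(np.diff(times).mean()) if len(times) > 1 else dt
    if abs(native_dt - dt) > 1e-9:
        # integrate on the requested grid, then sample back onto the input grid
        fine_t = np.arange(times[0], times[-1] + dt / 2, dt)
        fine_tl = np.column_stack([
            np.interp(fine_t, times, vals[:, j]) for j in range(vals.shape[1])])
    else:
        fine_t, fine_tl = times, vals
    init = np.tile([1.0, 0.0, 0.0], (fine_tl.shape[1], 1))
    traj = integrate_states(init, fine_tl, params, dt)
    if mode == "active_fraction":
        fine_out = traj[:, :, 1]
    elif mode == "residual_capacity":
        fine_out = fine_tl * (1.0 - traj[:, :, 2])
    else:
        raise ValueError(f"unknown fatigue output mode {mode!r}")
    out = np.column_stack([
        np.interp(times, fine_t, fine_out[:, j])
        for j in range(fine_out.shape[1])])
    if excitations.values.ndim == 1:
        out = out[:, 0]
    return ActivationTrace(times, np.clip(out, 0.0, 1.0))
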