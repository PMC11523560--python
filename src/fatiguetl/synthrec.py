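"""Synthetic stand-in for the human recording sessions.

Each session emulates the experimental protocol: three 5 s maximum
voluntary contraction (MVC) plateaus separated by rest, then sustained
elbow flexion at 80 % of the measured MVC torque until the termination rule
fires (torque below 70 % MVC for a cumulative 3 s within the trailing 5 s).

Signal synthesis per muscle:
  * target loads come from the minimum-norm redundancy solve at 80 % MVC on
    a strength-calibrated subject model (flexor forces rescaled so the
    model's strength ceiling equals the subject's MVC torque — the
    subject's "true" strength);
  * loads feed the 3-compartment fatigue model (with per-subject lognormal
    jitter on the fatigue rate to spread time-to-failure across the cohort);
  * achieved torque = forward torque of the fatigued activations plus
    heteroscedastic noise whose SD grows as residual capacity approaches
    the target — torque becomes more variable near task failure;
  * raw EMG = band-limited (20-450 Hz) Gaussian carrier amplitude-modulated
    by the fatigued activation envelope with a slow upward amplitude drift
    (fatigue-related EMG growth — the deliberate "reality gap" versus the
    clean simulated data), plus baseline noise and a DC offset.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import json
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .anthropometry import (GENERIC_ACTUATORS, GROUP_ORDER, ScaledElbowModel,
                            SubjectStatics, scale_model)
from .elbow import ActivationTrace, TorqueTrace, forward_torque, \
    solve_activations
from .fatigue import FatigueParams, integrate_states

__all__ = ["SessionConfig", "Session", "generate_session",
           "apply_termination_rule", "calibrate_strength"]


@dataclass(frozen=True)
class SessionConfig:
    target_fraction: float = 0.80   # of measured MVC torque
    stop_fraction: float = 0.70     # of measured MVC torque
    stop_window: float = 5.0        # s
    stop_count: float = 3.0         # s cumulative below threshold
    emg_rate: float = 3000.0        # Hz
    torque_rate: float = 100.0      # Hz
    mvc_duration: float = 5.0       # s per MVC trial
    max_duration: float = 120.0     # s cap on the sustained task
    # noise model
    mvc_noise_sd: float = 0.02      # multiplicative, on MVC plateaus
    torque_noise_sd: float = 0.015  # multiplicative base SD on task torque
    torque_noise_end_multiplier: float = 8.0  # SD growth near failure
    emg_baseline_sd: float = 0.01   # additive carrier-free noise (a.u.)
    emg_dc_offset: float = 0.05     # a.u.
    emg_drift: float = 0.10         # fractional amplitude growth over task
    emg_envelope_jitter_sd: float = 0.15  # lognormal SD of slow gain wander
    emg_envelope_jitter_cutoff: float = 0.2  # Hz, bandwidth of the wander
    effort_wander_sd: float = 0.05  # lognormal SD of voluntary effort wander
    effort_wander_cutoff: float = 0.15  # Hz
    antagonist_coactivation: float = 0.05  # TRI load during flexion
    rampup_duration: float = 2.0  # s, rise from rest to the target torque
    fatigue_rate_jitter_sd: float = 0.3  # lognormal sigma on F per subject

    def __post_init__(self) -> None:
        if not 0 < self.stop_fraction < self.target_fraction <= 1:
            raise ValueError("require 0 < stop_fraction < target_fraction <= 1")


@dataclass(frozen=True)
class Session:
    statics: SubjectStatics
    emg_rate: float
    emg: np.ndarray                 # (n_emg, 4) raw EMG, a.u.
    torque_rate: float
    torque: np.ndarray              # (n_torque,) achieved torque, N·m
    mvc_trials: tuple[np.ndarray, ...]  # three torque plateaus at torque_rate
    measured_mvc: float             # max over the three MVC plateaus, N·m
    true_activations: np.ndarray    # (n_torque, 4) noiseless fatigued envelope
    true_torque: np.ndarray         # (n_torque,) noiseless achieved torque

    @property
    def duration(self) -> float:
        return len(self.torque) / self.torque_rate


def calibrate_strength(model: ScaledElbowModel, mvc: float) -> ScaledElbowModel:
    """Rescale flexor forces so the strength ceiling equals ``mvc`` (N·m)."""
    if mvc <= 0:
        raise ValueError("mvc must be positive")
    factor = mvc / model.strength_ceiling
    actuators = tuple(
        replace(a, fmax=a.fmax * factor) if a.group != "TRI" else a
        for a in model.actuators)
    return ScaledElbowModel(statics=model.statics, actuators=actuators)


def apply_termination_rule(torque: np.ndarray, rate: float, mvc: float,
                           cfg: SessionConfig = SessionConfig()) -> int:
    """First index where the trailing window holds >= ``stop_count`` seconds
    below ``stop_fraction * mvc``; returns len(torque) if never triggered."""
    torque = np.asarray(torque, dtype=float)
    below = (torque < cfg.stop_fraction * mvc).astype(float)
    w = int(round(cfg.stop_window * rate))
    csum = np.concatenate([[0.0], np.cumsum(below)])
    idx = np.arange(len(torque))
    window_sum = csum[idx + 1] - csum[np.maximum(idx + 1 - w, 0)]
    hits = np.flatnonzero(window_sum / rate >= cfg.stop_count)
    return int(hits[0]) if len(hits) else len(torque)


def _bandlimited_carrier(rng: np.random.Generator, n: int, rate: float,
                         band: tuple[float, float] = (20.0, 450.0)) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to the EMG power band."""
    x = rng.standard_normal(n)
    sos = sps.butter(4, band, btype="bandpass", fs=rate, output="sos")
    y = sps.sosfiltfilt(sos, x)
    return y / y.std()


def _slow_gain_wander(rng: np.random.Generator, n: int, rate: float,
                      sigma: float, cutoff: float) -> np.ndarray:
    """Lognormal multiplicative gain with sub-Hz bandwidth, unit median."""
    if sigma <= 0:
        return np.ones(n)
    # synthesize at a coarse rate to keep the lowpass well-conditioned
    coarse_rate = max(20.0 * cutoff, 4.0)
    n_coarse = max(int(np.ceil(n * coarse_rate / rate)) + 8, 16)
    x = rng.standard_normal(n_coarse)
    sos = sps.butter(2, cutoff, btype="lowpass", fs=coarse_rate, output="sos")
    y = sps.sosfiltfilt(sos, x)
    y = sigma * y / max(y.std(), 1e-12)
    t_c = np.arange(n_coarse) / coarse_rate
    t = np.arange(n) / rate
    return np.exp(np.interp(t, t_c, y))


def generate_session(statics: SubjectStatics, fatigue: FatigueParams,
                     cfg: SessionConfig = SessionConfig(),
                     seed: int = 0) -> Session:
    """Synthesize one subject's full recording session (deterministic per seed)."""
    if statics.mvc_torque <= 0:
        raise ValueError("subject MVC torque must be positive")
    rng = np.random.default_rng(seed)
    dt = 1.0 / cfg.torque_rate
    model = calibrate_strength(scale_model(GENERIC_ACTUATORS, statics),
                               statics.mvc_torque)

    # --- MVC trials: three noisy 5 s plateaus at the true MVC torque;
    # strength is read out as the best plateau mean (sample maxima would
    # inflate the estimate by several percent at this noise level)
    n_mvc = int(round(cfg.mvc_duration * cfg.torque_rate))
    mvc_trials = tuple(
        statics.mvc_torque * (1.0 + cfg.mvc_noise_sd * rng.standard_normal(n_mvc))
        for _ in range(3))
    measured_mvc = float(max(t.mean() for t in mvc_trials))

    # --- sustained task: target loads via redundancy solve at 80 % MVC.
    # Subjects do not hold the target perfectly: exerted effort wanders
    # slowly (sub-Hz, a few percent) around it, which shows up coherently
    # in both the muscle activations (hence EMG) and the achieved torque.
    target = cfg.target_fraction * measured_mvc
    n_task = int(round(cfg.max_duration * cfg.torque_rate))
    times = np.arange(n_task) * dt
    wander = _slow_gain_wander(rng, n_task, cfg.torque_rate,
                               cfg.effort_wander_sd, cfg.effort_wander_cutoff)
    # subjects ramp from rest up to the target under visual feedback, so
    # trials contain a low-torque rise before the sustained hold
    rampup = np.clip(times / max(cfg.rampup_duration, dt), 0.0, 1.0)
    effort = np.minimum(target * wander * rampup, model.strength_ceiling)
    tgt_trace = TorqueTrace(times, effort)
    # unlike the simulations, real flexion shows antagonist (TRI) activity;
    # the flexors compensate its extension torque
    loads, _ = solve_activations(
        model, tgt_trace, coactivation_floor=cfg.antagonist_coactivation)

    # per-subject fatigue-rate jitter spreads time to task failure
    jitter = float(np.exp(cfg.fatigue_rate_jitter_sd * rng.standard_normal()))
    fat = FatigueParams(F=fatigue.F * jitter, R=fatigue.R, LD=fatigue.LD,
                        LR=fatigue.LR)
    init = np.tile([1.0, 0.0, 0.0], (7, 1))
    traj = integrate_states(init, loads.values, fat, dt)
    ma = np.clip(traj[:, :, 1], 0.0, 1.0)           # (n, 7)
    mf = traj[:, :, 2]
    true_torque = forward_torque(model, ActivationTrace(times, ma)).values

    # heteroscedastic torque noise: SD ramps from base to base*multiplier as
    # residual capacity (1 - MF per muscle, weighted into a torque ceiling)
    # approaches the target
    c = np.array([a.torque_capacity for a in model.actuators])
    flex = c > 0
    capacity = (1.0 - mf[:, flex]) @ c[flex]  # residual-capacity torque ceiling
    # quadratic SD ramp in normalized capacity decline, reaching
    # base * multiplier where the noiseless torque crosses the failure
    # threshold (variability is concentrated near task failure)
    stop_level = cfg.stop_fraction * measured_mvc
    crossing = np.flatnonzero(true_torque < stop_level)
    # ignore the ramp-up and recruitment transient when locating failure
    crossing = crossing[crossing > int((cfg.rampup_duration + 1.0)
                                       * cfg.torque_rate)]
    i_fail = int(crossing[0]) if len(crossing) else n_task - 1
    cap0, cap_fail = capacity[0], capacity[i_fail]
    denom = max(cap0 - cap_fail, 1e-9)
    w = np.clip((cap0 - capacity) / denom, 0.0, 1.0) ** 2
    sd = cfg.torque_noise_sd * (1.0 + (cfg.torque_noise_end_multiplier - 1) * w)
    torque = true_torque * (1.0 + sd * rng.standard_normal(n_task))

    # truncate at task failure; the rule applies to the hold phase (the
    # commanded ramp-up would otherwise count toward the below-threshold
    # budget)
    n_ramp = int(round(cfg.rampup_duration * cfg.torque_rate))
    stop = n_ramp + apply_termination_rule(torque[n_ramp:], cfg.torque_rate,
                                           measured_mvc, cfg)
    stop = max(stop, int(5 * cfg.torque_rate))  # never shorter than 5 s
    torque, true_torque, times = torque[:stop], true_torque[:stop], times[:stop]
    ma = ma[:stop]

    # 4-group activation envelope for EMG synthesis (fmax-weighted mean)
    from .simdata import aggregate_groups
    env4 = aggregate_groups(model, ma)

    # --- raw EMG: AM band-limited carrier + drift + slow gain wander +
    # baseline noise + DC.  The wander (lognormal, sub-Hz) emulates the
    # dissociation between surface EMG amplitude and the underlying
    # activation (electrode shift, crosstalk, tissue filtering); unlike a
    # static gain it survives peak normalization and is part of the
    # simulation-to-reality gap.
    n_emg = int(round(stop * cfg.emg_rate / cfg.torque_rate))
    t_emg = np.arange(n_emg) / cfg.emg_rate
    drift = 1.0 + cfg.emg_drift * (t_emg / max(t_emg[-1], 1e-9))
    emg = np.empty((n_emg, len(GROUP_ORDER)))
    for j in range(len(GROUP_ORDER)):
        env = np.interp(t_emg, times, env4[:, j])
        carrier = _bandlimited_carrier(rng, n_emg, cfg.emg_rate)
        gain = _slow_gain_wander(rng, n_emg, cfg.emg_rate,
                                 cfg.emg_envelope_jitter_sd,
                                 cfg.emg_envelope_jitter_cutoff)
        noise = cfg.emg_baseline_sd * rng.standard_normal(n_emg)
        emg[:, j] = env * drift * gain * carrier + noise + cfg.emg_dc_offset

    return Session(statics=statics, emg_rate=cfg.emg_rate, emg=emg,
                   torque_rate=cfg.torque_rate, torque=torque,
                   mvc_trials=mvc_trials, measured_mvc=measured_mvc,
                   true_activations=env4, true_torque=true_torque)


def write_session(session: Session, out_dir: str | Path) -> None:
    """One directory per subject: mvc_*.csv, task_emg.csv, task_torque.csv,
    statics.json."""
    import pandas as pd

    from .emg import RawEMG, raw_emg_to_csv

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, tq in enumerate(session.mvc_trials, start=1):
        pd.DataFrame({
            "t_s": np.arange(len(tq)) / session.torque_rate,
            "torque_Nm": tq,
        }).to_csv(out / f"mvc_{i}.csv", index=False)
    raw_emg_to_csv(RawEMG(session.emg_rate, session.emg), out / "task_emg.csv")
    pd.DataFrame({
        "t_s": np.arange(len(session.torque)) / session.torque_rate,
        "torque_Nm": session.torque,
    }).to_csv(out / "task_torque.csv", index=False)
    s = session.statics
    (out / "statics.json").write_text(json.dumps({
        "subject_id": s.subject_id, "sex": s.sex, "height_m": s.height,
        "mass_kg": s.mass, "mvc_Nm": s.mvc_torque, "forearm_cm": s.forearm_length,
        "elbow_width_cm": s.elbow_width, "upper_arm_cm": s.upper_arm_length,
        "measured_mvc_Nm": session.measured_mvc,
    }, indent=2))
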