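"""Assembly of the simulated pre-training dataset.

Pipeline per (subject, peak-torque) configuration: build the ramp-and-hold
target profile, solve the muscle-redundancy problem for pre-fatigue
excitations, drop configurations whose target exceeds the subject's
strength ceiling (the convergence surrogate), hold the final excitation
vector to 30 s, run the excitations through the fatigue model, evaluate the
forward torque of the fatigued excitations, resample both signals to 300
time instances (10 Hz) and aggregate the 7 actuators into the 4 recorded
muscle groups (BRA, TRI, BIC, BRD).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .anthropometry import (GENERIC_ACTUATORS, GROUP_ORDER, ScaledElbowModel,
                            SubjectStatics, scale_model)
from .elbow import (ActivationTrace, TorqueTarget, TorqueTrace,
                    build_target_profile, forward_torque,
                    solve_activation_matrix)
from .fatigue import FatigueParams, integrate_states

__all__ = ["Trial", "DatasetSplit", "DEFAULT_PEAKS", "N_STEPS",
           "enumerate_configurations", "run_simulation_pipeline",
           "aggregate_groups", "resample_to_grid",
           "trials_to_csv", "trials_from_csv", "write_dataset"]

DEFAULT_PEAKS = tuple(range(30, 100, 10))  # 30..90 N·m in 10 N·m steps
N_STEPS = 300  # 30 s at 10 Hz


@dataclass(frozen=True)
class Trial:
    """One time-aligned training example: 4 activation channels + torque."""

    subject_id: str
    activations: np.ndarray          # (300, 4), channels (BRA, TRI, BIC, BRD)
    torque: np.ndarray               # (300,), N·m
    provenance: str                  # simulated | recorded | synthetic_recorded
    converged: bool = True
    statics: SubjectStatics | None = None
    peak: float | None = None        # target peak for simulated trials, N·m

    def __post_init__(self) -> None:
        a = np.asarray(self.activations, dtype=float)
        t = np.asarray(self.torque, dtype=float)
        object.__setattr__(self, "activations", a)
        object.__setattr__(self, "torque", t)
        if a.shape != (N_STEPS, len(GROUP_ORDER)):
            raise ValueError(f"activations must be {(N_STEPS, 4)}, got {a.shape}")
        if t.shape != (N_STEPS,):
            raise ValueError(f"torque must be ({N_STEPS},), got {t.shape}")
        if np.any(a < -1e-9) or np.any(a > 1 + 1e-9):
            raise ValueError("activations must lie in [0, 1]")
        if self.provenance not in ("simulated", "recorded", "synthetic_recorded"):
            raise ValueError(f"unknown provenance {self.provenance!r}")

    @property
    def times(self) -> np.ndarray:
        return np.linspace(0.0, 30.0, N_STEPS)


@dataclass(frozen=True)
class DatasetSplit:
    train_subjects: tuple[str, ...]
    leaveout_subjects: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.train_subjects) & set(self.leaveout_subjects):
            raise ValueError("train and leave-out subjects must be disjoint")


def enumerate_configurations(cohort: list[SubjectStatics],
                             peaks: tuple[float, ...] = DEFAULT_PEAKS,
                             ) -> list[tuple[SubjectStatics, TorqueTarget]]:
    """Cartesian product subjects × peak torques, subject-major order."""
    if not cohort:
        raise ValueError("cohort must be non-empty")
    if not peaks:
        raise ValueError("peaks must be non-empty")
    return [(s, TorqueTarget(peak=float(p))) for s in cohort for p in peaks]


def resample_to_grid(times: np.ndarray, values: np.ndarray,
                     n_points: int = N_STEPS) -> tuple[np.ndarray, np.ndarray]:
    """Linear interpolation onto n_points equally spaced samples (inclusive)."""
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    times = np.asarray(times, dtype=float)
    if len(times) < 2:
        raise ValueError("trace must have at least 2 samples")
    new_t = np.linspace(times[0], times[-1], n_points)
    vals = np.asarray(values, dtype=float)
    if vals.ndim == 1:
        return new_t, np.interp(new_t, times, vals)
    out = np.column_stack([np.interp(new_t, times, vals[:, j])
                           for j in range(vals.shape[1])])
    return new_t, out


def aggregate_groups(model: ScaledElbowModel, act7: np.ndarray) -> np.ndarray:
    """Collapse 7 actuator channels to the 4 muscle groups.

    Per group the fmax-weighted mean of member activations (single-member
    groups pass through); column order (BRA, TRI, BIC, BRD).
    """
    act7 = np.asarray(act7, dtype=float)
    if act7.shape[1] != len(model.actuators):
        raise ValueError("expected one column per actuator")
    cols = []
    for g in GROUP_ORDER:
        idx = [i for i, a in enumerate(model.actuators) if a.group == g]
        if not idx:
            raise ValueError(f"no actuators labelled {g}")
        w = np.array([model.actuators[i].fmax for i in idx])
        cols.append(act7[:, idx] @ (w / w.sum()))
    return np.column_stack(cols)


def run_simulation_pipeline(configs: list[tuple[SubjectStatics, TorqueTarget]],
                            fatigue: FatigueParams = FatigueParams(),
                            dt: float = 0.01,
                            coactivation_floor: float = 0.0,
                            n_steps: int = N_STEPS) -> list[Trial]:
    """Run every configuration through the full simulation chain.

    Only converged (feasible) configurations yield trials.  All trials are
    integrated in one batched Euler pass for speed; the computation is
    deterministic, so identical configs reproduce identical trials.
    """
    if not configs:
        return []
    # group configs by subject so each model is scaled once
    entries = []  # (subject, model, target, excitation (n,7)) for feasible
    for statics, target in configs:
        model = scale_model(GENERIC_ACTUATORS, statics)
        profile = build_target_profile(target, dt)
        flex_idx = [i for i, a in enumerate(model.actuators) if a.group != "TRI"]
        ext_idx = [i for i, a in enumerate(model.actuators) if a.group == "TRI"]
        c_flex = np.array([model.actuators[i].torque_capacity for i in flex_idx])
        c_ext = np.array([model.actuators[i].torque_capacity for i in ext_idx])
        eff = profile.values - coactivation_floor * c_ext.sum()
        a_flex, feasible = solve_activation_matrix(c_flex, eff)
        if not feasible.all():
            continue
        exc = np.zeros((len(profile.values), 7))
        exc[:, flex_idx] = a_flex
        exc[:, ext_idx] = coactivation_floor
        # hold the final pre-fatigue excitation vector out to the full length
        ramp_end = target.ramp_duration + target.plateau_duration
        hold_from = int(round(ramp_end / dt))
        exc[hold_from:] = exc[min(hold_from, len(exc) - 1)]
        entries.append((statics, model, target, profile.times, exc))
    if not entries:
        return []
    # one batched fatigue integration across all trials x 7 muscles; muscles
    # start already holding the ramp-start load (MA(0) = TL(0)), since the
    # trial begins mid-contraction at the 10 N·m ramp start
    tl = np.concatenate([e[4] for e in entries], axis=1)  # (n_t, 7*m)
    tl0 = tl[0]
    init = np.column_stack([1.0 - tl0, tl0, np.zeros_like(tl0)])
    ma = integrate_states(init, tl, fatigue, dt)[:, :, 1]  # (n_t, 7*m)
    trials = []
    for j, (statics, model, target, times, _) in enumerate(entries):
        fatigued = np.clip(ma[:, 7 * j:7 * (j + 1)], 0.0, 1.0)
        torque = forward_torque(model, ActivationTrace(times, fatigued)).values
        _, act4 = resample_to_grid(times, aggregate_groups(model, fatigued),
                                   n_steps)
        _, tq = resample_to_grid(times, torque, n_steps)
        trials.append(Trial(
            subject_id=statics.subject_id,
            activations=np.clip(act4, 0.0, 1.0), torque=tq,
            provenance="simulated", converged=True, statics=statics,
            peak=target.peak))
    return trials


# ---------------------------------------------------------------------------
# serialization

def trials_to_csv(trials: list[Trial], path: str | Path) -> None:
    """Long-format trial table: trial_id, step, t_s, bra, tri, bic, brd, torque_Nm."""
    frames = []
    for i, tr in enumerate(trials):
        df = pd.DataFrame(tr.activations, columns=["bra", "tri", "bic", "brd"])
        df.insert(0, "t_s", tr.times)
        df.insert(0, "step", np.arange(N_STEPS))
        df.insert(0, "trial_id", f"{tr.subject_id}_p{tr.peak or 0:g}_{i}")
        df["torque_Nm"] = tr.torque
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def trials_from_csv(path: str | Path, provenance: str = "simulated",
                    ) -> list[Trial]:
    df = pd.read_csv(path)
    trials = []
    for tid, g in df.groupby("trial_id", sort=False):
        g = g.sort_values("step")
        trials.append(Trial(
            subject_id=str(tid).rsplit("_p", 1)[0],
            activations=g[["bra", "tri", "bic", "brd"]].to_numpy(),
            torque=g["torque_Nm"].to_numpy(), provenance=provenance))
    return trials


def config_hash(obj) -> str:
    """Stable short hash of any JSON-serializable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_dataset(trials: list[Trial], cohort: list[SubjectStatics],
                  out_dir: str | Path, seed: int, config: dict,
                  n_configurations: int | None = None) -> dict:
    """Write trials.csv, subjects.csv and manifest.json; return the manifest."""
    from .anthropometry import cohort_to_csv

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    trials_to_csv(trials, out / "trials.csv")
    cohort_to_csv(cohort, out / "subjects.csv")
    manifest = {
        "n_trials": len(trials),
        "n_subjects": len(cohort),
        "n_configurations": n_configurations if n_configurations is not None
        else len(trials),
        "seed": seed,
        "config_hash": config_hash(config),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
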