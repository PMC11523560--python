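"""Leave-out evaluation of the three prediction approaches.

Compares the transfer-learning model, the direct-learning model, and the
physics-based forward-simulation baseline on held-out subjects.  Errors are
pooled over all time steps of all leave-out trials (per-subject values are
also emitted); prediction smoothness is summarized by the SD of predictions
versus the SD of the actual torque; parity pairs support predicted-vs-actual
scatter.  Dataset distributions are summarized with Tukey boxplot
statistics (fences at 1.5 IQR, linear-interpolation quantiles).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .anthropometry import GROUP_ORDER, scale_model, GENERIC_ACTUATORS
from .elbow import ActivationTrace, forward_torque
from .emg import prepare_for_simulation
from .simdata import DatasetSplit, N_STEPS, Trial

__all__ = ["ApproachResult", "EvalReport", "rmse_mae", "make_split",
           "simulation_baseline", "evaluate_three_way", "distribution_summary"]


def rmse_mae(actual: np.ndarray, predicted: np.ndarray) -> tuple[float, float]:
    """Root-mean-square and mean-absolute error of a prediction vector."""
    a = np.asarray(actual, dtype=float).ravel()
    p = np.asarray(predicted, dtype=float).ravel()
    if a.shape != p.shape:
        raise ValueError("actual and predicted must have equal length")
    if a.size == 0:
        raise ValueError("empty inputs")
    err = a - p
    return float(np.sqrt(np.mean(err ** 2))), float(np.mean(np.abs(err)))


def make_split(subject_ids: list[str], n_leaveout: int = 5,
               seed: int = 0) -> DatasetSplit:
    """Seeded uniform leave-out split over subjects."""
    ids = list(dict.fromkeys(subject_ids))  # stable unique
    if not 0 <= n_leaveout < len(ids):
        raise ValueError("n_leaveout must be < number of subjects")
    rng = np.random.default_rng(seed)
    held = set(rng.choice(len(ids), size=n_leaveout, replace=False).tolist())
    return DatasetSplit(
        train_subjects=tuple(s for i, s in enumerate(ids) if i not in held),
        leaveout_subjects=tuple(s for i, s in enumerate(ids) if i in held))


@dataclass
class ApproachResult:
    rmse: float
    mae: float
    prediction_sd: float
    per_subject: dict[str, dict[str, float]]

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class EvalReport:
    approaches: dict[str, ApproachResult]
    actual_sd: float
    actual_mean: float
    split: DatasetSplit
    parity: pd.DataFrame = field(repr=False)  # subject, approach, actual, predicted

    def to_json(self, path: str | Path | None = None) -> dict:
        out = {
            "actual_sd_Nm": self.actual_sd,
            "actual_mean_Nm": self.actual_mean,
            "train_subjects": list(self.split.train_subjects),
            "leaveout_subjects": list(self.split.leaveout_subjects),
            "approaches": {k: v.to_dict() for k, v in self.approaches.items()},
        }
        if path is not None:
            Path(path).write_text(json.dumps(out, indent=2))
        return out


def simulation_baseline(leaveout: list[Trial], window: int = 25,
                        ) -> np.ndarray:
    """Physics-based predictions for leave-out trials.

    Per subject: scale the generic elbow model anthropometrically (no
    strength calibration — the generic model does not know the subject's
    true strength), smooth the processed activations with a moving average,
    and evaluate the isometric forward torque.
    """
    preds = np.empty((len(leaveout), N_STEPS))
    for i, tr in enumerate(leaveout):
        if tr.statics is None:
            raise ValueError("baseline requires trial statics")
        model = scale_model(GENERIC_ACTUATORS, tr.statics)
        act = prepare_for_simulation(tr.activations, window=window)
        preds[i] = forward_torque(model,
                                  ActivationTrace(tr.times, act)).values
    return preds


def _summarize(leaveout: list[Trial], preds: np.ndarray,
               ) -> tuple[ApproachResult, pd.DataFrame]:
    actual = np.stack([t.torque for t in leaveout])
    rmse, mae = rmse_mae(actual, preds)
    per_subject = {}
    frames = []
    for i, tr in enumerate(leaveout):
        r, m = rmse_mae(actual[i], preds[i])
        per_subject[tr.subject_id] = {"rmse": r, "mae": m}
        frames.append(pd.DataFrame({
            "subject_id": tr.subject_id, "actual_Nm": actual[i],
            "predicted_Nm": preds[i]}))
    res = ApproachResult(rmse=rmse, mae=mae,
                         prediction_sd=float(np.std(preds)),
                         per_subject=per_subject)
    return res, pd.concat(frames, ignore_index=True)


def evaluate_predictions(transfer_preds: np.ndarray, direct_preds: np.ndarray,
                         baseline_preds: np.ndarray, leaveout: list[Trial],
                         split: DatasetSplit) -> EvalReport:
    """Assemble the three-approach leave-out report from aligned predictions.

    Pure given its inputs (bit-identical on regeneration).  All prediction
    arrays must be (n_leaveout, 300) on the leave-out trials' time grids.
    """
    n = (len(leaveout), N_STEPS)
    for name, p in (("transfer", transfer_preds), ("direct", direct_preds),
                    ("simulation", baseline_preds)):
        if p.shape != n:
            raise ValueError(f"{name} predictions misaligned: {p.shape} != {n}")
    actual = np.stack([t.torque for t in leaveout])
    approaches = {}
    parity_frames = []
    for name, p in (("transfer", transfer_preds), ("direct", direct_preds),
                    ("simulation", baseline_preds)):
        res, parity = _summarize(leaveout, p)
        approaches[name] = res
        parity["approach"] = name
        parity_frames.append(parity)
    return EvalReport(approaches=approaches,
                      actual_sd=float(np.std(actual)),
                      actual_mean=float(np.mean(actual)),
                      split=split,
                      parity=pd.concat(parity_frames, ignore_index=True))


def evaluate_three_way(transfer_model, direct_model, leaveout: list[Trial],
                       split: DatasetSplit,
                       baseline_window: int = 25) -> EvalReport:
    """Run all three approaches on the leave-out trials and summarize.

    ``transfer_model`` and ``direct_model`` are trained ``ModelHandle``s;
    the simulation baseline is computed from each leave-out subject's
    anthropometrically scaled model and smoothed activations.
    """
    from .training import predict

    return evaluate_predictions(
        predict(transfer_model, leaveout), predict(direct_model, leaveout),
        simulation_baseline(leaveout, window=baseline_window),
        leaveout, split)


def distribution_summary(trials: list[Trial]) -> pd.DataFrame:
    """Tukey boxplot statistics per activation channel and for torque.

    Quantiles use linear interpolation between order statistics; outliers
    fall outside [Q1 - 1.5 IQR, Q3 + 1.5 IQR].
    """
    if not trials:
        raise ValueError("empty dataset")
    columns = {g.lower(): np.concatenate([t.activations[:, i] for t in trials])
               for i, g in enumerate(GROUP_ORDER)}
    columns["torque_Nm"] = np.concatenate([t.torque for t in trials])
    rows = []
    for name, vals in columns.items():
        q1, q2, q3 = np.quantile(vals, [0.25, 0.5, 0.75], method="linear")
        iqr = q3 - q1
        lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        n_out = int(np.sum((vals < lo) | (vals > hi)))
        rows.append({"channel": name, "q1": q1, "median": q2, "q3": q3,
                     "iqr": iqr, "fence_low": lo, "fence_high": hi,
                     "n": len(vals), "n_outliers": n_out,
                     "outlier_fraction": n_out / len(vals)})
    return pd.DataFrame(rows)
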