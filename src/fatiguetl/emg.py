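"""Surface/fine-wire EMG processing and forward-simulation preparation.

Envelope chain (per channel): mean-subtract, 4th-order Butterworth bandpass
10-500 Hz (zero-phase), full-wave rectify, 4th-order Butterworth lowpass
5 Hz (zero-phase), 0.5 s median filter for outlier removal, normalize by
the subject's peak activation across trials, clip to [0, 1], linear
interpolation onto 300 time instances.

For the physics-based baseline the normalized activations are additionally
smoothed with a centered moving average; the window (default 25 samples) can
be screened with a sum-of-absolute-differences (SAD) sweep over candidate
windows 5..50.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .anthropometry import GROUP_ORDER
from .simdata import resample_to_grid

__all__ = ["RawEMG", "EnvelopeSettings", "median_window_samples",
           "process_emg", "select_smoothing_window", "prepare_for_simulation"]


@dataclass(frozen=True)
class RawEMG:
    """Multi-channel raw EMG block, channels in (BRA, TRI, BIC, BRD) order."""

    rate: float                 # Hz
    signals: np.ndarray         # (n, 4), arbitrary units

    def __post_init__(self) -> None:
        s = np.atleast_2d(np.asarray(self.signals, dtype=float).T).T
        object.__setattr__(self, "signals", s)
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    @property
    def duration(self) -> float:
        return self.signals.shape[0] / self.rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.signals.shape[0]) / self.rate


@dataclass(frozen=True)
class EnvelopeSettings:
    bandpass: tuple[float, float] = (10.0, 500.0)  # Hz
    bandpass_order: int = 4
    lowpass: float = 5.0                           # Hz
    lowpass_order: int = 4
    median_window_s: float = 0.5                   # s
    output_steps: int = 300

    def validate(self, rate: float) -> None:
        lo, hi = self.bandpass
        if not 0 < lo < hi < rate / 2:
            raise ValueError("bandpass cutoffs must satisfy 0 < lo < hi < rate/2")
        if not 0 < self.lowpass < rate / 2:
            raise ValueError("lowpass cutoff must lie below Nyquist")


def median_window_samples(window_s: float, rate: float) -> int:
    """Largest odd sample count not exceeding ``window_s`` at ``rate``.

    The canonical case: a 0.5 s window at 3000 Hz is 1499 samples.
    """
    n = int(np.floor(window_s * rate))
    if n < 1:
        raise ValueError("window shorter than one sample")
    return n if n % 2 == 1 else n - 1


def _envelope(x: np.ndarray, rate: float, settings: EnvelopeSettings,
              ) -> np.ndarray:
    """Unnormalized envelope of one channel (all steps before scaling)."""
    x = x - x.mean()
    sos_bp = signal.butter(settings.bandpass_order, settings.bandpass,
                           btype="bandpass", fs=rate, output="sos")
    x = signal.sosfiltfilt(sos_bp, x)
    x = np.abs(x)
    sos_lp = signal.butter(settings.lowpass_order, settings.lowpass,
                           btype="lowpass", fs=rate, output="sos")
    x = signal.sosfiltfilt(sos_lp, x)
    w = median_window_samples(settings.median_window_s, rate)
    if len(x) <= w:
        raise ValueError("signal shorter than the median-filter window")
    return ndimage.median_filter(x, size=w, mode="reflect")


def process_emg(raw: RawEMG, settings: EnvelopeSettings = EnvelopeSettings(),
                subject_peak: np.ndarray | None = None,
                ) -> tuple[np.ndarray, np.ndarray]:
    """Full envelope chain for all 4 channels.

    ``subject_peak`` holds the per-channel peak envelope across all of the
    subject's trials; when None the peaks of this trial are used (the
    single-trial case, where the trial defines its own peak).

    Returns (times, activations) with activations of shape
    (output_steps, 4), values in [0, 1].
    """
    settings.validate(raw.rate)
    env = np.column_stack([_envelope(raw.signals[:, j], raw.rate, settings)
                           for j in range(raw.signals.shape[1])])
    if subject_peak is None:
        subject_peak = env.max(axis=0)
    subject_peak = np.asarray(subject_peak, dtype=float)
    if np.any(subject_peak <= 0):
        raise ValueError("subject peaks must be strictly positive")
    env = np.clip(env / subject_peak, 0.0, 1.0)
    return resample_to_grid(raw.times, env, settings.output_steps)


def envelope_peaks(raw: RawEMG,
                   settings: EnvelopeSettings = EnvelopeSettings(),
                   ) -> np.ndarray:
    """Per-channel peak of the unnormalized envelope (for cross-trial scaling)."""
    settings.validate(raw.rate)
    return np.array([_envelope(raw.signals[:, j], raw.rate, settings).max()
                     for j in range(raw.signals.shape[1])])


DEFAULT_SAD_CANDIDATES = tuple(range(5, 55, 5))


def select_smoothing_window(x: np.ndarray,
                            candidates: tuple[int, ...] = DEFAULT_SAD_CANDIDATES,
                            default: int = 25,
                            rel_tol: float = 0.05,
                            ) -> tuple[int, pd.DataFrame]:
    """Screen moving-average windows by sum of absolute differences (SAD).

    Computes SAD of the smoothed signal for each candidate window.  Returns
    ``default`` unless diminishing returns (relative SAD drop below
    ``rel_tol`` between consecutive candidates) set in at a smaller window,
    in which case that window is returned.  The SAD table is returned for
    visualization.
    """
    x = np.asarray(x, dtype=float)
    if not candidates:
        raise ValueError("candidates must be non-empty")
    if max(candidates) >= len(x):
        raise ValueError("candidate window not smaller than the signal")
    sads = [float(np.abs(np.diff(
        ndimage.uniform_filter1d(x, size=int(w), mode="reflect"))).sum())
        for w in candidates]
    table = pd.DataFrame({"window": list(candidates), "sad": sads})
    if sads[0] == 0.0:
        return int(candidates[0]), table
    chosen = default
    for k in range(1, len(candidates)):
        drop = (sads[k - 1] - sads[k]) / sads[k - 1]
        if drop < rel_tol and candidates[k] < default:
            chosen = int(candidates[k])
            break
        if candidates[k] >= default:
            break
    return chosen, table


def prepare_for_simulation(act: np.ndarray, window: int = 25) -> np.ndarray:
    """Centered moving average (reflect padding) applied per channel."""
    if window < 1:
        raise ValueError("window must be >= 1")
    act = np.asarray(act, dtype=float)
    out = ndimage.uniform_filter1d(act, size=int(window), axis=0, mode="reflect")
    return np.clip(out, 0.0, 1.0)


def raw_emg_to_csv(raw: RawEMG, path) -> None:
    """CSV with a `# rate_hz=` header comment, columns t_s + group channels."""
    df = pd.DataFrame(raw.signals, columns=[g.lower() for g in GROUP_ORDER])
    df.insert(0, "t_s", raw.times)
    with open(path, "w") as fh:
        fh.write(f"# rate_hz={raw.rate:g}\n")
        df.to_csv(fh, index=False)


def raw_emg_from_csv(path) -> RawEMG:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# rate_hz="):
            raise ValueError("missing rate header comment")
        rate = float(header.split("=", 1)[1])
        df = pd.read_csv(fh)
    return RawEMG(rate, df[[g.lower() for g in GROUP_ORDER]].to_numpy())
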