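"""Sequence network numerics: stacked LSTM backbone + feedforward head.

Implemented directly on numpy: forward pass, full backpropagation through
time, and Adam with (coupled) weight decay.  The architecture mirrors the
study design: muscle-activation sequences enter a stack of unidirectional
LSTM layers; at every time step the top hidden state is concatenated with
an encoded static-feature vector and passed through a shared (per-step)
ReLU feedforward stack ending in one torque output, giving a full torque
sequence per trial.  During pre-training a temporary linear readout
replaces the feedforward head.

Gradient correctness is enforced by finite-difference checks in the test
suite; layer freezing works by excluding parameters from the optimizer and
(for speed) truncating backpropagation below the lowest trainable layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ArchConfig", "SeqTorqueNet", "Adam", "mse_loss"]


@dataclass(frozen=True)
class ArchConfig:
    lstm_layers: int = 3
    lstm_width: int = 24
    ff_layers: int = 2
    ff_width: int = 23
    unfrozen_backend_layers: int = 0  # counted from the top of the stack

    def __post_init__(self) -> None:
        if min(self.lstm_layers, self.lstm_width, self.ff_layers,
               self.ff_width) < 1:
            raise ValueError("widths and layer counts must be >= 1")
        if self.unfrozen_backend_layers not in (0, 1, 2):
            raise ValueError("unfrozen_backend_layers must be 0, 1 or 2")
        if self.unfrozen_backend_layers > self.lstm_layers:
            raise ValueError("cannot unfreeze more layers than exist")

    @property
    def n_parameters_per_trial_step(self) -> int:  # proxy for tie-breaking
        return self.lstm_layers * self.lstm_width + self.ff_layers * self.ff_width


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


class SeqTorqueNet:
    """Stacked-LSTM sequence regressor with a per-step feedforward head.

    Parameters are a flat ``dict[str, np.ndarray]``; LSTM gate order is
    (input, forget, cell, output).  ``head="linear"`` builds the temporary
    pre-training readout (no static features); ``head="mlp"`` builds the
    full static-feature head.
    """

    def __init__(self, arch: ArchConfig, n_channels: int = 4,
                 n_static: int = 7, head: str = "mlp", seed: int = 0):
        if head not in ("mlp", "linear"):
            raise ValueError("head must be 'mlp' or 'linear'")
        self.arch = arch
        self.n_channels = n_channels
        self.n_static = n_static if head == "mlp" else 0
        self.head = head
        self.params: dict[str, np.ndarray] = {}
        rng = np.random.default_rng(seed)
        H = arch.lstm_width
        k = 1.0 / np.sqrt(H)
        d_in = n_channels
        for l in range(arch.lstm_layers):
            self.params[f"lstm{l}_Wx"] = rng.uniform(-k, k, (4 * H, d_in))
            self.params[f"lstm{l}_Wh"] = rng.uniform(-k, k, (4 * H, H))
            self.params[f"lstm{l}_b"] = rng.uniform(-k, k, 4 * H)
            d_in = H
        if head == "linear":
            self.params["out_W"] = rng.uniform(-k, k, (1, H))
            self.params["out_b"] = np.zeros(1)
        else:
            d = H + self.n_static
            for j in range(arch.ff_layers):
                kj = 1.0 / np.sqrt(d)
                self.params[f"ff{j}_W"] = rng.uniform(-kj, kj, (arch.ff_width, d))
                self.params[f"ff{j}_b"] = rng.uniform(-kj, kj, arch.ff_width)
                d = arch.ff_width
            kj = 1.0 / np.sqrt(d)
            self.params["out_W"] = rng.uniform(-kj, kj, (1, d))
            self.params["out_b"] = np.zeros(1)
        self._cache = None

    # -- parameter bookkeeping -------------------------------------------
    def lstm_param_names(self, layer: int) -> list[str]:
        return [f"lstm{layer}_{p}" for p in ("Wx", "Wh", "b")]

    def trainable_names(self, frozen_lstm_layers: set[int] = frozenset(),
                        ) -> list[str]:
        names = []
        for l in range(self.arch.lstm_layers):
            if l not in frozen_lstm_layers:
                names.extend(self.lstm_param_names(l))
        names.extend(n for n in self.params
                     if not n.startswith("lstm"))
        return names

    # -- forward ----------------------------------------------------------
    def forward(self, X: np.ndarray, S: np.ndarray | None = None,
                keep_cache: bool = True) -> np.ndarray:
        """Predict torque sequences.

        X : (B, T, n_channels) activation sequences.
        S : (B, n_static) encoded static features (mlp head only).
        Returns (B, T) torque predictions.
        """
        X = np.asarray(X, dtype=float)
        B, T, C = X.shape
        if C != self.n_channels:
            raise ValueError(f"expected {self.n_channels} channels, got {C}")
        if self.head == "mlp":
            if self.n_static and (S is None or S.shape != (B, self.n_static)):
                raise ValueError("static feature matrix of shape "
                                 f"({B}, {self.n_static}) required")
        H = self.arch.lstm_width
        caches = []
        inp = X
        for l in range(self.arch.lstm_layers):
            Wx = self.params[f"lstm{l}_Wx"]
            Wh = self.params[f"lstm{l}_Wh"]
            b = self.params[f"lstm{l}_b"]
            # pre-compute input contributions for all steps at once
            ZX = np.einsum("btc,gc->btg", inp, Wx) + b
            h = np.zeros((B, H))
            c = np.zeros((B, H))
            I = np.empty((B, T, H)); F = np.empty((B, T, H))
            G = np.empty((B, T, H)); O = np.empty((B, T, H))
            Cc = np.empty((B, T, H)); Th = np.empty((B, T, H))
            Hs = np.empty((B, T, H))
            for t in range(T):
                z = ZX[:, t] + h @ Wh.T
                i = _sigmoid(z[:, :H])
                f = _sigmoid(z[:, H:2 * H])
                g = np.tanh(z[:, 2 * H:3 * H])
                o = _sigmoid(z[:, 3 * H:])
                c = f * c + i * g
                tc = np.tanh(c)
                h = o * tc
                I[:, t], F[:, t], G[:, t], O[:, t] = i, f, g, o
                Cc[:, t], Th[:, t], Hs[:, t] = c, tc, h
            caches.append(dict(inp=inp, I=I, F=F, G=G, O=O, Cc=Cc, Th=Th,
                               Hs=Hs))
            inp = Hs
        Htop = inp  # (B, T, H)
        if self.head == "linear":
            preds = np.einsum("bth,oh->bto", Htop, self.params["out_W"])[..., 0] \
                + self.params["out_b"][0]
            head_cache = {"z": Htop.reshape(B * T, H)}
        else:
            z = Htop.reshape(B * T, H)
            if self.n_static:
                z = np.concatenate(
                    [z, np.repeat(S, T, axis=0).reshape(B * T, self.n_static)],
                    axis=1)
            head_cache = {"acts": [z]}
            for j in range(self.arch.ff_layers):
                z = z @ self.params[f"ff{j}_W"].T + self.params[f"ff{j}_b"]
                z = np.maximum(z, 0.0)
                head_cache["acts"].append(z)
            preds = (z @ self.params["out_W"].T + self.params["out_b"]
                     ).reshape(B, T)
        if keep_cache:
            self._cache = dict(X=X, S=S, lstm=caches, head=head_cache,
                               shape=(B, T))
        return preds

    # -- backward ---------------------------------------------------------
    def backward(self, dpreds: np.ndarray,
                 lowest_trainable_layer: int = 0) -> dict[str, np.ndarray]:
        """Gradients w.r.t. all parameters given d(loss)/d(preds) (B, T).

        Backpropagation through LSTM layers stops below
        ``lowest_trainable_layer`` (their gradients are returned as absent),
        which is exact when those layers are frozen.
        """
        if self._cache is None:
            raise RuntimeError("forward(..., keep_cache=True) must run first")
        B, T = self._cache["shape"]
        H = self.arch.lstm_width
        grads: dict[str, np.ndarray] = {}
        dflat = np.asarray(dpreds, dtype=float).reshape(B * T, 1)
        if self.head == "linear":
            z = self._cache["head"]["z"]
            grads["out_W"] = dflat.T @ z
            grads["out_b"] = dflat.sum(axis=0)
            dz = (dflat @ self.params["out_W"])
            dHtop = dz.reshape(B, T, H)
        else:
            acts = self._cache["head"]["acts"]
            dz = dflat
            grads["out_W"] = dz.T @ acts[-1]
            grads["out_b"] = dz.sum(axis=0)
            dz = dz @ self.params["out_W"]
            for j in range(self.arch.ff_layers - 1, -1, -1):
                dz = dz * (acts[j + 1] > 0)
                grads[f"ff{j}_W"] = dz.T @ acts[j]
                grads[f"ff{j}_b"] = dz.sum(axis=0)
                dz = dz @ self.params[f"ff{j}_W"]
            dHtop = dz[:, :H].reshape(B, T, H)  # static-feature grads unused
        dH = dHtop
        for l in range(self.arch.lstm_layers - 1, lowest_trainable_layer - 1, -1):
            cache = self._cache["lstm"][l]
            Wx = self.params[f"lstm{l}_Wx"]
            Wh = self.params[f"lstm{l}_Wh"]
            inp = cache["inp"]
            I, F, G, O = cache["I"], cache["F"], cache["G"], cache["O"]
            Cc, Th, Hs = cache["Cc"], cache["Th"], cache["Hs"]
            dWx = np.zeros_like(Wx)
            dWh = np.zeros_like(Wh)
            db = np.zeros(4 * H)
            dInp = np.empty_like(inp)
            dh_next = np.zeros((B, H))
            dc_next = np.zeros((B, H))
            for t in range(T - 1, -1, -1):
                dh = dH[:, t] + dh_next
                tc = Th[:, t]
                do = dh * tc
                dc = dc_next + dh * O[:, t] * (1.0 - tc * tc)
                di = dc * G[:, t]
                dg = dc * I[:, t]
                c_prev = Cc[:, t - 1] if t > 0 else np.zeros((B, H))
                df = dc * c_prev
                dc_next = dc * F[:, t]
                dz = np.concatenate([
                    di * I[:, t] * (1 - I[:, t]),
                    df * F[:, t] * (1 - F[:, t]),
                    dg * (1 - G[:, t] ** 2),
                    do * O[:, t] * (1 - O[:, t]),
                ], axis=1)
                h_prev = Hs[:, t - 1] if t > 0 else np.zeros((B, H))
                dWx += dz.T @ inp[:, t]
                dWh += dz.T @ h_prev
                db += dz.sum(axis=0)
                dInp[:, t] = dz @ Wx
                dh_next = dz @ Wh
            grads[f"lstm{l}_Wx"] = dWx
            grads[f"lstm{l}_Wh"] = dWh
            grads[f"lstm{l}_b"] = db
            dH = dInp
        return grads


def mse_loss(preds: np.ndarray, targets: np.ndarray,
             ) -> tuple[float, np.ndarray]:
    """Mean squared error over all elements and its gradient w.r.t. preds."""
    diff = preds - targets
    loss = float(np.mean(diff ** 2))
    return loss, 2.0 * diff / diff.size


class Adam:
    """Adam with coupled weight decay (L2 added to the gradient)."""

    def __init__(self, params: dict[str, np.ndarray], names: list[str],
                 lr: float, weight_decay: float = 0.0,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8):
        self.params = params
        self.names = list(names)
        self.lr = lr
        self.wd = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {n: np.zeros_like(params[n]) for n in self.names}
        self.v = {n: np.zeros_like(params[n]) for n in self.names}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for n in self.names:
            g = grads[n] + self.wd * self.params[n]
            self.m[n] = self.b1 * self.m[n] + (1 - self.b1) * g
            self.v[n] = self.b2 * self.v[n] + (1 - self.b2) * g * g
            self.params[n] -= self.lr * (self.m[n] / b1t) / (
                np.sqrt(self.v[n] / b2t) + self.eps)
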