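"""Direct- and transfer-learning training regimes.

Direct learning trains the full sequence network (LSTM backbone + static
feature head) from scratch on recorded-style trials.  Transfer learning
first pre-trains the backbone on the simulated dataset with a temporary
linear readout (activations → torque, no statics), then freezes the
backbone except the last 0-2 layers, attaches a fresh feedforward head and
fine-tunes on recorded-style trials.  Hyperparameters can be chosen by
random search under subject-wise 5-fold cross-validation.

Torque targets are trained in raw newton-meters; static features are
encoded as sex∈{0,1} plus six z-scored body measures, standardized on
training subjects only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .nnet import Adam, ArchConfig, SeqTorqueNet, mse_loss
from .simdata import Trial

__all__ = ["TrainConfig", "SearchSpace", "StaticScaler", "ModelHandle",
           "DIRECT_ARCH", "TRANSFER_ARCH", "DIRECT_TRAIN", "TRANSFER_TRAIN",
           "build_model", "pretrain_backbone", "finetune_transfer",
           "train_direct", "predict", "random_search", "trials_to_arrays"]

# Published final architectures/hyperparameters of the two regimes
DIRECT_ARCH = ArchConfig(lstm_layers=3, lstm_width=24, ff_layers=2,
                         ff_width=23, unfrozen_backend_layers=0)
TRANSFER_ARCH = ArchConfig(lstm_layers=3, lstm_width=24, ff_layers=2,
                           ff_width=18, unfrozen_backend_layers=2)


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 6.4e-3
    weight_decay: float = 4.5e-2
    epochs: int = 300
    batch_size: int = 4
    seed: int = 0
    early_stop_patience: int = 30  # used only when a validation set is given

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.weight_decay <= 0:
            raise ValueError("learning_rate and weight_decay must be > 0")


DIRECT_TRAIN = TrainConfig(learning_rate=6.4e-3, weight_decay=4.5e-2)
TRANSFER_TRAIN = TrainConfig(learning_rate=9.0e-3, weight_decay=9.4e-2)


@dataclass(frozen=True)
class SearchSpace:
    lr_range: tuple[float, float] = (1e-4, 1e-1)        # log-uniform
    wd_range: tuple[float, float] = (1e-4, 1.0)         # log-uniform
    widths: tuple[int, ...] = (8, 16, 24, 32, 48)
    unfrozen_options: tuple[int, ...] = (0, 1, 2)
    n_draws: int = 30
    cv_folds: int = 5

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")


@dataclass(frozen=True)
class StaticScaler:
    """Standardization of the 7-feature static vector.

    Column 0 (sex) stays binary; columns 1-6 are z-scored with constants
    fitted on training subjects only.
    """

    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, statics_matrix: np.ndarray) -> "StaticScaler":
        m = statics_matrix.mean(axis=0)
        s = statics_matrix.std(axis=0)
        m[0] = 0.0
        s[0] = 1.0
        s[s == 0] = 1.0
        return cls(mean=m, sd=s)

    def transform(self, statics_matrix: np.ndarray) -> np.ndarray:
        return (statics_matrix - self.mean) / self.sd


@dataclass
class ModelHandle:
    arch: ArchConfig
    net: SeqTorqueNet
    provenance: str                      # direct | pretrained | transfer
    scaler: StaticScaler | None = None
    train_config: TrainConfig | None = None
    history: list[dict] = field(default_factory=list)

    def save(self, path: str | Path) -> None:
        import json

        meta = dict(
            provenance=self.provenance, head=self.net.head,
            n_channels=self.net.n_channels, n_static=self.net.n_static,
            **{f"arch_{k}": v for k, v in vars(self.arch).items()})
        arrays = {f"param_{k}": v for k, v in self.net.params.items()}
        if self.scaler is not None:
            arrays["scaler_mean"] = self.scaler.mean
            arrays["scaler_sd"] = self.scaler.sd
        np.savez(path, _meta=np.array([json.dumps(meta)]), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "ModelHandle":
        import json

        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["_meta"][0]))
        arch = ArchConfig(**{k[5:]: v for k, v in meta.items()
                             if k.startswith("arch_")})
        net = SeqTorqueNet(arch, n_channels=meta["n_channels"],
                           n_static=meta["n_static"] or 7, head=meta["head"])
        for k in list(net.params):
            net.params[k] = data[f"param_{k}"]
        scaler = None
        if "scaler_mean" in data:
            scaler = StaticScaler(data["scaler_mean"], data["scaler_sd"])
        return cls(arch=arch, net=net, provenance=meta["provenance"],
                   scaler=scaler)


def trials_to_arrays(trials: list[Trial], scaler: StaticScaler | None = None,
                     ) -> tuple[np.ndarray, np.ndarray | None, np.ndarray]:
    """Stack trials into (X, S, y); S is None when trials carry no statics."""
    if not trials:
        raise ValueError("empty trial list")
    X = np.stack([t.activations for t in trials])
    y = np.stack([t.torque for t in trials])
    if all(t.statics is not None for t in trials):
        S = np.stack([t.statics.numeric_vector() for t in trials])
        if scaler is not None:
            S = scaler.transform(S)
    else:
        S = None
    return X, S, y


def build_model(arch: ArchConfig, n_static: int = 7, n_channels: int = 4,
                head: str = "mlp", seed: int = 0) -> ModelHandle:
    net = SeqTorqueNet(arch, n_channels=n_channels, n_static=n_static,
                       head=head, seed=seed)
    return ModelHandle(arch=arch, net=net, provenance="direct")


def _train_loop(net: SeqTorqueNet, X: np.ndarray, S: np.ndarray | None,
                y: np.ndarray, cfg: TrainConfig,
                frozen_lstm_layers: set[int] = frozenset(),
                val: tuple | None = None) -> list[dict]:
    rng = np.random.default_rng(cfg.seed)
    names = net.trainable_names(frozen_lstm_layers)
    if cfg.epochs > 0:
        # start the output bias at the target mean: Adam moves each
        # parameter by at most ~lr per step, so a bias initialized near 0
        # would need thousands of steps to reach torque scale (tens of Nm)
        net.params["out_b"][:] = float(np.mean(y))
    opt = Adam(net.params, names, lr=cfg.learning_rate,
               weight_decay=cfg.weight_decay)
    lowest = 0
    if frozen_lstm_layers:
        trainable_lstm = [l for l in range(net.arch.lstm_layers)
                          if l not in frozen_lstm_layers]
        lowest = min(trainable_lstm) if trainable_lstm else net.arch.lstm_layers
    n = len(X)
    history: list[dict] = []
    best_val, best_params, patience = np.inf, None, 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            preds = net.forward(X[idx], None if S is None else S[idx])
            loss, dpred = mse_loss(preds, y[idx])
            grads = net.backward(dpred, lowest_trainable_layer=lowest)
            opt.step({k: grads[k] for k in names})
            epoch_loss += loss * len(idx)
        rec = {"epoch": epoch, "train_mse": epoch_loss / n}
        if val is not None:
            Xv, Sv, yv = val
            pv = net.forward(Xv, Sv, keep_cache=False)
            vmse = float(np.mean((pv - yv) ** 2))
            rec["val_mse"] = vmse
            if vmse < best_val - 1e-12:
                best_val, patience = vmse, 0
                best_params = {k: v.copy() for k, v in net.params.items()}
            else:
                patience += 1
                if patience >= cfg.early_stop_patience:
                    history.append(rec)
                    break
        history.append(rec)
    if val is not None and best_params is not None:
        net.params.update(best_params)
    return history


def pretrain_backbone(sim_trials: list[Trial], arch: ArchConfig,
                      cfg: TrainConfig) -> ModelHandle:
    """Pre-train the LSTM backbone on simulated activations → torque.

    Uses a temporary linear per-step readout which is discarded at
    hand-off; simulated trials carry no static features.
    """
    if not sim_trials:
        raise ValueError("empty simulated dataset")
    X, _, y = trials_to_arrays(sim_trials)
    net = SeqTorqueNet(arch, n_channels=X.shape[2], head="linear",
                       seed=cfg.seed)
    history = _train_loop(net, X, None, y, cfg)
    return ModelHandle(arch=arch, net=net, provenance="pretrained",
                       train_config=cfg, history=history)


def _fit_scaler(trials: list[Trial]) -> StaticScaler:
    if any(t.statics is None for t in trials):
        raise ValueError("recorded-style trials must carry static features")
    return StaticScaler.fit(np.stack([t.statics.numeric_vector()
                                      for t in trials]))


def finetune_transfer(pretrained: ModelHandle, rec_trials: list[Trial],
                      arch: ArchConfig, cfg: TrainConfig,
                      val_trials: list[Trial] | None = None) -> ModelHandle:
    """Freeze the pre-trained backbone (except the last
    ``arch.unfrozen_backend_layers``), attach a fresh feedforward head and
    fine-tune on recorded-style trials."""
    if pretrained.arch.lstm_layers != arch.lstm_layers \
            or pretrained.arch.lstm_width != arch.lstm_width:
        raise ValueError("pretrained backbone does not match architecture")
    if not rec_trials:
        raise ValueError("empty fine-tuning dataset")
    scaler = _fit_scaler(rec_trials)
    X, S, y = trials_to_arrays(rec_trials, scaler)
    net = SeqTorqueNet(arch, n_channels=X.shape[2], n_static=S.shape[1],
                       head="mlp", seed=cfg.seed)
    for l in range(arch.lstm_layers):
        for name in net.lstm_param_names(l):
            net.params[name] = pretrained.net.params[name].copy()
    frozen = set(range(arch.lstm_layers - arch.unfrozen_backend_layers))
    val = None
    if val_trials:
        Xv, Sv, yv = trials_to_arrays(val_trials, scaler)
        val = (Xv, Sv, yv)
    history = _train_loop(net, X, S, y, cfg, frozen_lstm_layers=frozen,
                          val=val)
    return ModelHandle(arch=arch, net=net, provenance="transfer",
                       scaler=scaler, train_config=cfg, history=history)


def train_direct(rec_trials: list[Trial], arch: ArchConfig, cfg: TrainConfig,
                 val_trials: list[Trial] | None = None) -> ModelHandle:
    """Train the full network from random initialization on recorded-style
    trials (all parameters trainable)."""
    if not rec_trials:
        raise ValueError("empty training dataset")
    scaler = _fit_scaler(rec_trials)
    X, S, y = trials_to_arrays(rec_trials, scaler)
    net = SeqTorqueNet(arch, n_channels=X.shape[2], n_static=S.shape[1],
                       head="mlp", seed=cfg.seed)
    val = None
    if val_trials:
        Xv, Sv, yv = trials_to_arrays(val_trials, scaler)
        val = (Xv, Sv, yv)
    history = _train_loop(net, X, S, y, cfg, val=val)
    return ModelHandle(arch=arch, net=net, provenance="direct",
                       scaler=scaler, train_config=cfg, history=history)


def predict(handle: ModelHandle, trials: list[Trial]) -> np.ndarray:
    """Torque predictions (n_trials, 300) in newton-meters."""
    X, S, _ = trials_to_arrays(trials, handle.scaler)
    if handle.net.head == "linear":
        S = None
    return handle.net.forward(X, S, keep_cache=False)


def _subject_folds(subject_ids: list[str], k: int, seed: int,
                   ) -> list[list[str]]:
    ids = sorted(set(subject_ids))
    if len(ids) < k:
        raise ValueError(f"need at least {k} subjects for {k}-fold CV")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    return [[ids[i] for i in order[j::k]] for j in range(k)]


def random_search(space: SearchSpace, data: list[Trial], mode: str,
                  seed: int, pretrained: ModelHandle | None = None,
                  base_arch: ArchConfig | None = None,
                  epochs: int = 150, batch_size: int = 4,
                  ) -> tuple[ArchConfig, TrainConfig, "pd.DataFrame"]:
    """Random hyperparameter search under subject-wise k-fold CV.

    Draws ``n_draws`` (learning rate, weight decay, width, unfrozen count)
    configurations, evaluates each by mean validation MSE across folds that
    partition *subjects* (never trials), and returns the arg-min; ties break
    toward fewer parameters, then draw order.
    """
    import pandas as pd

    if mode not in ("direct", "transfer"):
        raise ValueError("mode must be 'direct' or 'transfer'")
    if mode == "transfer" and pretrained is None:
        raise ValueError("transfer search requires a pretrained backbone")
    rng = np.random.default_rng(seed)
    base = base_arch or (TRANSFER_ARCH if mode == "transfer" else DIRECT_ARCH)
    folds = _subject_folds([t.subject_id for t in data], space.cv_folds, seed)
    rows = []
    results = []  # (mean_mse, param_count, draw_index, arch, cfg)
    for d in range(space.n_draws):
        lr = float(np.exp(rng.uniform(np.log(space.lr_range[0]),
                                      np.log(space.lr_range[1]))))
        wd = float(np.exp(rng.uniform(np.log(space.wd_range[0]),
                                      np.log(space.wd_range[1]))))
        width = int(rng.choice(space.widths))
        unfrozen = int(rng.choice(space.unfrozen_options)) \
            if mode == "transfer" else 0
        if mode == "transfer":
            # backbone shape is fixed by the pretrained network
            arch = replace(base, ff_width=width, unfrozen_backend_layers=unfrozen)
        else:
            arch = replace(base, ff_width=width)
        cfg = TrainConfig(learning_rate=lr, weight_decay=wd, epochs=epochs,
                          batch_size=batch_size, seed=seed + d)
        fold_mses = []
        for f, held in enumerate(folds):
            train = [t for t in data if t.subject_id not in held]
            valid = [t for t in data if t.subject_id in held]
            if mode == "transfer":
                h = finetune_transfer(pretrained, train, arch, cfg)
            else:
                h = train_direct(train, arch, cfg)
            preds = predict(h, valid)
            _, _, yv = trials_to_arrays(valid)
            mse = float(np.mean((preds - yv) ** 2))
            fold_mses.append(mse)
            rows.append({"draw": d, "fold": f, "lr": lr, "wd": wd,
                         "ff_width": width, "unfrozen": unfrozen,
                         "val_mse": mse})
        pcount = arch.n_parameters_per_trial_step
        results.append((float(np.mean(fold_mses)), pcount, d, arch, cfg))
    results.sort(key=lambda r: (r[0], r[1], r[2]))
    best = results[0]
    return best[3], best[4], pd.DataFrame(rows)
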