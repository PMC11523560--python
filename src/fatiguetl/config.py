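"""Run configuration: one YAML file drives every pipeline stage.

Every output directory receives a manifest carrying the hash of the
effective configuration, so reruns with identical config + seed are
recognizably identical.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .benchmark import BenchmarkConfig
from .fatigue import FatigueParams
from .simdata import DEFAULT_PEAKS, config_hash
from .synthrec import SessionConfig

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "results"
    n_sim_subjects: int = 300
    n_recorded_subjects: int = 25
    n_leaveout: int = 5
    peaks: tuple[float, ...] = DEFAULT_PEAKS
    fatigue: FatigueParams = field(default_factory=FatigueParams)
    session: SessionConfig = field(default_factory=SessionConfig)
    pretrain_epochs: int = 50
    pretrain_batch: int = 32
    finetune_epochs: int = 200
    finetune_batch: int = 4
    train_seeds: tuple[int, ...] = (0, 1, 2)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["peaks"] = list(self.peaks)
        d["train_seeds"] = list(self.train_seeds)
        return d

    @property
    def hash(self) -> str:
        return config_hash(self.to_dict())

    def benchmark_config(self) -> BenchmarkConfig:
        return BenchmarkConfig(
            n_sim_subjects=self.n_sim_subjects,
            n_recorded_subjects=self.n_recorded_subjects,
            n_leaveout=self.n_leaveout, fatigue=self.fatigue,
            session=self.session, pretrain_epochs=self.pretrain_epochs,
            pretrain_batch=self.pretrain_batch,
            finetune_epochs=self.finetune_epochs,
            finetune_batch=self.finetune_batch)


def load_config(path: str | Path | None) -> RunConfig:
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    fat = FatigueParams(**raw.pop("fatigue", {}))
    ses = SessionConfig(**raw.pop("session", {}))
    raw["peaks"] = tuple(raw.get("peaks", DEFAULT_PEAKS))
    raw["train_seeds"] = tuple(raw.get("train_seeds", (0, 1, 2)))
    return RunConfig(fatigue=fat, session=ses, **raw)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
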