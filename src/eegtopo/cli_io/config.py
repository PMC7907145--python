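"""Pipeline configuration: JSON in, validated dataclass out.

Defaults mirror the method's stated settings: theta/alpha/beta bands,
1.4 s trials, 400/200 ms sliding windows, 32x32 mesh, FuzzyEn r = 0.25 and
m = 2, Adam (1e-3, 0.9, 0.999), batch 32, dropout 0.5, tenfold CV.  The
epoch default is desk-scale (30); set ``train.epochs`` to 200 for the
full-scale protocol.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

from eegtopo.classify.baselines import BASELINE_METHODS
from eegtopo.classify.configs import CONFIGS
from eegtopo.classify.train import TrainConfig
from eegtopo.features import FuzzyEnParams
from eegtopo.montage_layout import OCULAR_LABELS
from eegtopo.signal_prep import BandDefinition, DEFAULT_BANDS

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # paths
    input_dir: Optional[str] = None  # cohort directory (None -> simulate)
    output_dir: str = "eegtopo_out"
    montage_file: Optional[str] = None
    # synthesis (used when input_dir is None)
    synth: dict = field(default_factory=dict)
    # preprocessing
    drop_channels: Tuple[str, ...] = OCULAR_LABELS
    trial_length: float = 1.4
    max_trials: Optional[int] = 55
    window: float = 0.4
    step: float = 0.2
    bands: Tuple[BandDefinition, ...] = DEFAULT_BANDS
    # features
    feature: str = "fuzzyen"
    fuzzyen: FuzzyEnParams = field(default_factory=FuzzyEnParams)
    # model / training
    model: str = "C"
    lstm_hidden: int = 128
    train: TrainConfig = field(default_factory=TrainConfig)
    # cross-validation
    cv_k: int = 10
    cv_level: str = "trial"  # or "subject" for leakage-free splits
    train_subsample: Optional[int] = None
    baselines: Tuple[str, ...] = ()
    # statistics
    stats_alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.feature not in ("fuzzyen", "fft"):
            raise ValueError(f"unknown feature {self.feature!r}")
        if self.model not in CONFIGS and self.model != "none":
            raise ValueError(
                f"unknown CNN configuration {self.model!r}; choose from {sorted(CONFIGS)} or 'none'"
            )
        for method in self.baselines:
            if method not in BASELINE_METHODS:
                raise ValueError(f"unknown baseline {method!r}; choose from {BASELINE_METHODS}")
        if self.cv_level not in ("trial", "subject"):
            raise ValueError("cv_level must be 'trial' or 'subject'")
        if self.cv_k < 2:
            raise ValueError("cv_k must be >= 2")
        if not (self.window <= self.trial_length):
            raise ValueError("window must not exceed trial_length")
        if self.input_dir is not None and not Path(self.input_dir).exists():
            raise FileNotFoundError(f"input_dir does not exist: {self.input_dir}")
        if self.montage_file is not None and not Path(self.montage_file).exists():
            raise FileNotFoundError(f"montage_file does not exist: {self.montage_file}")

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        if "bands" in raw:
            raw["bands"] = tuple(
                BandDefinition(b["name"], float(b["f_lo"]), float(b["f_hi"]))
                for b in raw["bands"]
            )
        if "fuzzyen" in raw:
            raw["fuzzyen"] = FuzzyEnParams(**raw["fuzzyen"])
        if "train" in raw:
            raw["train"] = TrainConfig(**raw["train"])
        if "drop_channels" in raw:
            raw["drop_channels"] = tuple(raw["drop_channels"])
        if "baselines" in raw:
            raw["baselines"] = tuple(raw["baselines"])
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
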