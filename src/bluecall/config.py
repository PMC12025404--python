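"""Pipeline configuration: validated defaults, YAML round-trip, and hashing.

Defaults encode the study conditions: 15-30 Hz fourth-order band, 26-s
analysis windows, embedding dimension m=2, tolerance 0.2 sigma, scales up
to tau=12, BIC search over K=1..8, 70/30 train/test split.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

from .entropy import NORM_MODES


@dataclass
class PipelineConfig:
    f_low: float = 15.0
    f_high: float = 30.0
    filter_order: int = 4
    rate: float = 1000.0
    decimation: int = 10
    window_s: float = 26.0
    m: int = 2
    r_coef: float = 0.2
    tau_max: int = 12
    norm_mode: str = "paper"
    method: str = "mse"
    k_range: list[int] = field(default_factory=lambda: list(range(1, 9)))
    zeta: int | None = None
    test_size: float = 0.3
    seed: int = 0
    snr_db: float = 10.0
    noise_kind: str = "white"
    n_scenes: int = 100

    def __post_init__(self) -> None:
        if not (0 < self.f_low < self.f_high < self.rate / 2):
            raise ValueError("band edges must satisfy 0 < f_low < f_high < rate/2")
        if self.window_s <= 0 or self.m < 1 or self.tau_max < 1:
            raise ValueError("window_s, m and tau_max must be positive")
        if not 0.0 < self.r_coef:
            raise ValueError("r_coef must be positive")
        if self.norm_mode not in NORM_MODES:
            raise ValueError(f"norm_mode must be one of {NORM_MODES}")
        if self.method not in ("mse", "pca", "dmd", "wf"):
            raise ValueError(f"unknown method {self.method!r}")
        if not 0 < self.test_size < 1:
            raise ValueError("test_size must lie in (0, 1)")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def replace(self, **overrides) -> "PipelineConfig":
        data = asdict(self)
        data.update({k: v for k, v in overrides.items() if v is not None})
        return PipelineConfig(**data)

    def hash(self) -> str:
        """Short stable digest of the canonicalised config."""
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
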