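"""Flat pipeline configuration with lossless YAML round-trip."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .features import FeatureConfig
from .sst import WaveletSpec
from .synth import NoiseSpec

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Every tunable of the simulate -> evaluate pipeline, flat.

    Defaults follow the operating point of the detection method: 500 Hz
    sampling, a 35 Hz Morlet center frequency, five reconstructed modes,
    Renyi order 3, embedding m=2 with tolerance 0.2 x SD, and a
    150-tree random forest.
    """

    # synthetic cohort
    n_negative_records: int = 30
    n_positive_records: int = 25
    beats_per_record: int = 1200
    separation: float = 1.0
    train_fraction: float = 0.6
    mean_hr: float = 60.0
    hr_jitter: float = 0.05
    baseline_amp: float = 0.05
    baseline_freq: float = 0.25
    powerline_amp: float = 0.02
    powerline_freq: float = 50.0
    white_sd: float = 0.02
    # preprocessing
    fs: float = 500.0
    denoise: bool = True
    include_r: bool = False
    # SST
    wavelet_fc: float = 35.0
    wavelet_tau: float = 0.025
    n_voices: int = 32
    freq_min: float = 0.5
    freq_max: float = 250.0
    gamma_rel: float = 1e-4
    n_modes: int = 5
    ridge_penalty: float = 0.2
    bandwidth_bins: int = 4
    # features
    tf_bands: int = 10
    renyi_alpha: float = 3.0
    embedding_m: int = 2
    r_factor: float = 0.2
    # classifier
    n_trees: int = 150
    # reproducibility
    seed: int = 0

    def wavelet(self) -> WaveletSpec:
        return WaveletSpec(center_frequency=self.wavelet_fc,
                           reference_time=self.wavelet_tau,
                           n_voices=self.n_voices,
                           freq_range=(self.freq_min, self.freq_max))

    def noise(self) -> NoiseSpec:
        return NoiseSpec(baseline_amp=self.baseline_amp,
                         baseline_freq=self.baseline_freq,
                         powerline_amp=self.powerline_amp,
                         powerline_freq=self.powerline_freq,
                         white_sd=self.white_sd)

    def feature_config(self) -> FeatureConfig:
        return FeatureConfig(fs=self.fs, wavelet=self.wavelet(),
                             n_modes=self.n_modes, gamma_rel=self.gamma_rel,
                             ridge_penalty=self.ridge_penalty,
                             bandwidth_bins=self.bandwidth_bins,
                             tf_bands=self.tf_bands, alpha=self.renyi_alpha,
                             m=self.embedding_m, r_factor=self.r_factor)

    # --- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        d = self.to_dict()
        d.update({k: v for k, v in kwargs.items() if v is not None})
        return self.from_dict(d)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
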