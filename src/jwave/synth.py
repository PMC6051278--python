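"""Synthetic single-lead ECG with controllable J-wave morphology.

Each beat is a sum of Gaussian bumps, one per P, Q, R, S, T wave, plus an
optional J bump on the descending slope of the terminal QRS.  Records are
concatenated beats with heart-rate jitter, baseline wander, powerline
interference and white noise; ground-truth R-peak sample indices are kept so
detector performance can be scored exactly.  A dataset is a record-level
collection with a train/test split that never mixes beats of one record
across splits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BeatMorphology",
    "NoiseSpec",
    "EcgRecord",
    "Dataset",
    "generate_beat",
    "generate_record",
    "generate_dataset",
    "POST_R_WINDOW_S",
]

#: length of the post-R analysis window in seconds (120 samples at 500 Hz)
POST_R_WINDOW_S = 0.24

#: fraction of the RR interval at which the R peak sits inside a beat
_R_POSITION = 0.35

#: RR interval below which P/T offsets are compressed toward the QRS
_OFFSET_COMPRESS_RR = 0.9


@dataclass(frozen=True)
class BeatMorphology:
    """Gaussian-bump parameters of one ECG beat.

    Each wave is an ``(amplitude_mV, offset_s, width_s)`` triple; offsets are
    relative to the R-peak center and widths are Gaussian standard
    deviations.  ``j_amplitude > 0`` makes the beat J-wave-positive: a bump of
    that height is added ``j_offset`` seconds after R, on the S-wave upstroke
    / early ST segment, strictly inside the 0.24 s post-R analysis window.
    """

    p: tuple[float, float, float] = (0.12, -0.17, 0.025)
    q: tuple[float, float, float] = (-0.08, -0.025, 0.010)
    r: tuple[float, float, float] = (1.10, 0.0, 0.010)
    s: tuple[float, float, float] = (-0.22, 0.025, 0.010)
    t: tuple[float, float, float] = (0.30, 0.30, 0.060)
    j_amplitude: float = 0.0
    j_offset: float = 0.05
    j_width: float = 0.012

    def __post_init__(self) -> None:
        for name in ("p", "q", "r", "s", "t"):
            amp, _off, width = getattr(self, name)
            if width <= 0:
                raise ValueError(f"{name}-wave width must be > 0, got {width}")
        r_amp = self.r[0]
        if not (r_amp > abs(self.q[0]) and r_amp > abs(self.s[0])):
            raise ValueError("R amplitude must dominate |Q| and |S|")
        if self.j_width <= 0:
            raise ValueError("j_width must be > 0")
        if self.j_amplitude < 0:
            raise ValueError("j_amplitude must be >= 0")
        if self.j_amplitude > 0:
            lo = self.j_offset - 2.0 * self.j_width
            hi = self.j_offset + 2.0 * self.j_width
            if not (0.0 < lo and hi < POST_R_WINDOW_S):
                raise ValueError(
                    "J bump must sit strictly inside the post-R window "
                    f"(0, {POST_R_WINDOW_S}) s; got offset={self.j_offset}, "
                    f"width={self.j_width}"
                )

    @property
    def is_positive(self) -> bool:
        return self.j_amplitude > 0

    def with_j(self, amplitude: float, offset: float | None = None,
               width: float | None = None) -> "BeatMorphology":
        """Copy of this morphology with a different J bump."""
        return replace(
            self,
            j_amplitude=float(amplitude),
            j_offset=self.j_offset if offset is None else float(offset),
            j_width=self.j_width if width is None else float(width),
        )

    def scaled(self, factor: float) -> "BeatMorphology":
        """Copy with every wave amplitude (incl. J) multiplied by ``factor``."""
        def _sc(w: tuple[float, float, float]) -> tuple[float, float, float]:
            return (w[0] * factor, w[1], w[2])

        return replace(
            self,
            p=_sc(self.p), q=_sc(self.q), r=_sc(self.r), s=_sc(self.s),
            t=_sc(self.t), j_amplitude=self.j_amplitude * factor,
        )


@dataclass(frozen=True)
class NoiseSpec:
    """Additive artifact model: baseline wander + powerline + white noise."""

    baseline_amp: float = 0.05     # mV
    baseline_freq: float = 0.25    # Hz, must stay below 1 Hz
    powerline_amp: float = 0.02    # mV
    powerline_freq: float = 50.0   # Hz, mains: 50 or 60
    white_sd: float = 0.02         # mV

    def __post_init__(self) -> None:
        if min(self.baseline_amp, self.powerline_amp, self.white_sd) < 0:
            raise ValueError("noise amplitudes must be >= 0")
        if not 0 < self.baseline_freq < 1.0:
            raise ValueError("baseline wander frequency must be in (0, 1) Hz")
        if self.powerline_freq not in (50.0, 60.0):
            raise ValueError("powerline frequency must be 50 or 60 Hz")

    @classmethod
    def none(cls) -> "NoiseSpec":
        return cls(baseline_amp=0.0, powerline_amp=0.0, white_sd=0.0)


@dataclass
class EcgRecord:
    """A labeled, uniformly sampled single-lead voltage series."""

    record_id: str
    samples: np.ndarray            # mV
    fs: float = 500.0              # Hz
    label: str = "negative"        # {"positive", "negative"}
    true_r_indices: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("record samples must be finite")
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        if self.label not in ("positive", "negative"):
            raise ValueError(f"label must be positive/negative, got {self.label!r}")
        if self.true_r_indices is not None:
            idx = np.asarray(self.true_r_indices, dtype=int)
            if idx.size > 1 and not np.all(np.diff(idx) > 0):
                raise ValueError("true_r_indices must be strictly increasing")
            self.true_r_indices = idx

    def __len__(self) -> int:
        return self.samples.size

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame({
            "sample_index": np.arange(self.samples.size),
            "voltage_mV": self.samples,
        })
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, record_id: str | None = None,
                 fs: float = 500.0, label: str = "negative",
                 true_r_indices: Sequence[int] | None = None) -> "EcgRecord":
        df = pd.read_csv(path)
        rid = record_id if record_id is not None else Path(path).stem
        return cls(record_id=rid, samples=df["voltage_mV"].to_numpy(),
                   fs=fs, label=label, true_r_indices=true_r_indices)


def generate_beat(morph: BeatMorphology, fs: float = 500.0,
                  rr: float = 1.0) -> np.ndarray:
    """One beat of length ``round(rr*fs)`` samples.

    The R peak sits at 35% of the RR interval.  For short cycles
    (rr < 0.9 s) the P and T offsets are compressed proportionally — the
    synthetic analogue of rate-dependent PR/QT shortening — so the beat
    always decays to baseline at its edges.
    """
    if not 0.4 <= rr <= 2.0:
        raise ValueError(f"rr must be in [0.4, 2.0] s, got {rr}")
    if fs <= 0:
        raise ValueError(f"fs must be > 0, got {fs}")
    n = int(round(rr * fs))
    t = np.arange(n) / fs
    t_r = _R_POSITION * rr
    stretch = min(1.0, rr / _OFFSET_COMPRESS_RR)

    y = np.zeros(n)
    for name, scale_offset in (("p", True), ("q", False), ("r", False),
                               ("s", False), ("t", True)):
        amp, off, width = getattr(morph, name)
        center = t_r + (off * stretch if scale_offset else off)
        y += amp * np.exp(-0.5 * ((t - center) / width) ** 2)
    if morph.j_amplitude > 0:
        center = t_r + morph.j_offset
        y += morph.j_amplitude * np.exp(-0.5 * ((t - center) / morph.j_width) ** 2)
    return y


def generate_record(n_beats: int, morph: BeatMorphology,
                    noise: NoiseSpec | None = None, fs: float = 500.0,
                    mean_hr: float = 60.0, hr_jitter: float = 0.05,
                    seed: int = 0, record_id: str = "rec") -> EcgRecord:
    """Concatenate ``n_beats`` beats with RR jitter, then add noise.

    RR intervals are drawn as ``(60/mean_hr)·(1 + jitter·N(0,1))`` clipped
    to the physiological [0.4, 2.0] s range.  The record mean is subtracted
    before noise is added (AC-coupled acquisition).  Identical arguments,
    identical output — all randomness flows from ``seed``.
    """
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    noise = NoiseSpec() if noise is None else noise
    rng = np.random.default_rng(seed)
    rr_mean = 60.0 / mean_hr
    rrs = rr_mean * (1.0 + hr_jitter * rng.standard_normal(n_beats))
    rrs = np.clip(rrs, 0.4, 2.0)

    pieces = []
    r_indices = np.empty(n_beats, dtype=int)
    offset = 0
    for i, rr in enumerate(rrs):
        beat = generate_beat(morph, fs=fs, rr=float(rr))
        r_indices[i] = offset + int(round(_R_POSITION * rr * fs))
        pieces.append(beat)
        offset += beat.size
    x = np.concatenate(pieces)
    x = x - x.mean()

    t = np.arange(x.size) / fs
    if noise.baseline_amp > 0:
        x = x + noise.baseline_amp * np.sin(
            2 * np.pi * noise.baseline_freq * t + rng.uniform(0, 2 * np.pi))
    if noise.powerline_amp > 0:
        x = x + noise.powerline_amp * np.sin(
            2 * np.pi * noise.powerline_freq * t + rng.uniform(0, 2 * np.pi))
    if noise.white_sd > 0:
        x = x + noise.white_sd * rng.standard_normal(x.size)

    label = "positive" if morph.is_positive else "negative"
    return EcgRecord(record_id=record_id, samples=x, fs=fs, label=label,
                     true_r_indices=r_indices)


# defaults of the record population; J amplitude/offset/width values follow
# the usual clinical description of J waves (~0.1-0.2 mV bump 40-60 ms after
# the R peak, 8-15 ms wide)
_J_AMP_MEAN = 0.15        # mV at separation=1
_AMP_FACTOR_SIGMA = 0.10  # log-normal sigma of per-record gain
_J_FACTOR_SIGMA = 0.15    # log-normal sigma of per-record J amplitude


@dataclass
class Dataset:
    """Record-level dataset with a by-record train/test split.

    ``manifest`` has one row per record (record_id, label, split, seed,
    n_beats, mean_hr, j_amplitude).  Records are synthesized on demand from
    their manifest row, so listing a 55-record cohort costs nothing until a
    record is actually materialized.
    """

    manifest: pd.DataFrame
    fs: float = 500.0
    hr_jitter: float = 0.05
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    base_morph: BeatMorphology = field(default_factory=BeatMorphology)
    _cache: dict = field(default_factory=dict, repr=False)

    def record(self, record_id: str, cache: bool = False) -> EcgRecord:
        if record_id in self._cache:
            return self._cache[record_id]
        row = self.manifest.set_index("record_id").loc[record_id]
        morph = self.base_morph.scaled(float(row["amp_factor"]))
        morph = morph.with_j(float(row["j_amplitude"]))
        rec = generate_record(
            n_beats=int(row["n_beats"]), morph=morph, noise=self.noise,
            fs=self.fs, mean_hr=float(row["mean_hr"]),
            hr_jitter=self.hr_jitter, seed=int(row["seed"]),
            record_id=record_id)
        # group label comes from the manifest, not the morphology: in a
        # separation=0 null cohort, "positive" records carry no J bump
        rec.label = str(row["label"])
        if cache:
            self._cache[record_id] = rec
        return rec

    def records(self, split: str | None = None) -> Iterator[EcgRecord]:
        rows = self.manifest
        if split is not None:
            rows = rows[rows["split"] == split]
        for rid in rows["record_id"]:
            yield self.record(rid)

    def record_ids(self, split: str | None = None,
                   label: str | None = None) -> list[str]:
        rows = self.manifest
        if split is not None:
            rows = rows[rows["split"] == split]
        if label is not None:
            rows = rows[rows["label"] == label]
        return list(rows["record_id"])

    def to_dir(self, out_dir: str | Path) -> None:
        """Write every record as CSV plus a JSON manifest."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        entries = []
        for _, row in self.manifest.iterrows():
            rec = self.record(row["record_id"])
            rec.to_csv(out / f"{rec.record_id}.csv")
            entries.append({
                "record_id": rec.record_id,
                "label": rec.label,
                "split": row["split"],
                "seed": int(row["seed"]),
                "fs": self.fs,
                "n_beats": int(row["n_beats"]),
                "true_r_indices": rec.true_r_indices.tolist(),
            })
        (out / "manifest.json").write_text(json.dumps(entries, indent=1))


def generate_dataset(n_negative_records: int = 30,
                     n_positive_records: int = 25,
                     beats_per_record: int = 1200,
                     separation: float = 1.0,
                     train_fraction: float = 0.6,
                     seed: int = 0,
                     fs: float = 500.0,
                     mean_hr: float = 60.0,
                     hr_jitter: float = 0.05,
                     noise: NoiseSpec | None = None,
                     base_morph: BeatMorphology | None = None) -> Dataset:
    """Build a labeled multi-record cohort with a record-level split.

    Between-record variability: every record gets a log-normal gain on all
    wave amplitudes, and every positive record draws its own J amplitude
    around ``separation·0.15`` mV (log-normal spread).  ``separation=0``
    collapses the positive class onto the negative distribution exactly.
    The split is by record: ``round(train_fraction·n)`` records per class go
    to training (defaults reproduce an 18/15 train, 12/10 test layout).
    """
    if n_negative_records < 1 or n_positive_records < 1:
        raise ValueError("need at least one record per class")
    if separation < 0:
        raise ValueError("separation must be >= 0")
    n_train_neg = int(round(train_fraction * n_negative_records))
    n_train_pos = int(round(train_fraction * n_positive_records))
    if (min(n_train_neg, n_train_pos) < 1
            or n_train_neg >= n_negative_records
            or n_train_pos >= n_positive_records):
        raise ValueError(
            "infeasible record-level split: each class needs >= 1 train and "
            ">= 1 test record")

    noise = NoiseSpec() if noise is None else noise
    base_morph = BeatMorphology() if base_morph is None else base_morph
    rng = np.random.default_rng(seed)
    rows = []
    for label, n_rec, n_train in (("negative", n_negative_records, n_train_neg),
                                  ("positive", n_positive_records, n_train_pos)):
        splits = np.array(["train"] * n_train
                          + ["test"] * (n_rec - n_train), dtype=object)
        rng.shuffle(splits)
        for i in range(n_rec):
            amp_factor = float(np.exp(_AMP_FACTOR_SIGMA * rng.standard_normal()))
            if label == "positive" and separation > 0:
                j_amp = float(_J_AMP_MEAN * separation
                              * np.exp(_J_FACTOR_SIGMA * rng.standard_normal()))
            else:
                j_amp = 0.0
            rows.append({
                "record_id": f"{label[:3]}-{i + 1:03d}",
                "label": label,
                "split": splits[i],
                "seed": int(rng.integers(0, 2 ** 31 - 1)),
                "n_beats": beats_per_record,
                "mean_hr": float(np.clip(
                    mean_hr + 5.0 * rng.standard_normal(), 45.0, 110.0)),
                "amp_factor": amp_factor,
                "j_amplitude": j_amp,
            })
    manifest = pd.DataFrame(rows)
    return Dataset(manifest=manifest, fs=fs, hr_jitter=hr_jitter,
                   noise=noise, base_morph=base_morph)
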