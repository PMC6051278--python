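import warnings

import numpy as np
import pytest

from jwave import features, preprocess, synth
from jwave.config import PipelineConfig


@pytest.fixture(scope="session")
def fs() -> float:
    return 500.0


@pytest.fixture(scope="session")
def clean_record(fs):
    """60-beat clean synthetic record at 60 bpm."""
    return synth.generate_record(
        60, synth.BeatMorphology(), synth.NoiseSpec.none(), fs=fs,
        mean_hr=60.0, hr_jitter=0.05, seed=11, record_id="clean")


@pytest.fixture(scope="session")
def beat_windows(fs):
    """A few denoised beat windows from a J-positive record."""
    rec = synth.generate_record(
        6, synth.BeatMorphology(j_amplitude=0.15), synth.NoiseSpec(),
        fs=fs, seed=7, record_id="pos")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rec = preprocess.denoise(rec)
    r = preprocess.detect_r_peaks(rec)
    ws = preprocess.segment_beats(rec, r)
    assert len(ws) >= 4
    return ws


@pytest.fixture(scope="session")
def reduced_pipeline_outcome():
    """Shared end-to-end run: 6+6 train / 4+4 test records, 200 beats each.

    Computed once per session; reused by the discrimination, feature
    statistics and importance checks.
    """
    from jwave.pipeline import (build_features, build_windows,
                                train_and_evaluate)
    from jwave.synth import generate_dataset

    cfg = PipelineConfig(n_negative_records=10, n_positive_records=10,
                         beats_per_record=200, separation=1.0, seed=42)
    ds = generate_dataset(
        n_negative_records=cfg.n_negative_records,
        n_positive_records=cfg.n_positive_records,
        beats_per_record=cfg.beats_per_record, separation=cfg.separation,
        train_fraction=cfg.train_fraction, seed=cfg.seed, fs=cfg.fs,
        mean_hr=cfg.mean_hr, hr_jitter=cfg.hr_jitter, noise=cfg.noise())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        windows = build_windows(ds, cfg)
        feats = build_features(windows, cfg)
        outcome = train_and_evaluate(feats, ds, cfg)
    return {"config": cfg, "dataset": ds, "features": feats, **outcome}


def brute_force_apen(x, m, r):
    """Textbook O(N^2) approximate entropy (self-matches included)."""
    x = np.asarray(x, dtype=float)
    n = x.size

    def phi(mm):
        templates = [x[i:i + mm] for i in range(n - mm + 1)]
        logs = []
        for ti in templates:
            count = sum(
                1 for tj in templates if np.max(np.abs(ti - tj)) <= r)
            logs.append(np.log(count / len(templates)))
        return np.mean(logs)

    return phi(m) - phi(m + 1)


def brute_force_sampen(x, m, r):
    """Textbook O(N^2) sample entropy (self-matches excluded)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    nt = n - m
    b = a = 0
    for i in range(nt):
        for j in range(nt):
            if i == j:
                continue
            if np.max(np.abs(x[i:i + m] - x[j:j + m])) <= r:
                b += 1
            if np.max(np.abs(x[i:i + m + 1] - x[j:j + m + 1])) <= r:
                a += 1
    if a == 0 or b == 0:
        return float("nan")
    return -np.log(a / b)
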