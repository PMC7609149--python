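"""Shared fixtures; the heavyweight synthetic benchmark is session-scoped."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pytest

from threshseg import (
    HandSegmenter,
    PhantomParams,
    equalize_histogram,
    generate_dataset,
    label_dataset,
)
from threshseg.features import feature_matrix

BENCHMARK_SEED = 7
N_TRAIN, N_TEST = 500, 100


@dataclass
class Benchmark:
    """The default synthetic study: 500 training / 100 test phantoms,
    engine trained on the training split, everything precomputed once."""

    train: list
    test: list
    engine: HandSegmenter
    X_test: np.ndarray  # normalized test features
    y_test: np.ndarray  # oracle threshold labels of the test split
    y_pred: np.ndarray  # stacked predictions
    results: list  # SegmentationResult per test image


@pytest.fixture(scope="session")
def benchmark() -> Benchmark:
    samples = generate_dataset(N_TRAIN + N_TEST, PhantomParams(seed=BENCHMARK_SEED))
    train, test = samples[:N_TRAIN], samples[N_TRAIN:]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        engine = HandSegmenter(random_state=0).fit(
            [s.image for s in train], [s.mask for s in train]
        )
        enh_test = [equalize_histogram(s.image) for s in test]
        labels = label_dataset(enh_test, [s.mask for s in test], enhance=False)
        X_test = engine.normalizer_.transform(feature_matrix(enh_test))
        y_pred = engine.stacker_.predict(X_test)
        results = engine.predict([s.image for s in test])
    return Benchmark(
        train=train,
        test=test,
        engine=engine,
        X_test=X_test,
        y_test=labels["label"].to_numpy(dtype=int),
        y_pred=y_pred,
        results=results,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture()
def phantom_pair():
    """One moderately noisy phantom (image, mask) at default settings."""
    s = generate_dataset(1, PhantomParams(seed=11))[0]
    return s.image, s.mask
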