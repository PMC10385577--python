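"""Shared fixtures: synthetic benchmarks and fitted classifiers.

Everything is generated programmatically; session scope keeps the more
expensive artifacts (the 600-patch benchmark, trained models) shared
across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

from tonguemap.classifier import SmallCNNClassifier, TextureBaselineClassifier
from tonguemap.dataset import records_to_arrays
from tonguemap.synthfix import fixture_suite, generate_patch_benchmark

BENCHMARK_SEED = 7
N_PER_CLASS = 200


@pytest.fixture(scope="session")
def benchmark_records():
    """The standard separability benchmark: 200 patches per class, seed 7."""
    return generate_patch_benchmark(BENCHMARK_SEED, N_PER_CLASS)


@pytest.fixture(scope="session")
def benchmark_arrays(benchmark_records):
    return records_to_arrays(benchmark_records)


@pytest.fixture(scope="session")
def benchmark_split(benchmark_arrays):
    """Deterministic 480/120 train/validation partition of the benchmark."""
    X, y = benchmark_arrays
    idx = np.random.default_rng(0).permutation(len(X))
    tr, va = idx[:480], idx[480:]
    return (X[tr], y[tr]), (X[va], y[va])


@pytest.fixture(scope="session")
def small_arrays():
    """A small, quick benchmark for unit tests (40 per class, seed 3)."""
    return records_to_arrays(generate_patch_benchmark(3, 40))


@pytest.fixture(scope="session")
def fitted_baseline(benchmark_arrays):
    """Texture baseline fitted on the even-index half of the benchmark."""
    X, y = benchmark_arrays
    return TextureBaselineClassifier().fit(X[::2], y[::2])


@pytest.fixture(scope="session")
def cnn_training_runs(benchmark_split):
    """Two independent CNN fits with identical data and seed (600 patches,
    10 epochs): the pair backs both the determinism and the learning checks."""
    (Xtr, ytr), (Xva, yva) = benchmark_split
    runs = []
    for _ in range(2):
        est = SmallCNNClassifier(epochs=10, seed=BENCHMARK_SEED)
        est.fit(Xtr, ytr, X_val=Xva, y_val=yva)
        runs.append(est)
    return runs


@pytest.fixture(scope="session")
def scene_fixtures():
    """Named degenerate scenes (all-normal, all-abnormal, half/half, ...)."""
    return fixture_suite()
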