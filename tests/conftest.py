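import numpy as np
import pytest

from sccase import (
    ModelParams,
    PeakByCellMatrix,
    Peak,
    SimulationSpec,
    corrupt_dropout,
    filter_peaks,
    sample_mask,
    simulate_discrete,
    tfidf_transform,
)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_instance(rng):
    """A small random (X, W, H, Z, R, params) tuple for derivative checks."""
    m, n, k = 6, 5, 2
    X = rng.random((m, n))
    W = rng.random((m, k))
    H = rng.random((k, n))
    Z = rng.random((n, n))
    params = ModelParams(k=k, lam=2.0, gamma1=0.7, gamma2=0.3, mask_p=0.8, seed=1)
    R = sample_mask(n, params.mask_p, seed=3)
    return X, W, H, Z, R, params


def make_pbc(values, layer_tag="raw"):
    values = np.asarray(values)
    m, n = values.shape
    peaks = [Peak("chr1", i * 1000, i * 1000 + 500) for i in range(m)]
    barcodes = [f"cell{j}" for j in range(n)]
    return PeakByCellMatrix(values, peaks, barcodes, layer_tag)


@pytest.fixture(scope="session")
def desk_dataset():
    """The desk-scale benchmark: 5 planted clusters, 60% dropout, preprocessed.

    Shared (session-scoped) because fitting it is the expensive part of the
    recovery tests.
    """
    spec = SimulationSpec(
        n_clusters=5,
        cells_per_cluster=100,
        n_marker_peaks_per_cluster=500,
        n_shared_peaks=500,
        seed=11,
    )
    data = simulate_discrete(spec)
    corrupted = corrupt_dropout(data.observed, rate=0.6, seed=12)
    X_filt = filter_peaks(corrupted)
    X_tfidf = tfidf_transform(X_filt)
    kept = {str(p) for p in X_filt.peaks}
    keep_idx = [i for i, p in enumerate(data.truth.peaks) if str(p) in kept]
    truth = PeakByCellMatrix(
        data.truth.dense()[keep_idx],
        [data.truth.peaks[i] for i in keep_idx],
        list(data.truth.barcodes),
        "truth",
    )
    return {
        "data": data,
        "X_filt": X_filt,
        "X_tfidf": X_tfidf,
        "truth": truth,
        "labels": data.true_types(),
    }
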