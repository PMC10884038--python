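"""Reference-guided enhancement (the scCASER variant).

When bulk or pseudo-bulk accessibility profiles over the same peak set are
available, a non-negative basis ``P`` (m x k1) extracted from them by NMF can
anchor part of the projection matrix.  The objective splits ``W`` into an
anchored block ``W1`` (m x k1, drawn toward P by a penalty α||P − W1||²) and
a free block ``W2`` (m x k2, k = k1 + k2) learned from the target data alone:

    F = ||X(Z∘R) − (M∘W1 + N∘W2)H||² + λ||Z − HᵀH||²
        + γ1||W_m||² + γ2||H||² + α||P − W1||²

``M`` and ``N`` are complementary binary column masks (M is 1 exactly on the
k1 anchored columns); the Hadamard-mask composition M∘W1 + N∘W2 equals the
column concatenation [W1, W2] when W1 and W2 live on their own blocks, and
the combined matrix W_m is optimized with the same projected-gradient engine
as the plain model.

Three ways of building the reference are provided: depth-scaled bulk
profiles, pseudo-bulk sums over labelled cells of a companion dataset, and
pseudo-bulk sums over the target's own Louvain clusters (self-reference).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import CellLabels, PeakByCellMatrix, SccaseIOError, filter_peaks, tfidf_transform
from .model import (
    FitResult,
    ModelParams,
    _as_array,
    _column_normalize,
    _fit_engine,
    _spawn_seed,
    jaccard_similarity,
    nmf_init,
)

__all__ = [
    "ReferenceMatrix",
    "ReferenceParams",
    "MaskPair",
    "make_masks",
    "nmf_reference",
    "loss_with_reference",
    "gradients_with_reference",
    "fit_with_reference",
    "build_reference_from_bulk",
    "build_pseudobulk",
    "build_self_reference",
    "align_reference",
]


@dataclass
class ReferenceMatrix:
    """Non-negative m peaks x s samples profiles sharing the target's peak set."""

    values: np.ndarray
    sample_names: list[str]
    peaks: list
    provenance: str = "bulk"  # bulk | pseudo-bulk-labels | self-reference

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.sample_names):
            raise SccaseIOError("reference values and sample names disagree in shape")
        if self.values.shape[0] != len(self.peaks):
            raise SccaseIOError("reference values and peak list disagree in shape")
        if self.values.min() < 0:
            raise SccaseIOError("reference profiles must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def write_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            self.values, index=[str(p) for p in self.peaks], columns=self.sample_names
        ).to_csv(path, sep="\t")


@dataclass
class ReferenceParams(ModelParams):
    """Model parameters plus the anchored/free split and the anchoring weight.

    k1 anchored components come from the reference, k2 = k − k1 are free;
    alpha weights the pull of W1 toward the reference basis P.
    """

    k1: int = 1
    alpha: float = 1.0

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.k1 < 1:
            raise ValueError("k1 must be at least 1")
        if self.k - self.k1 < 1:
            raise ValueError("k2 = k - k1 must be at least 1 so free structure can be learned")
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")

    @property
    def k2(self) -> int:
        return self.k - self.k1


@dataclass
class MaskPair:
    """Complementary binary column masks selecting the anchored and free blocks."""

    M: np.ndarray
    N: np.ndarray

    def __post_init__(self) -> None:
        if not np.array_equal(self.M + self.N, np.ones_like(self.M)):
            raise ValueError("M + N must be the all-ones matrix")


def make_masks(m: int, k: int, k1: int) -> MaskPair:
    """M is 1 on the first k1 columns (the anchored block), N on the rest."""
    M = np.zeros((m, k))
    M[:, :k1] = 1.0
    return MaskPair(M=M, N=1.0 - M)


def nmf_reference(ref: ReferenceMatrix | np.ndarray, k1: int, seed: int = 0,
                  max_iter: int = 500) -> np.ndarray:
    """Projection basis P (m x k1) from conventional NMF of the reference."""
    values = ref.values if isinstance(ref, ReferenceMatrix) else np.asarray(ref, float)
    s = values.shape[1]
    if k1 > s:
        raise ValueError(f"k1={k1} exceeds the {s} reference samples")
    P, _ = nmf_init(values, k1, seed=seed, max_iter=max_iter)
    return P


# ---------------------------------------------------------------------------
# masked objective (the explicit two-block form, used for validation)
# ---------------------------------------------------------------------------


def loss_with_reference(X, W1, W2, H, Z, R, masks: MaskPair, P, params: ReferenceParams) -> float:
    """The masked two-block objective, evaluated literally.

    W1 and W2 are both m x k (W1 zero-padded outside its block); P is padded
    to m x k on the anchored columns.  Equals the concatenation form
    ||X(Z∘R) − [W1, W2]H||² + ... when the blocks respect the masks.
    """
    X = _as_array(X)
    Wm = masks.M * W1 + masks.N * W2
    P_pad = np.zeros_like(Wm)
    k1 = P.shape[1]
    P_pad[:, :k1] = P
    return float(
        np.linalg.norm(X @ (Z * R) - Wm @ H) ** 2
        + params.lam * np.linalg.norm(Z - H.T @ H) ** 2
        + params.gamma1 * np.linalg.norm(Wm) ** 2
        + params.gamma2 * np.linalg.norm(H) ** 2
        + params.alpha * np.linalg.norm(P_pad - masks.M * W1) ** 2
    )


def gradients_with_reference(X, W1, W2, H, Z, R, masks: MaskPair, P, params: ReferenceParams):
    """Partial derivatives of the masked objective w.r.t. (W1, W2, H, Z).

    Derived from the trace expansion of the two-block loss: each W-block
    gradient is the usual factorization gradient Hadamard-restricted to its
    mask, and W1 additionally feels 2α(M∘W1 − P).
    """
    X = _as_array(X)
    ZR = Z * R
    XZR = X @ ZR
    Wm = masks.M * W1 + masks.N * W2
    E_grad = -2.0 * XZR @ H.T + 2.0 * Wm @ (H @ H.T) + 2.0 * params.gamma1 * Wm
    P_pad = np.zeros_like(Wm)
    k1 = P.shape[1]
    P_pad[:, :k1] = P
    DW1 = masks.M * E_grad + 2.0 * params.alpha * masks.M * (masks.M * W1 - P_pad)
    DW2 = masks.N * E_grad
    HtH = H.T @ H
    DH = (
        -2.0 * Wm.T @ XZR
        + 2.0 * (Wm.T @ Wm) @ H
        - 2.0 * params.lam * H @ (Z + Z.T)
        + 4.0 * params.lam * (H @ H.T) @ H
        + 2.0 * params.gamma2 * H
    )
    DZ = (
        2.0 * (X.T @ XZR) * R
        - 2.0 * (X.T @ (Wm @ H)) * R
        + 2.0 * params.lam * Z
        - 2.0 * params.lam * HtH
    )
    return DW1, DW2, DH, DZ


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def align_reference(X: PeakByCellMatrix, ref: ReferenceMatrix,
                    drop_unmatched: bool = False) -> tuple[PeakByCellMatrix, ReferenceMatrix]:
    """Check (or restore) an identical, identically ordered peak set.

    With ``drop_unmatched`` the intersection is kept on both sides, in the
    target's order, and the dropped counts are reported in a warning.
    """
    tgt = [str(p) for p in X.peaks]
    rp = [str(p) for p in ref.peaks]
    if tgt == rp:
        return X, ref
    if not drop_unmatched:
        raise SccaseIOError(
            "reference and target peak sets differ; pass drop_unmatched=True "
            "to keep the intersection"
        )
    ref_index = {p: i for i, p in enumerate(rp)}
    keep_t, keep_r = [], []
    for i, p in enumerate(tgt):
        j = ref_index.get(p)
        if j is not None:
            keep_t.append(i)
            keep_r.append(j)
    if not keep_t:
        raise SccaseIOError("reference and target share no peaks")
    warnings.warn(
        f"dropped {len(tgt) - len(keep_t)} target and {len(rp) - len(keep_t)} "
        "reference peaks without a match",
        stacklevel=2,
    )
    X2 = PeakByCellMatrix(
        X.dense()[keep_t], [X.peaks[i] for i in keep_t], list(X.barcodes), X.layer_tag
    )
    ref2 = ReferenceMatrix(
        ref.values[keep_r], list(ref.sample_names),
        [ref.peaks[j] for j in keep_r], ref.provenance,
    )
    return X2, ref2


def _tfidf_reference(ref: ReferenceMatrix) -> np.ndarray:
    """TF-IDF the reference profiles (samples as columns) onto the target scale.

    Raw pseudo-bulk sums are orders of magnitude above TF-IDF weights; without
    this the anchoring penalty α||P − W1||² would compare incommensurate
    scales.
    """
    pbc = PeakByCellMatrix(ref.values, ref.peaks, [f"s{i}" for i in range(ref.n_samples)],
                           layer_tag="filtered")
    return tfidf_transform(pbc).dense()


def fit_with_reference(X, ref: Optional[ReferenceMatrix], params: ReferenceParams | ModelParams,
                       preprocess_reference: bool = True) -> FitResult:
    """Fit the reference-anchored model.

    The reference is TF-IDF transformed (unless ``preprocess_reference`` is
    off), factorized into P = NMF(ref, k1), and P initializes — and anchors —
    the leading k1 columns of W; H and the free columns come from NMF of the
    target.  ``ref=None`` with a plain ModelParams runs the degenerate
    zero-anchor model, which takes the identical engine path as :func:`fit`.
    """
    if isinstance(X, PeakByCellMatrix) and X.layer_tag != "tfidf":
        raise ValueError(f"fit_with_reference expects the TF-IDF layer, got {X.layer_tag!r}")
    Xd = _as_array(X)

    if ref is None:
        P, alpha, k1 = None, 0.0, 0
    else:
        if not isinstance(params, ReferenceParams):
            raise ValueError("a ReferenceParams is required when a reference is given")
        if isinstance(X, PeakByCellMatrix):
            X_chk, ref = align_reference(X, ref)
            Xd = X_chk.dense()
        ref_vals = _tfidf_reference(ref) if preprocess_reference else ref.values
        P = nmf_reference(
            ReferenceMatrix(np.maximum(ref_vals, 0.0), ref.sample_names, ref.peaks, ref.provenance),
            params.k1, seed=_spawn_seed(params.seed, 2),
        )
        alpha, k1 = params.alpha, params.k1

    Z0 = _column_normalize(jaccard_similarity(Xd))
    W0, H0 = nmf_init(Xd, params.k, seed=_spawn_seed(params.seed, 0))
    if k1 > 0:
        W0 = W0.copy()
        W0[:, :k1] = P
    return _fit_engine(Xd, params, Z0, W0, H0, P=P, alpha=alpha)


# ---------------------------------------------------------------------------
# reference construction
# ---------------------------------------------------------------------------


def build_reference_from_bulk(counts, sample_names: Sequence[str], peaks,
                              total_mapped_reads: Sequence[float]) -> ReferenceMatrix:
    """Depth-normalize bulk counts: each sample column scaled to reads per million."""
    counts = np.asarray(counts, dtype=float)
    depths = np.asarray(total_mapped_reads, dtype=float)
    if np.any(depths <= 0):
        raise SccaseIOError("every bulk sample needs a positive total mapped read count")
    scaled = counts / depths[None, :] * 1e6
    return ReferenceMatrix(scaled, list(sample_names), list(peaks), provenance="bulk")


def build_pseudobulk(X: PeakByCellMatrix, labels: CellLabels) -> ReferenceMatrix:
    """Per-type pseudo-bulk: sum each peak over the cells of the same type."""
    types = labels.aligned_to(X.barcodes)
    dense = X.dense()
    names, cols = [], []
    for t in dict.fromkeys(types):
        idx = np.flatnonzero(types == t)
        if idx.size == 0:
            warnings.warn(f"label class {t!r} has no cells; dropped", stacklevel=2)
            continue
        names.append(str(t))
        cols.append(dense[:, idx].sum(axis=1))
    return ReferenceMatrix(
        np.column_stack(cols), names, list(X.peaks), provenance="pseudo-bulk-labels"
    )


def build_self_reference(X_raw: PeakByCellMatrix, resolution: float = 1.0, seed: int = 0,
                         X_tfidf: Optional[PeakByCellMatrix] = None,
                         n_components: int = 50, n_neighbors: int = 15) -> ReferenceMatrix:
    """Pseudo-bulk over the target's own Louvain clusters.

    Cells are clustered on the k-NN graph of a PCA embedding of the TF-IDF
    layer (computed from ``X_raw`` if not supplied); raw counts are then
    summed per cluster.
    """
    from .evaluation import louvain_at_resolution, pca_reduce

    if X_tfidf is None:
        X_tfidf = tfidf_transform(
            X_raw if X_raw.layer_tag == "filtered" else X_raw.with_values(X_raw.values, "filtered")
        )
    embedding = pca_reduce(X_tfidf, n_components=n_components, seed=seed)
    cluster_ids = louvain_at_resolution(embedding, resolution=resolution, seed=seed,
                                        n_neighbors=n_neighbors)
    n_clusters = len(np.unique(cluster_ids))
    if n_clusters == 1:
        warnings.warn("Louvain found a single cluster; the self-reference has one column",
                      stacklevel=2)
    labels = CellLabels(list(X_raw.barcodes), [f"cluster{c}" for c in cluster_ids])
    ref = build_pseudobulk(X_raw, labels)
    ref.provenance = "self-reference"
    return ref


def read_reference_tsv(path: str | Path) -> ReferenceMatrix:
    """Read a peaks x samples reference table (peak ids in the first column)."""
    from .io import Peak

    df = pd.read_csv(path, sep="\t", index_col=0)
    peaks = [Peak.parse(str(p)) for p in df.index]
    return ReferenceMatrix(df.to_numpy(dtype=float), [str(c) for c in df.columns], peaks)
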