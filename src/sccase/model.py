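"""The scCASE optimization model.

The method enhances a TF-IDF-weighted peaks x cells matrix ``X`` (m x n) by
learning, jointly, a non-negative factorization ``X(Z∘R) ≈ WH`` and a
cell-to-cell similarity matrix ``Z`` tied to the cell embedding through
``Z ≈ HᵀH``:

    F(W, H, Z) = ||X(Z∘R) − WH||_F² + λ||Z − HᵀH||_F²
                 + γ1||W||_F² + γ2||H||_F²,       W, H, Z ≥ 0

``R`` is a fixed binary Bernoulli mask, Hadamard-applied to ``Z``, that stops
highly similar cells from collapsing onto identical enhanced profiles.  The
three factors are updated by projected gradient descent: ``W`` and ``Z`` use
exact closed-form line searches along their gradients (their 1-D restrictions
of F are quadratics), while ``H`` — whose restriction is quartic — uses
backtracking from an initial step of 0.2.  Enhancement is the matrix product
``X · Z`` with the converged, column-stochastic ``Z``.

A single engine (:func:`_fit_engine`) also serves the reference-augmented
variant, which anchors the leading ``k1`` columns of ``W`` to a projection
``P`` learned from reference profiles with an extra term ``α||P − W1||²``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.decomposition import NMF

from .io import PeakByCellMatrix, binarize

__all__ = [
    "ModelParams",
    "FitResult",
    "estimate_k_eigengap",
    "jaccard_similarity",
    "nmf_init",
    "sample_mask",
    "loss",
    "gradients",
    "optimal_step_w",
    "optimal_step_z",
    "update_h",
    "fit",
    "enhance",
    "DegenerateDirectionError",
]

_EPS = 1e-12
_MIN_H_STEP = 1e-10


class DegenerateDirectionError(ValueError):
    """A line search was requested along a direction with zero curvature."""


@dataclass
class ModelParams:
    """Hyper-parameters of the model.

    k is the latent dimension (the number of cell programs; in practice the
    number of expected cell types).  lam weights the similarity-consistency
    term and defaults to 1e6; gamma1/gamma2 are ridge penalties on W and H;
    mask_p is the Bernoulli success probability of the random mask R.
    """

    k: int
    lam: float = 1e6
    gamma1: float = 1.0
    gamma2: float = 1.0
    mask_p: float = 0.8
    tol: float = 1e-6
    max_iter: int = 100
    seed: int = 0
    delta3_init: float = 0.2
    stop_on: str = "relative"  # or "absolute"

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be at least 2")
        if min(self.lam, self.gamma1, self.gamma2) < 0:
            raise ValueError("lam, gamma1 and gamma2 must be non-negative")
        if not 0 < self.mask_p <= 1:
            raise ValueError("mask_p must lie in (0, 1]; 0 would annihilate the similarity term")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.stop_on not in ("relative", "absolute"):
            raise ValueError("stop_on must be 'relative' or 'absolute'")


@dataclass
class FitResult:
    """Converged factors, the column-stochastic similarity matrix and the loss trace."""

    Z: np.ndarray
    W: np.ndarray
    H: np.ndarray
    loss_trace: np.ndarray
    n_iter: int
    converged: bool
    k1: int = 0  # leading columns of W anchored to a reference projection


def _as_array(X) -> np.ndarray:
    if isinstance(X, PeakByCellMatrix):
        return X.dense()
    return np.asarray(X, dtype=float)


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------


def jaccard_similarity(Xbin) -> np.ndarray:
    """Pairwise Jaccard similarity between cells of a binarized matrix.

    Entry (i, j) is |supp_i ∩ supp_j| / |supp_i ∪ supp_j| over the peak
    supports of cells i and j.  Symmetric with unit diagonal.
    """
    B = _as_array(Xbin)
    B = (B > 0).astype(float)
    sizes = B.sum(axis=0)
    if np.any(sizes == 0):
        raise ValueError("a cell has empty support; Jaccard similarity undefined")
    inter = B.T @ B
    union = sizes[:, None] + sizes[None, :] - inter
    Z = inter / union
    np.fill_diagonal(Z, 1.0)
    return Z


def _column_normalize(Z: np.ndarray) -> np.ndarray:
    colsums = Z.sum(axis=0)
    bad = colsums <= 0
    if bad.any():
        Z = Z.copy()
        Z[np.flatnonzero(bad), np.flatnonzero(bad)] = 1.0
        colsums = Z.sum(axis=0)
    return Z / colsums


def estimate_k_eigengap(Xbin, k_max: int = 20) -> int:
    """Rough latent-dimension guess from the spectrum of the Jaccard matrix.

    Returns the position of the largest eigengap (skipping the trivial
    leading eigenvalue) of the symmetrically normalized cell-cell Jaccard
    similarity.  A coarse heuristic only — dedicated cell-type-number
    estimators are preferable when available, and a warning says so.
    """
    warnings.warn(
        "the eigengap heuristic is a coarse guess at the number of cell "
        "programs; prefer a known cell-type count when one exists",
        stacklevel=2,
    )
    Z = jaccard_similarity(Xbin)
    d = Z.sum(axis=0)
    sym = Z / np.sqrt(d[:, None] * d[None, :])
    eigvals = np.linalg.eigvalsh(sym)[::-1]
    k_max = min(k_max, len(eigvals) - 1)
    gaps = -np.diff(eigvals[: k_max + 1])
    return int(np.argmax(gaps[1:]) + 2)  # k >= 2


def nmf_init(X, k: int, seed: int = 0, max_iter: int = 500) -> tuple[np.ndarray, np.ndarray]:
    """Conventional NMF of X into (W0, H0), minimizing ||X − WH||_F².

    Uses coordinate descent with NNDSVDa initialization; deterministic for a
    given seed.
    """
    Xd = _as_array(X)
    m, n = Xd.shape
    if k > min(m, n):
        raise ValueError(f"k={k} exceeds min(m, n)={min(m, n)}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = NMF(
            n_components=k,
            init="nndsvda",
            solver="cd",
            max_iter=max_iter,
            tol=1e-6,
            random_state=int(seed) % (2**31),
        )
        W = model.fit_transform(Xd)
        H = model.components_
    return W, H


def sample_mask(n: int, mask_p: float = 0.8, seed: int = 0) -> np.ndarray:
    """An n x n binary matrix of i.i.d. Bernoulli(mask_p) entries."""
    if n < 1:
        raise ValueError("n must be at least 1")
    if not 0 < mask_p <= 1:
        raise ValueError("mask_p must lie in (0, 1]; 0 would annihilate the similarity term")
    rng = np.random.default_rng(seed)
    return (rng.random((n, n)) < mask_p).astype(float)


# ---------------------------------------------------------------------------
# objective and derivatives (reference terms optional)
# ---------------------------------------------------------------------------


def loss(X, W, H, Z, R, params: ModelParams, form: str = "norm",
         P: Optional[np.ndarray] = None, alpha: float = 0.0) -> float:
    """Evaluate F in its Frobenius-norm form or the equivalent trace form.

    The two forms are algebraically identical; both are exposed so that the
    expansion used internally can be checked against the definition.
    """
    X = _as_array(X)
    ZR = Z * R
    if form == "norm":
        val = (
            np.linalg.norm(X @ ZR - W @ H) ** 2
            + params.lam * np.linalg.norm(Z - H.T @ H) ** 2
            + params.gamma1 * np.linalg.norm(W) ** 2
            + params.gamma2 * np.linalg.norm(H) ** 2
        )
    elif form == "trace":
        G = X.T @ X
        HtH = H.T @ H
        val = (
            np.trace(ZR.T @ G @ ZR)
            - 2 * np.trace(H.T @ (W.T @ X) @ ZR)
            + np.trace((H.T @ (W.T @ W)) @ H)
            + params.lam
            * (
                np.trace(Z.T @ Z)
                - np.trace(HtH @ Z)
                - np.trace(Z.T @ HtH)
                + np.trace(HtH @ HtH)
            )
            + params.gamma1 * np.trace(W.T @ W)
            + params.gamma2 * np.trace(H.T @ H)
        )
    else:
        raise ValueError("form must be 'norm' or 'trace'")
    if P is not None:
        k1 = P.shape[1]
        val += alpha * np.linalg.norm(P - W[:, :k1]) ** 2
    return float(val)


def gradients(X, W, H, Z, R, params: ModelParams,
              P: Optional[np.ndarray] = None, alpha: float = 0.0):
    """Partial derivatives (∂F/∂W, ∂F/∂H, ∂F/∂Z) at the current iterate.

    The Z gradient carries the Hadamard mask R on its two data terms.  When a
    reference projection ``P`` anchors the leading columns of ``W``, the W
    gradient gains ``2α(W1 − P)`` on that block.
    """
    X = _as_array(X)
    ZR = Z * R
    XZR = X @ ZR
    HHt = H @ H.T
    D1 = -2.0 * XZR @ H.T + 2.0 * W @ HHt + 2.0 * params.gamma1 * W
    if P is not None and alpha > 0:
        k1 = P.shape[1]
        D1[:, :k1] += 2.0 * alpha * (W[:, :k1] - P)
    HtH = H.T @ H
    D3 = (
        -2.0 * W.T @ XZR
        + 2.0 * (W.T @ W) @ H
        - 2.0 * params.lam * H @ (Z + Z.T)
        + 4.0 * params.lam * HHt @ H
        + 2.0 * params.gamma2 * H
    )
    D2 = (
        2.0 * (X.T @ XZR) * R
        - 2.0 * (X.T @ (W @ H)) * R
        + 2.0 * params.lam * Z
        - 2.0 * params.lam * HtH
    )
    return D1, D3, D2


def optimal_step_w(X, W, H, Z, R, D1, params: ModelParams,
                   P: Optional[np.ndarray] = None, alpha: float = 0.0) -> float:
    """Exact minimizer of the quadratic δ ↦ F(W − δ·D1, H, Z).

    F restricted to the line is a parabola; the vertex is
    ⟨D1, ∇_W F⟩ / (2(||D1 H||² + γ1||D1||² [+ α||D1 on the anchored block||²])).
    With γ1 = 0 (and no anchor) this is the classical trace-ratio step for the
    data term alone.
    """
    X = _as_array(X)
    E = X @ (Z * R) - W @ H  # residual of the data term
    num = params.gamma1 * np.vdot(W, D1) - np.vdot(E, D1 @ H)
    den = np.linalg.norm(D1 @ H) ** 2 + params.gamma1 * np.linalg.norm(D1) ** 2
    if P is not None and alpha > 0:
        k1 = P.shape[1]
        num += alpha * np.vdot(W[:, :k1] - P, D1[:, :k1])
        den += alpha * np.linalg.norm(D1[:, :k1]) ** 2
    if den <= _EPS:
        raise DegenerateDirectionError("zero curvature along D1; cannot form a W step")
    return float(num / den)


def optimal_step_z(X, W, H, Z, R, D2, params: ModelParams) -> float:
    """Exact minimizer of the quadratic δ ↦ F(W, H, Z − δ·D2).

    Equivalent to the trace-form ratio
    [tr(eq1) − tr(eq3) + λ·tr(eq4) − λ·tr(eq6)] / [2 tr(eq2) + 2λ tr(eq5)]
    with eq1..eq6 the six trace blocks of the expanded objective; evaluated
    here through the identical inner-product contractions.
    """
    X = _as_array(X)
    DR = D2 * R
    XDR = X @ DR
    num = (
        np.vdot(XDR, X @ (Z * R))          # ½ tr(eq1)
        - np.vdot(XDR, W @ H)              # -½ tr(eq3)
        + params.lam * np.vdot(D2, Z)      # ½ λ tr(eq4)
        - params.lam * np.vdot(D2, H.T @ H)  # -½ λ tr(eq6)
    )
    den = np.linalg.norm(XDR) ** 2 + params.lam * np.linalg.norm(D2) ** 2  # ½(tr eq2 + λ tr eq5)
    if den <= _EPS:
        raise DegenerateDirectionError("zero curvature along D2; cannot form a Z step")
    return float(num / den)


def update_h(X, W, H, Z, R, D3, params: ModelParams,
             P: Optional[np.ndarray] = None, alpha: float = 0.0) -> np.ndarray:
    """Backtracking projected-gradient update of H.

    Starting from ``delta3_init`` the step is halved until the projected step
    lowers F; if no step above 1e-10 does, H is returned unchanged (a legal
    no-op for that iteration).
    """
    f0 = loss(X, W, H, Z, R, params, P=P, alpha=alpha)
    delta = params.delta3_init
    while delta >= _MIN_H_STEP:
        H_new = np.maximum(H - delta * D3, 0.0)
        if loss(X, W, H_new, Z, R, params, P=P, alpha=alpha) < f0:
            return H_new
        delta *= 0.5
    return H


def enhance(X_source, Z: np.ndarray, layer_tag: str = "enhanced"):
    """Enhanced matrix X·Z from a column-stochastic similarity matrix."""
    if isinstance(X_source, PeakByCellMatrix):
        vals = X_source.dense()
        if vals.shape[1] != Z.shape[0]:
            raise ValueError("matrix and similarity dimensions disagree")
        return X_source.with_values(vals @ Z, layer_tag)
    X_source = np.asarray(X_source, dtype=float)
    if X_source.shape[1] != Z.shape[0]:
        raise ValueError("matrix and similarity dimensions disagree")
    return X_source @ Z


# ---------------------------------------------------------------------------
# the optimization engine
# ---------------------------------------------------------------------------


class _Objective:
    """Cached trace-form evaluation of F, sharing the n x n Gram matrix XᵀX.

    All expansions avoid m x n temporaries: the data term is contracted to
    tr(ZRᵀ G ZR) − 2 tr(Hᵀ(WᵀX)ZR) + tr((WᵀW)(HHᵀ)) with G = XᵀX.
    """

    def __init__(self, X: np.ndarray, R: np.ndarray, params: ModelParams,
                 P: Optional[np.ndarray], alpha: float):
        self.X = X
        self.G = X.T @ X
        self.R = R
        self.p = params
        self.P = P
        self.alpha = alpha
        self.k1 = 0 if P is None else P.shape[1]

    def value(self, W, H, Z, ZR=None, GZR=None, WtX=None) -> float:
        p = self.p
        if ZR is None:
            ZR = Z * self.R
        if GZR is None:
            GZR = self.G @ ZR
        if WtX is None:
            WtX = W.T @ self.X
        data = (
            np.vdot(ZR, GZR)
            - 2.0 * np.vdot(H, WtX @ ZR)
            + np.vdot(W.T @ W, H @ H.T)
        )
        sim = p.lam * np.linalg.norm(Z - H.T @ H) ** 2
        reg = p.gamma1 * np.vdot(W, W) + p.gamma2 * np.vdot(H, H)
        val = data + sim + reg
        if self.k1 > 0:
            val += self.alpha * np.linalg.norm(self.P - W[:, : self.k1]) ** 2
        return float(val)


def _backtrack_accept(obj: _Objective, f_cur: float, delta: float, update, max_halvings: int = 30):
    """Try a projected step, halving ``delta`` until F does not increase.

    ``update(delta)`` must return (candidate state, new loss).  Returns the
    accepted (state, loss) or (None, f_cur) when every step increases F —
    which can happen only through the non-negativity projection, since the
    un-projected step is an exact line minimizer.
    """
    for _ in range(max_halvings):
        state, f_new = update(delta)
        if f_new <= f_cur:
            return state, f_new
        delta *= 0.5
    return None, f_cur


def _fit_engine(X: np.ndarray, params: ModelParams, Z0: np.ndarray,
                W0: np.ndarray, H0: np.ndarray,
                P: Optional[np.ndarray] = None, alpha: float = 0.0) -> FitResult:
    """Projected gradient descent with closed-form W/Z steps and backtracked H.

    Shared by the plain and the reference-anchored fits (the latter passes a
    projection P anchoring the first k1 columns of W); with P=None the two
    code paths are identical, so the anchored model with an empty anchor
    reproduces the plain fit bitwise.
    """
    p = params
    n = X.shape[1]
    R = sample_mask(n, p.mask_p, _spawn_seed(p.seed, 1))
    obj = _Objective(X, R, p, P, alpha)
    k1 = obj.k1

    W, H, Z = W0.copy(), H0.copy(), Z0.copy()
    f_cur = obj.value(W, H, Z)
    trace = [f_cur]
    converged = False
    n_iter = 0

    for n_iter in range(1, p.max_iter + 1):
        ZR = Z * R
        GZR = obj.G @ ZR
        XZRHt = X @ (ZR @ H.T)  # X(Z∘R)Hᵀ without the m x n intermediate
        HHt = H @ H.T

        # ---- W: exact line search along the gradient, projection-checked
        D1 = -2.0 * XZRHt + 2.0 * W @ HHt + 2.0 * p.gamma1 * W
        if k1 > 0:
            D1[:, :k1] += 2.0 * alpha * (W[:, :k1] - P)
        den = np.linalg.norm(D1 @ H) ** 2 + p.gamma1 * np.linalg.norm(D1) ** 2
        if k1 > 0:
            den += alpha * np.linalg.norm(D1[:, :k1]) ** 2
        if den > _EPS:
            delta1 = 0.5 * np.vdot(D1, D1) / den
            if delta1 > 0:
                def w_step(d):
                    W_new = np.maximum(W - d * D1, 0.0)
                    return W_new, obj.value(W_new, H, Z, ZR=ZR, GZR=GZR)
                W_new, f_new = _backtrack_accept(obj, f_cur, delta1, w_step)
                if W_new is not None:
                    W, f_cur = W_new, f_new
            else:
                warnings.warn("non-descent W direction; skipping W update", stacklevel=2)
        WtX = W.T @ X

        # ---- Z: exact line search along the gradient, projection-checked
        XtWH = WtX.T @ H  # (XᵀW)H = Xᵀ(WH)
        HtH = H.T @ H
        D2 = 2.0 * GZR * R - 2.0 * XtWH * R + 2.0 * p.lam * Z - 2.0 * p.lam * HtH
        DR = D2 * R
        GDR = obj.G @ DR
        den = np.vdot(DR, GDR) + p.lam * np.vdot(D2, D2)
        if den > _EPS:
            num = (
                np.vdot(DR, GZR)
                - np.vdot(DR, XtWH)
                + p.lam * np.vdot(D2, Z)
                - p.lam * np.vdot(D2, HtH)
            )
            delta2 = num / den
            if delta2 > 0:
                def z_step(d):
                    Z_new = np.maximum(Z - d * D2, 0.0)
                    return Z_new, obj.value(W, H, Z_new, WtX=WtX)
                Z_new, f_new = _backtrack_accept(obj, f_cur, delta2, z_step)
                if Z_new is not None:
                    Z, f_cur = Z_new, f_new
            else:
                warnings.warn("non-descent Z direction; skipping Z update", stacklevel=2)
        ZR = Z * R
        GZR = obj.G @ ZR

        # ---- H: backtracking projected gradient from delta3_init
        D3 = (
            -2.0 * WtX @ ZR
            + 2.0 * (W.T @ W) @ H
            - 2.0 * p.lam * H @ (Z + Z.T)
            + 4.0 * p.lam * (H @ H.T) @ H
            + 2.0 * p.gamma2 * H
        )
        delta3 = p.delta3_init
        while delta3 >= _MIN_H_STEP:
            H_new = np.maximum(H - delta3 * D3, 0.0)
            f_new = obj.value(W, H_new, Z, ZR=ZR, GZR=GZR, WtX=WtX)
            if f_new < f_cur:
                H, f_cur = H_new, f_new
                break
            delta3 *= 0.5

        trace.append(f_cur)
        prev, cur = trace[-2], trace[-1]
        change = abs(cur - prev)
        if p.stop_on == "relative":
            change = change / max(prev, _EPS)
        if change < p.tol:
            converged = True
            break

    return FitResult(
        Z=_column_normalize(np.maximum(Z, 0.0)),
        W=W,
        H=H,
        loss_trace=np.asarray(trace),
        n_iter=n_iter,
        converged=converged,
        k1=k1,
    )


def _spawn_seed(seed: int, stream: int) -> int:
    """Derive an independent 31-bit child seed for a named random stream."""
    return int(np.random.SeedSequence(seed).spawn(stream + 1)[stream].generate_state(1)[0] % (2**31))


def fit(X, params: ModelParams) -> FitResult:
    """Run the full enhancement optimization.

    Z starts from the column-normalized Jaccard similarity of the binarized
    matrix, (W, H) from conventional NMF of X, and the mask R is sampled once
    and held fixed.  Iterations stop when the relative loss change drops below
    ``params.tol`` or ``max_iter`` is reached; the returned Z is clipped at
    zero and column-renormalized to sum to 1.
    """
    if isinstance(X, PeakByCellMatrix) and X.layer_tag not in ("tfidf",):
        raise ValueError(f"fit expects the TF-IDF layer, got {X.layer_tag!r}")
    Xd = _as_array(X)
    Z0 = _column_normalize(jaccard_similarity(Xd))
    W0, H0 = nmf_init(Xd, params.k, seed=_spawn_seed(params.seed, 0))
    return _fit_engine(Xd, params, Z0, W0, H0)
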