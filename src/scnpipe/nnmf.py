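"""Structural covariance networks by non-negative matrix factorization.

A voxels x subjects matrix X of (exponentiated) Jacobian values is factorized
as X ~ W H with W (voxels x k) holding spatial network weights and H
(k x subjects) the per-subject expression of each network.  Non-negativity
yields an additive, parts-based decomposition in which each component is a
candidate structural covariance network: a set of voxels whose volumes covary
across individuals.

The rank k is chosen by split-half stability: subjects are repeatedly split
into random halves, the factorization is fitted in each half, networks are
matched across halves by cosine similarity (exact one-to-one assignment), and
the selected rank is the largest candidate whose mean matched similarity
clears a reliability threshold.  Reconstruction error per rank is reported
alongside as a (non-decisive) elbow diagnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

_EPS = 1e-12


@dataclass
class SCNModel:
    """Fitted factorization: non-negative basis W (V x k) and loadings H (k x N)."""

    W: np.ndarray
    H: np.ndarray
    k: int
    recon_error: float
    seed: int
    n_iter: int
    loss_trace: np.ndarray = field(default=None, repr=False)


@dataclass
class RankSelectionReport:
    candidate_ranks: list[int]
    recon_errors: dict[int, float]
    stability: dict[int, float]
    selected_rank: int
    n_splits: int
    threshold: float
    no_stable_rank: bool = False

    def to_text(self) -> str:
        lines = [
            f"selected_rank: {self.selected_rank}",
            f"stability_threshold: {self.threshold}",
            f"n_splits: {self.n_splits}",
            f"no_stable_rank: {self.no_stable_rank}",
            "rank\trecon_error\tstability",
        ]
        for r in self.candidate_ranks:
            lines.append(f"{r}\t{self.recon_errors[r]:.6g}\t{self.stability[r]:.4f}")
        return "\n".join(lines)


def _nndsvd_init(X: np.ndarray, k: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """NNDSVDa initialization: SVD-based, negative parts folded, zeros set to mean.

    Gives a deterministic, data-adapted starting point so multiplicative
    updates converge quickly and reproducibly; tiny seeded jitter breaks the
    exact ties that arise on synthetic data with symmetric structure.
    """
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    W = np.zeros((X.shape[0], k))
    H = np.zeros((k, X.shape[1]))
    W[:, 0] = np.sqrt(S[0]) * np.abs(U[:, 0])
    H[0, :] = np.sqrt(S[0]) * np.abs(Vt[0, :])
    for j in range(1, k):
        u, v = U[:, j], Vt[j, :]
        up, un = np.maximum(u, 0), np.maximum(-u, 0)
        vp, vn = np.maximum(v, 0), np.maximum(-v, 0)
        n_up, n_vp = np.linalg.norm(up), np.linalg.norm(vp)
        n_un, n_vn = np.linalg.norm(un), np.linalg.norm(vn)
        if n_up * n_vp >= n_un * n_vn:
            sig, uu, vv = n_up * n_vp, up / max(n_up, _EPS), vp / max(n_vp, _EPS)
        else:
            sig, uu, vv = n_un * n_vn, un / max(n_un, _EPS), vn / max(n_vn, _EPS)
        W[:, j] = np.sqrt(S[j] * sig) * uu
        H[j, :] = np.sqrt(S[j] * sig) * vv
    mean = X.mean()
    W[W < _EPS] = mean
    H[H < _EPS] = mean
    W *= 1.0 + 1e-4 * rng.random(W.shape)
    H *= 1.0 + 1e-4 * rng.random(H.shape)
    return W, H


def fit_nnmf(
    X: np.ndarray,
    k: int,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-5,
    init: str = "nndsvda",
) -> SCNModel:
    """Minimize ||X - W H||_F over non-negative W, H by multiplicative updates.

    Parameters
    ----------
    X : strictly positive voxels x subjects matrix (post-exponentiation).
    k : number of networks, 1 <= k <= min(V, N).
    seed : controls initialization; the fit is deterministic given the seed.
    tol : stop when the relative decrease of the loss over one iteration
        falls below this (checked each iteration, after a minimum of 10).
    init : "nndsvda" (default) or "random".

    Returns an SCNModel with the per-iteration loss trace attached.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2D")
    if np.any(X <= 0) or not np.all(np.isfinite(X)):
        raise ValueError("X must be strictly positive and finite")
    V, N = X.shape
    if not 1 <= k <= min(V, N):
        raise ValueError(f"k={k} out of range for {V}x{N} matrix")
    rng = np.random.default_rng(seed)
    if init == "nndsvda":
        W, H = _nndsvd_init(X, k, rng)
    elif init == "random":
        scale = np.sqrt(X.mean() / k)
        W = scale * rng.random((V, k)) + _EPS
        H = scale * rng.random((k, N)) + _EPS
    else:
        raise ValueError(f"unknown init {init!r}")

    x_sq = float(np.sum(X * X))
    losses = []
    prev = np.inf
    n_iter = 0
    for it in range(1, max_iter + 1):
        # H update
        WtX = W.T @ X
        WtW = W.T @ W
        H *= WtX / np.maximum(WtW @ H, _EPS)
        # W update
        XHt = X @ H.T
        HHt = H @ H.T
        W *= XHt / np.maximum(W @ HHt, _EPS)
        # loss via trace identity (no V x N residual needed):
        # ||X-WH||^2 = ||X||^2 - 2 tr(H' W' X) + tr(W'W H H')
        WtX = W.T @ X
        WtW = W.T @ W
        HHt = H @ H.T
        sq = x_sq - 2.0 * float(np.sum(WtX * H)) + float(np.sum(WtW * HHt))
        # the identity cancels catastrophically near exact fits; below its
        # noise floor the loss is numerically zero
        if sq < 1e-14 * x_sq:
            sq = 0.0
        loss = np.sqrt(sq)
        losses.append(loss)
        n_iter = it
        if it >= 10 and prev - loss <= tol * max(prev, _EPS):
            break
        prev = loss

    recon_error = float(np.linalg.norm(X - W @ H))
    return SCNModel(
        W=W,
        H=H,
        k=k,
        recon_error=recon_error,
        seed=seed,
        n_iter=n_iter,
        loss_trace=np.asarray(losses),
    )


def cosine_similarity_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pairwise cosine similarity between columns of A and columns of B."""
    An = A / np.maximum(np.linalg.norm(A, axis=0, keepdims=True), _EPS)
    Bn = B / np.maximum(np.linalg.norm(B, axis=0, keepdims=True), _EPS)
    return An.T @ Bn


def pearson_similarity_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlation between columns (cosine after centering).

    Centering removes the shared positive baseline that inflates raw cosine
    similarity between non-negative spatial maps.
    """
    return cosine_similarity_matrix(A - A.mean(axis=0), B - B.mean(axis=0))


def match_networks(
    W_a: np.ndarray, W_b: np.ndarray, metric: str = "cosine"
) -> tuple[np.ndarray, np.ndarray]:
    """Optimal one-to-one column matching by total similarity.

    Returns (perm, sims): column j of W_a is paired with column perm[j] of
    W_b, with similarity sims[j].  The assignment is solved exactly.
    metric is "cosine" (default) or "pearson".
    """
    W_a, W_b = np.asarray(W_a, float), np.asarray(W_b, float)
    if W_a.shape != W_b.shape:
        raise ValueError("shape mismatch")
    if metric == "cosine":
        sim = cosine_similarity_matrix(W_a, W_b)
    elif metric == "pearson":
        sim = pearson_similarity_matrix(W_a, W_b)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    rows, cols = linear_sum_assignment(-sim)
    perm = np.empty(W_a.shape[1], dtype=int)
    perm[rows] = cols
    return perm, sim[rows, perm[rows]]


def select_rank(
    X: np.ndarray,
    candidate_ranks: list[int],
    n_splits: int = 10,
    seed: int = 0,
    threshold: float = 0.875,
    max_iter: int = 300,
    tol: float = 1e-5,
    metric: str = "pearson",
    rule: str = "peak",
) -> RankSelectionReport:
    """Split-half stability rank selection.

    For each candidate rank, subjects are split at random into halves
    n_splits times; the factorization is fitted in each half and networks are
    matched across halves by the chosen similarity.  The default metric is
    the Pearson correlation of matched network maps: centering removes the
    shared positive baseline of non-negative maps, which otherwise keeps raw
    cosine similarity high even for over-factorized solutions and makes the
    stability curve uninformative.

    Selection rule "peak" (default): the largest candidate at which the
    stability curve has a local maximum >= threshold.  Very low ranks are
    generically stable (gross merges are trivially reproducible) and
    over-factorized ranks decay gradually, so a reproducible decomposition
    announces itself as the last peak above the reliability bar.  Rule
    "largest" takes the largest candidate with stability >= threshold.  If
    no rank qualifies, the report is flagged and the smallest candidate
    returned with a warning.
    """
    X = np.asarray(X, dtype=float)
    V, N = X.shape
    candidate_ranks = sorted(int(r) for r in candidate_ranks)
    if n_splits < 2:
        raise ValueError("n_splits must be >= 2")
    half = N // 2
    for r in candidate_ranks:
        if r > min(V, half):
            raise ValueError(f"candidate rank {r} too large for half-sample of {half}")
    rng = np.random.default_rng(seed)
    split_perms = [rng.permutation(N) for _ in range(n_splits)]

    recon_errors: dict[int, float] = {}
    stability: dict[int, float] = {}
    for r in candidate_ranks:
        full = fit_nnmf(X, r, seed=seed, max_iter=max_iter, tol=tol)
        recon_errors[r] = full.recon_error
        sims = []
        for s, perm in enumerate(split_perms):
            Xa, Xb = X[:, perm[:half]], X[:, perm[half : 2 * half]]
            ma = fit_nnmf(Xa, r, seed=seed + 1000 * (s + 1), max_iter=max_iter, tol=tol)
            mb = fit_nnmf(Xb, r, seed=seed + 1000 * (s + 1) + 1, max_iter=max_iter, tol=tol)
            _, pair_sims = match_networks(ma.W, mb.W, metric=metric)
            sims.append(float(np.mean(pair_sims)))
        stability[r] = float(np.mean(sims))

    if rule == "peak":
        stable = []
        for i, r in enumerate(candidate_ranks):
            v = stability[r]
            left = stability[candidate_ranks[i - 1]] if i > 0 else -np.inf
            right = stability[candidate_ranks[i + 1]] if i < len(candidate_ranks) - 1 else -np.inf
            if v >= threshold and v >= left and v >= right:
                stable.append(r)
    elif rule == "largest":
        stable = [r for r in candidate_ranks if stability[r] >= threshold]
    else:
        raise ValueError(f"unknown rule {rule!r}")
    if stable:
        selected = max(stable)
        flag = False
    else:
        selected = min(candidate_ranks)
        flag = True
        warnings.warn(
            "no candidate rank reached the stability threshold; "
            f"falling back to the smallest candidate ({selected})",
            stacklevel=2,
        )
    return RankSelectionReport(
        candidate_ranks=candidate_ranks,
        recon_errors=recon_errors,
        stability=stability,
        selected_rank=selected,
        n_splits=n_splits,
        threshold=threshold,
        no_stable_rank=flag,
    )


def scn_volumes(
    logJ_matrix: np.ndarray,
    W: np.ndarray,
    subject_ids: list[str] | None = None,
    normalize: str = "weights",
):
    """Weighted mean log-Jacobian per subject per network.

    value[n, j] = sum_v W[v, j] * logJ[v, n] / sum_v W[v, j] — each subject's
    log-Jacobian map averaged with every voxel weighted by its relative
    contribution to the network.  The log-domain (pre-exponentiation) matrix
    is used, so a network with uniform weights yields the plain mean
    log-Jacobian over the mask.  normalize="voxels" divides by V instead of
    the weight sum (plain average of the weighted map).
    """
    import pandas as pd

    logJ = np.asarray(logJ_matrix, dtype=float)
    W = np.asarray(W, dtype=float)
    if logJ.shape[0] != W.shape[0]:
        raise ValueError("voxel dimension mismatch between matrix and W")
    colsum = W.sum(axis=0)
    if np.any(colsum <= 0):
        raise ValueError("network column with all-zero weights")
    if normalize == "weights":
        denom = colsum
    elif normalize == "voxels":
        denom = np.full(W.shape[1], W.shape[0], dtype=float)
    else:
        raise ValueError(f"unknown normalize {normalize!r}")
    values = (logJ.T @ W) / denom  # N x k
    if subject_ids is None:
        subject_ids = [f"S{i:04d}" for i in range(values.shape[0])]
    cols = [f"scn_{j + 1}" for j in range(W.shape[1])]
    return pd.DataFrame(values, index=list(subject_ids), columns=cols)


def threshold_network(W_column: np.ndarray, fraction: float = 0.25) -> np.ndarray:
    """Binary support map: keep voxels with weight >= min + fraction * range."""
    w = np.asarray(W_column, dtype=float)
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    lo, hi = w.min(), w.max()
    if hi == lo:
        raise ValueError("constant network column cannot be thresholded")
    return w >= lo + fraction * (hi - lo)
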