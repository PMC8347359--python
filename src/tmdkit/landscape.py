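"""Conformational-landscape analysis.

The sampled ensemble is summarised in four steps that mirror standard
practice for long MD trajectories of transporters:

1. an all-vs-all Cα RMSD matrix (each pair superposed independently),
2. classical (Torgerson) multidimensional scaling of that matrix to 2-D,
3. Gaussian-mixture clustering of the embedding, with the number of
   clusters selected by the Bayesian Information Criterion, and
4. essential-dynamics PCA of the aligned Cα coordinates, with projection of
   other ensembles onto the leading modes.

The Gaussian-mixture EM is implemented here (full 2x2 covariances,
kmeans++-style restarts) so that the per-iteration log-likelihood trail is
available for auditing EM monotonicity; scikit-learn's mixture model serves
as an independent cross-check in the test suite, not as the implementation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import eigh
from sklearn.cluster import kmeans_plusplus

from .core_model import TrajectoryEnsemble, kabsch_superpose, superpose_frames

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# RMSD matrix
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrix:
    """Symmetric F × F matrix of pairwise Cα RMSD (Å)."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.diag(v) != 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(v < 0):
            raise ValueError("negative distances")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]


def rmsd_matrix(
    ens: TrajectoryEnsemble,
    selection: Sequence[int] | None = None,
    stride: int = 1,
) -> DistanceMatrix:
    """All-vs-all Cα RMSD with independent pairwise superposition.

    Entry (i, j) is the RMSD of frame i onto frame j after a Kabsch fit of
    that pair alone (no common reference), so the matrix is symmetric but
    need not satisfy the triangle inequality.
    """
    if selection is None:
        selection = ens.topology.protein_residues
    else:
        selection = list(selection)
    if len(selection) < 3:
        raise ValueError("RMSD matrix needs at least 3 selected residues")
    x = ens.ca_coords(selection)[::stride]
    F, N = x.shape[0], x.shape[1]
    xc = x - x.mean(axis=1, keepdims=True)
    ssq = (xc ** 2).sum(axis=(1, 2))
    ii, jj = np.triu_indices(F, k=1)
    d = np.zeros((F, F))
    # closed-form Kabsch RMSD from the singular values of the 3x3
    # cross-covariance (smallest singular value sign-flipped on reflection)
    for start in range(0, len(ii), 4096):
        sl = slice(start, start + 4096)
        a, b = ii[sl], jj[sl]
        C = np.einsum("pni,pnj->pij", xc[a], xc[b])
        s = np.linalg.svd(C, compute_uv=False)
        s[:, -1] *= np.sign(np.linalg.det(C))
        msd = (ssq[a] + ssq[b] - 2.0 * s.sum(axis=1)) / N
        d[a, b] = d[b, a] = np.sqrt(np.clip(msd, 0.0, None))
    return DistanceMatrix(d)


# ---------------------------------------------------------------------------
# Classical MDS
# ---------------------------------------------------------------------------


@dataclass
class Embedding:
    """Low-dimensional MDS coordinates plus the MDS operator's spectrum."""

    points: np.ndarray  # F x dims
    eigenvalues: np.ndarray  # full spectrum, descending

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)

    @property
    def n(self) -> int:
        return self.points.shape[0]


def classical_mds(D: DistanceMatrix | np.ndarray, dims: int = 2) -> Embedding:
    """Torgerson classical scaling of a distance matrix.

    Double-centers −½·D² and embeds with the top ``dims`` eigenpairs.
    Negative eigenvalues (the matrix not being exactly Euclidean, as is
    normal for pairwise-superposed RMSD) are truncated to zero with a
    logged warning.
    """
    d = D.values if isinstance(D, DistanceMatrix) else np.asarray(D, dtype=float)
    F = d.shape[0]
    if dims > F:
        raise ValueError(f"cannot embed {F} points in {dims} dimensions")
    J = np.eye(F) - np.ones((F, F)) / F
    B = -0.5 * J @ (d ** 2) @ J
    B = 0.5 * (B + B.T)
    evals, evecs = eigh(B)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    if np.any(evals < -1e-9 * max(1.0, abs(evals[0]))):
        logger.warning(
            "MDS operator has negative eigenvalues (min %.3g); "
            "distance matrix is non-Euclidean, truncating to zero",
            float(evals.min()),
        )
    top = np.clip(evals[:dims], 0.0, None)
    points = evecs[:, :dims] * np.sqrt(top)
    points = points - points.mean(axis=0)  # numerically exact centering
    return Embedding(points=points, eigenvalues=evals)


# ---------------------------------------------------------------------------
# Gaussian mixture with BIC selection
# ---------------------------------------------------------------------------


@dataclass
class ClusterModel:
    """Fitted 2-D Gaussian mixture over an embedding."""

    K: int
    weights: np.ndarray
    means: np.ndarray  # K x d
    covariances: np.ndarray  # K x d x d
    responsibilities: np.ndarray  # F x K
    labels: np.ndarray  # F
    log_likelihood: float
    bic: float
    ll_history: list[float] = field(default_factory=list)

    def __post_init__(self):
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if np.any(self.weights < 0):
            raise ValueError("negative mixture weight")


def gmm_n_params(K: int, d: int = 2) -> int:
    """Free parameters of a K-component full-covariance mixture in d dims:
    K−1 mixture weights, K·d means, K·d(d+1)/2 covariance entries."""
    return (K - 1) + K * d + K * (d * (d + 1) // 2)


def _log_gauss_all(X: np.ndarray, means: np.ndarray, covs: np.ndarray) -> np.ndarray:
    """F × K log-densities of every point under every component."""
    F, d = X.shape
    K = means.shape[0]
    if d == 2:
        # closed-form 2x2 inverse, vectorised over components
        a = covs[:, 0, 0]
        b = covs[:, 0, 1]
        c = covs[:, 1, 1]
        det = a * c - b * b
        dx = X[:, None, 0] - means[None, :, 0]
        dy = X[:, None, 1] - means[None, :, 1]
        maha = (c * dx * dx - 2.0 * b * dx * dy + a * dy * dy) / det
        return -0.5 * (d * np.log(2.0 * np.pi) + np.log(det)[None, :] + maha)
    out = np.empty((F, K))
    for k in range(K):
        chol = np.linalg.cholesky(covs[k])
        dev = X - means[k]
        sol = np.linalg.solve(chol, dev.T)
        out[:, k] = -0.5 * (
            d * np.log(2.0 * np.pi)
            + 2.0 * np.log(np.diag(chol)).sum()
            + (sol ** 2).sum(axis=0)
        )
    return out


def _ensure_spd(covs: np.ndarray, ridge: float) -> np.ndarray:
    """Add ridge; bump any non-positive-definite component with a warning."""
    d = covs.shape[1]
    covs = covs + ridge * np.eye(d)
    if d == 2:
        det = covs[:, 0, 0] * covs[:, 1, 1] - covs[:, 0, 1] ** 2
        bad = (det <= 0) | (covs[:, 0, 0] <= 0)
    else:
        bad = np.zeros(covs.shape[0], dtype=bool)
        for k in range(covs.shape[0]):
            try:
                np.linalg.cholesky(covs[k])
            except np.linalg.LinAlgError:
                bad[k] = True
    if np.any(bad):
        warnings.warn(
            "singular mixture covariance; applying 1e-6 ridge", stacklevel=3
        )
        covs[bad] += 1e-6 * np.eye(d)
    return covs


def _em_once(
    X: np.ndarray,
    K: int,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
    ridge: float,
):
    F, d = X.shape
    centers, _ = kmeans_plusplus(
        X, n_clusters=K, random_state=int(rng.integers(2 ** 31 - 1))
    )
    assign = np.argmin(
        ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2), axis=1
    )
    weights = np.full(K, 1.0 / K)
    means = centers.astype(float).copy()
    global_cov = np.cov(X.T) + ridge * np.eye(d)
    covs = np.empty((K, d, d))
    for k in range(K):
        pts = X[assign == k]
        if len(pts) > d:
            covs[k] = np.cov(pts.T) + ridge * np.eye(d)
        else:
            covs[k] = global_cov
        weights[k] = max(len(pts), 1) / F
    weights = weights / weights.sum()

    covs = _ensure_spd(covs, ridge)
    ll_history: list[float] = []
    prev_ll = -np.inf
    log_resp = None
    for _ in range(max_iter):
        # E step
        log_joint = np.log(weights + 1e-300)[None, :] + _log_gauss_all(X, means, covs)
        m = log_joint.max(axis=1)
        log_norm = m + np.log(np.exp(log_joint - m[:, None]).sum(axis=1))
        ll = float(log_norm.sum())
        ll_history.append(ll)
        log_resp = log_joint - log_norm[:, None]
        if np.isfinite(prev_ll) and abs(ll - prev_ll) < tol * abs(prev_ll):
            break
        prev_ll = ll
        # M step
        resp = np.exp(log_resp)
        nk = resp.sum(axis=0) + 1e-12
        weights = nk / F
        means = (resp.T @ X) / nk[:, None]
        dev = X[:, None, :] - means[None, :, :]  # F x K x d
        covs = np.einsum("fk,fki,fkj->kij", resp, dev, dev) / nk[:, None, None]
        covs = _ensure_spd(covs, ridge)
    resp = np.exp(log_resp)
    return weights, means, covs, resp, ll_history


def fit_gmm(
    emb: Embedding | np.ndarray,
    K: int,
    n_starts: int = 5,
    seed: int | None = None,
    max_iter: int = 500,
    tol: float = 1e-8,
    ridge: float = 1e-6,
) -> ClusterModel:
    """Fit a K-component full-covariance Gaussian mixture by EM.

    The best of ``n_starts`` kmeans++-style initialisations (by final
    log-likelihood) is returned.  BIC = p·ln(F) − 2·logL with p the free
    parameter count of the mixture.
    """
    X = emb.points if isinstance(emb, Embedding) else np.asarray(emb, dtype=float)
    F, d = X.shape
    if K < 1:
        raise ValueError("K must be >= 1")
    if F < K:
        raise ValueError(f"cannot fit {K} components to {F} points")
    rng = np.random.default_rng(seed)
    best = None
    best_degenerate = None
    for _ in range(max(1, n_starts)):
        fit = _em_once(X, K, rng, max_iter, tol, ridge)
        ll = fit[-1][-1]
        # a full covariance needs at least d+1 points of support; a fit
        # whose component collapses below that is a likelihood singularity,
        # not a better model — prefer non-degenerate restarts
        nk = fit[3].sum(axis=0)
        degenerate = bool(np.any(nk < d + 1))
        if degenerate:
            if best_degenerate is None or ll > best_degenerate[-1][-1]:
                best_degenerate = fit
        elif best is None or ll > best[-1][-1]:
            best = fit
    if best is None:
        warnings.warn(
            "all EM restarts produced a degenerate component; "
            "returning the best of them",
            stacklevel=2,
        )
        best = best_degenerate
    weights, means, covs, resp, ll_history = best
    ll = ll_history[-1]
    bic = gmm_n_params(K, X.shape[1]) * np.log(F) - 2.0 * ll
    return ClusterModel(
        K=K,
        weights=weights,
        means=means,
        covariances=covs,
        responsibilities=resp,
        labels=np.argmax(resp, axis=1),
        log_likelihood=ll,
        bic=float(bic),
        ll_history=ll_history,
    )


def select_k_bic(
    emb: Embedding | np.ndarray,
    k_range: Sequence[int] = tuple(range(1, 11)),
    n_starts: int = 5,
    seed: int | None = None,
) -> ClusterModel:
    """Fit every K in ``k_range`` and return the model with the smallest
    BIC (ties broken toward the smallest K)."""
    if len(k_range) == 0:
        raise ValueError("k_range must be non-empty")
    best = None
    rng = np.random.default_rng(seed)
    for K in sorted(k_range):
        model = fit_gmm(emb, K, n_starts=n_starts, seed=int(rng.integers(2 ** 31 - 1)))
        if best is None or model.bic < best.bic:
            best = model
    return best


# ---------------------------------------------------------------------------
# Essential-dynamics PCA
# ---------------------------------------------------------------------------


@dataclass
class PCModel:
    """Principal components of the aligned Cα coordinate fluctuations."""

    mean_structure: np.ndarray  # R x 3
    eigenvectors: np.ndarray  # 3R x n_modes (columns orthonormal)
    eigenvalues: np.ndarray  # Å², descending
    selection: list[int]

    @property
    def cumulative_variance(self) -> np.ndarray:
        total = self.eigenvalues.sum()
        if total <= 0:
            return np.zeros_like(self.eigenvalues)
        return np.cumsum(self.eigenvalues) / total


def fit_pca(
    ens: TrajectoryEnsemble,
    selection: Sequence[int] | None = None,
) -> PCModel:
    """Essential-dynamics PCA of the Cα coordinates.

    Frames are first aligned to the last frame, averaged to obtain the
    reference, re-aligned to that mean, and the 3R × 3R covariance of the
    aligned coordinates is eigendecomposed.
    """
    if ens.n_frames < 2:
        raise ValueError("PCA needs at least 2 frames")
    if selection is None:
        selection = ens.topology.protein_residues
    else:
        selection = list(selection)
    x = ens.ca_coords(selection)  # F x R x 3
    x = superpose_frames(x, x[-1])
    mean = x.mean(axis=0)
    # re-align to the mean until it is self-consistent
    for _ in range(50):
        x = superpose_frames(x, mean)
        new_mean = x.mean(axis=0)
        shift = float(np.sqrt(((new_mean - mean) ** 2).sum(axis=1).mean()))
        mean = new_mean
        if shift < 1e-10:
            break
    flat = (x - mean).reshape(ens.n_frames, -1)
    cov = flat.T @ flat / flat.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    return PCModel(
        mean_structure=mean,
        eigenvectors=evecs,
        eigenvalues=evals,
        selection=list(selection),
    )


def project_onto(
    model: PCModel,
    ens2: TrajectoryEnsemble,
    n_components: int = 3,
) -> np.ndarray:
    """Project another ensemble onto the leading principal components.

    Each frame of ``ens2`` (same residue selection as the model) is aligned
    to the model's mean structure and its displacement is dotted with the
    eigenvectors; returns an F₂ × n_components array.
    """
    idx = ens2.topology.ca_indices(model.selection)
    if len(idx) != model.mean_structure.shape[0]:
        raise ValueError(
            f"selection size {len(idx)} does not match model "
            f"({model.mean_structure.shape[0]} residues)"
        )
    x = ens2.coords[:, idx, :]
    x = superpose_frames(x, model.mean_structure)
    flat = (x - model.mean_structure).reshape(x.shape[0], -1)
    return flat @ model.eigenvectors[:, :n_components]


def bhattacharyya_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Bhattacharyya distance between two point clouds under Gaussian
    approximations — used to test that a projected ensemble overlaps the
    training ensemble."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    mu_a, mu_b = a.mean(axis=0), b.mean(axis=0)
    cov_a = np.cov(a.T) + 1e-9 * np.eye(a.shape[1])
    cov_b = np.cov(b.T) + 1e-9 * np.eye(b.shape[1])
    cov = 0.5 * (cov_a + cov_b)
    dmu = mu_a - mu_b
    term1 = 0.125 * dmu @ np.linalg.solve(cov, dmu)
    term2 = 0.5 * np.log(
        np.linalg.det(cov) / np.sqrt(np.linalg.det(cov_a) * np.linalg.det(cov_b))
    )
    return float(term1 + term2)
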