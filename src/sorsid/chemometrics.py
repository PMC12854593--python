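"""Multivariate analysis: PCA, KNN in score space, confidence ellipses, and
non-negative multivariate curve resolution (MCR-ALS).

These are the analysis primitives of the package and are implemented
directly (mean-centered SVD, exhaustive-distance KNN, alternating
non-negative least squares) rather than wrapped from a general-purpose ML
library, so that every numerical choice — sign conventions, tie-breaks,
initialization — is pinned down and testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.optimize import nnls

__all__ = [
    "PCAModel",
    "KNNModel",
    "Ellipse95",
    "MCRModel",
    "ContainerAssignment",
    "fit_pca",
    "project",
    "reconstruct",
    "confidence_ellipse",
    "knn_classify",
    "fit_mcr",
    "match_components_to_materials",
    "assign_container",
    "cosine_similarity",
]


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(a @ b / (na * nb))


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAModel:
    mean_spectrum: np.ndarray
    loadings: np.ndarray  # (n_components, n_features), rows orthonormal
    explained_variance: np.ndarray  # fraction of total variance per PC
    n_components: int

    def __post_init__(self):
        gram = self.loadings @ self.loadings.T
        if not np.allclose(gram, np.eye(self.n_components), atol=1e-8):
            raise ValueError("loadings are not orthonormal")
        if np.any(np.diff(self.explained_variance) > 1e-12):
            raise ValueError("explained variance must be non-increasing")


def fit_pca(spectra: np.ndarray, n_components: int) -> PCAModel:
    """Mean-centered SVD; loadings sign-fixed so each loading's
    largest-magnitude element is positive."""
    X = np.asarray(spectra, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    n, p = X.shape
    max_rank = min(n - 1, p)
    if n_components > max_rank:
        raise ValueError(
            f"n_components={n_components} exceeds max rank {max_rank} "
            f"for a {n}x{p} matrix"
        )
    mean = X.mean(axis=0)
    Xc = X - mean
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    total = var.sum()
    frac = var / total if total > 0 else var
    loadings = Vt[:n_components].copy()
    for row in loadings:
        j = int(np.argmax(np.abs(row)))
        if row[j] < 0:
            row *= -1.0
    return PCAModel(
        mean_spectrum=mean,
        loadings=loadings,
        explained_variance=frac[:n_components],
        n_components=n_components,
    )


def project(pca: PCAModel, spectra: np.ndarray) -> np.ndarray:
    """Scores: (x - mean) @ loadings.T.  Accepts one spectrum or a matrix."""
    X = np.asarray(spectra, dtype=float)
    single = X.ndim == 1
    X = np.atleast_2d(X)
    if X.shape[1] != pca.mean_spectrum.size:
        raise ValueError(
            f"spectra have {X.shape[1]} points but the model expects "
            f"{pca.mean_spectrum.size}; resample onto the model axis"
        )
    scores = (X - pca.mean_spectrum) @ pca.loadings.T
    return scores[0] if single else scores


def reconstruct(pca: PCAModel, scores: np.ndarray) -> np.ndarray:
    return np.atleast_2d(scores) @ pca.loadings + pca.mean_spectrum


# ---------------------------------------------------------------------------
# Confidence ellipses
# ---------------------------------------------------------------------------

@dataclass
class Ellipse95:
    label: str
    center: np.ndarray
    covariance: np.ndarray
    level: float = 0.95

    @property
    def mahalanobis_radius2(self) -> float:
        """Squared Mahalanobis radius of the ellipse boundary."""
        return float(stats.chi2.ppf(self.level, df=2))

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float)) - self.center
        cov_inv = np.linalg.pinv(self.covariance)
        d2 = np.einsum("ij,jk,ik->i", pts, cov_inv, pts)
        return d2 <= self.mahalanobis_radius2


def confidence_ellipse(scores_2d: np.ndarray, level: float = 0.95,
                       label: str = "") -> Ellipse95:
    """Gaussian confidence ellipse of a 2-D score cloud.

    Boundary at Mahalanobis radius sqrt(chi2.ppf(level, 2)) around the mean
    with the empirical covariance (PSD-guarded for degenerate clouds).
    """
    pts = np.asarray(scores_2d, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("scores_2d must be (n, 2)")
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 points for a confidence ellipse")
    center = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False)
    # PSD guard: clip tiny negative eigenvalues from round-off
    w, v = np.linalg.eigh(cov)
    cov = (v * np.clip(w, 0.0, None)) @ v.T
    return Ellipse95(label=label, center=center, covariance=cov, level=level)


# ---------------------------------------------------------------------------
# KNN in PCA space
# ---------------------------------------------------------------------------

@dataclass
class KNNModel:
    training_scores: np.ndarray  # (n_train, n_components)
    training_labels: np.ndarray  # (n_train,), str
    k: int = 4

    def __post_init__(self):
        self.training_scores = np.asarray(self.training_scores, dtype=float)
        self.training_labels = np.asarray(self.training_labels)
        n = self.training_scores.shape[0]
        if n == 0:
            raise ValueError("empty training set")
        if not 1 <= self.k <= n:
            raise ValueError(f"k={self.k} must be in [1, {n}]")


@dataclass
class KNNVote:
    label: str
    neighbor_distances: np.ndarray
    neighbor_labels: np.ndarray
    mean_distance: float
    votes: dict
    class_mean_distance: dict


def knn_classify(model: KNNModel, query_scores: np.ndarray) -> KNNVote:
    """Majority vote among the k nearest training points (Euclidean).

    Ties are broken by the smallest mean neighbor distance within the tied
    classes, then lexicographically by label.
    """
    q = np.asarray(query_scores, dtype=float).ravel()
    if q.size != model.training_scores.shape[1]:
        raise ValueError("query dimensionality does not match training scores")
    d = np.linalg.norm(model.training_scores - q, axis=1)
    order = np.argsort(d, kind="stable")
    nn = order[: model.k]
    nn_labels = model.training_labels[nn]
    nn_dist = d[nn]
    votes: dict[str, int] = {}
    dist_by_class: dict[str, list[float]] = {}
    for lab, dist in zip(nn_labels, nn_dist):
        votes[str(lab)] = votes.get(str(lab), 0) + 1
        dist_by_class.setdefault(str(lab), []).append(float(dist))
    class_mean = {lab: float(np.mean(v)) for lab, v in dist_by_class.items()}
    max_votes = max(votes.values())
    tied = [lab for lab, v in votes.items() if v == max_votes]
    winner = min(tied, key=lambda lab: (class_mean[lab], lab))
    return KNNVote(
        label=winner,
        neighbor_distances=nn_dist,
        neighbor_labels=nn_labels,
        mean_distance=float(nn_dist.mean()),
        votes=votes,
        class_mean_distance=class_mean,
    )


def loo_mean_knn_distances(model: KNNModel) -> np.ndarray:
    """Leave-one-out mean k-neighbor distance per training point (used to
    anchor the out-of-calibration threshold)."""
    X = model.training_scores
    n = X.shape[0]
    k = min(model.k, n - 1)
    d = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=2)
    np.fill_diagonal(d, np.inf)
    part = np.sort(d, axis=1)[:, :k]
    return part.mean(axis=1)


# ---------------------------------------------------------------------------
# MCR-ALS (non-negative)
# ---------------------------------------------------------------------------

@dataclass
class MCRModel:
    component_spectra: np.ndarray  # S: (n_components, n_features), >= 0
    scores: np.ndarray  # C: (n_samples, n_components), >= 0
    n_components: int
    n_iterations: int
    converged: bool
    final_change: float
    reconstruction_error: float  # relative Frobenius
    error_history: list = field(default_factory=list)

    def __post_init__(self):
        if np.any(self.component_spectra < 0) or np.any(self.scores < 0):
            raise ValueError("MCR factors must be non-negative")


def _nndsvd_init(X: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic SVD-based non-negative initialization (NNDSVDa)."""
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    n, p = X.shape
    C = np.zeros((n, k))
    S = np.zeros((k, p))
    C[:, 0] = np.sqrt(s[0]) * np.abs(U[:, 0])
    S[0] = np.sqrt(s[0]) * np.abs(Vt[0])
    for j in range(1, min(k, s.size)):
        u, v = U[:, j], Vt[j]
        up, un = np.clip(u, 0, None), np.clip(-u, 0, None)
        vp, vn = np.clip(v, 0, None), np.clip(-v, 0, None)
        n_up, n_vp = np.linalg.norm(up), np.linalg.norm(vp)
        n_un, n_vn = np.linalg.norm(un), np.linalg.norm(vn)
        if n_up * n_vp >= n_un * n_vn:
            sigma = n_up * n_vp
            cu, cv = up / max(n_up, 1e-30), vp / max(n_vp, 1e-30)
        else:
            sigma = n_un * n_vn
            cu, cv = un / max(n_un, 1e-30), vn / max(n_vn, 1e-30)
        C[:, j] = np.sqrt(s[j] * sigma) * cu
        S[j] = np.sqrt(s[j] * sigma) * cv
    mean = X.mean() if X.size else 0.0
    C[C == 0] = mean * 1e-2
    S[S == 0] = mean * 1e-2
    return C, S


def fit_mcr(
    spectra: np.ndarray,
    n_components: int = 6,
    tol: float = 1e-8,
    max_iter: int = 2000,
    seed: int = 0,
) -> MCRModel:
    """Non-negative MCR by alternating least squares.

    Rows with negative entries are min-shifted to non-negativity first.
    Starts from a deterministic SVD-based non-negative factorization (the
    seed only adds a vanishing jitter to break exact symmetry); alternates
    NNLS updates of scores and component spectra until the relative change
    of the reconstruction error drops below ``tol``.  Components are ordered
    by total score mass; component spectra are scaled to unit maximum.
    """
    X = np.asarray(spectra, dtype=float)
    if X.ndim != 2:
        raise ValueError("spectra must be a 2-D matrix")
    n, p = X.shape
    if n_components > min(n, p):
        raise ValueError(
            f"n_components={n_components} exceeds matrix dimensions {X.shape}; "
            "use fewer components"
        )
    row_min = X.min(axis=1, keepdims=True)
    X = X - np.minimum(row_min, 0.0)  # min-shift rows that go negative

    C, S = _nndsvd_init(X, n_components)
    rng = np.random.default_rng(seed)
    S = S + 1e-10 * S.max(initial=1.0) * rng.random(S.shape)

    norm_x = np.linalg.norm(X)
    if norm_x == 0.0:
        return MCRModel(S * 0, C * 0, n_components, 0, True, 0.0, 0.0)
    err_prev = np.inf
    err = np.linalg.norm(X - C @ S) / norm_x
    history = [err]
    it = 0
    change = np.inf
    for it in range(1, max_iter + 1):
        St = S.T
        for i in range(n):
            C[i], _ = nnls(St, X[i])
        for j in range(p):
            S[:, j], _ = nnls(C, X[:, j])
        err_prev, err = err, np.linalg.norm(X - C @ S) / norm_x
        history.append(err)
        change = abs(err_prev - err)
        if change < tol:
            break
    converged = change < tol

    # resolve scale indeterminacy (unit-max spectra) and order by score mass
    peak = S.max(axis=1)
    peak[peak == 0] = 1.0
    S = S / peak[:, None]
    C = C * peak[None, :]
    order = np.argsort(-C.sum(axis=0), kind="stable")
    return MCRModel(
        component_spectra=S[order],
        scores=C[:, order],
        n_components=n_components,
        n_iterations=it,
        converged=bool(converged),
        final_change=float(change),
        reconstruction_error=float(err),
        error_history=history,
    )


# ---------------------------------------------------------------------------
# Container assignment from MCR scores
# ---------------------------------------------------------------------------

@dataclass
class ContainerAssignment:
    material: str
    score: float
    margin: float


def match_components_to_materials(
    mcr: MCRModel, references: Mapping[str, np.ndarray]
) -> dict[int, str]:
    """Map each MCR component to the reference container profile with the
    highest cosine similarity to its spectrum."""
    mapping: dict[int, str] = {}
    for i, comp in enumerate(mcr.component_spectra):
        best, best_cos = "indeterminate", -np.inf
        for material, profile in references.items():
            c = cosine_similarity(comp, profile)
            if c > best_cos:
                best, best_cos = material, c
        mapping[i] = best
    return mapping


def assign_container(
    mcr: MCRModel, sample_index: int, material_map: Mapping[int, str]
) -> ContainerAssignment:
    """Label a sample by the material of its highest-scoring MCR component.

    An all-zero score row, or an exact tie between the two best components,
    yields 'indeterminate'."""
    row = mcr.scores[sample_index]
    if not np.any(row > 0):
        return ContainerAssignment("indeterminate", 0.0, 0.0)
    order = np.argsort(-row, kind="stable")
    best = order[0]
    margin = float(row[best] - (row[order[1]] if row.size > 1 else 0.0))
    if margin <= 0.0 and row.size > 1:
        return ContainerAssignment("indeterminate", float(row[best]), 0.0)
    return ContainerAssignment(
        str(material_map.get(int(best), "indeterminate")),
        float(row[best]),
        margin,
    )
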