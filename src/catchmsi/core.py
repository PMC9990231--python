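"""Estimation core of the covariate-adjusted tensor discriminant classifier.

The model: each sample carries a metabolite tensor M (d1 x d2), a covariate
vector G (q metabolic-gene expression values), and a binary outcome Y
(1 = MSS, 2 = MSI). Gene expression confounds the metabolite signal, so the
tensor is first adjusted,

    M_adj = M - alpha x3 G,

where ``alpha`` (d1 x d2 x q) is the within-class regression of every tensor
cell on G and ``x3`` contracts along the covariate axis. Classification is
the Bayes rule of a linear discriminant on (M_adj, G) under a tensor-normal
model with separable (row x column) covariance:

    score = a2 + gamma' G + <B, M_adj>,   predict MSI iff score > 0,

with ``B`` the sparse direct-effect tensor estimated by an l1-penalized
discriminant solved with cyclic coordinate descent, ``gamma`` the covariate
LDA direction, and ``a2`` the LDA intercept. Only the Bayes rule itself is
classical; every estimator here (moment estimators plus the penalized
coordinate-descent discriminant) is the package's completion of it.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cho_factor as _cho_factor, cho_solve as _cho_solve

__all__ = [
    "ConvergenceError",
    "estimate_alpha",
    "adjust",
    "estimate_moments",
    "lambda_max",
    "solve_sparse_discriminant",
    "fit_covariate_discriminant",
    "compute_intercept",
    "catch_score",
    "predict_from_score",
]


class ConvergenceError(RuntimeError):
    """Coordinate descent failed to converge within max_iter sweeps."""


def _class_masks(labels):
    labels = np.asarray(labels)
    if not np.isin(labels, (1, 2)).all():
        raise ValueError("labels must be coded 1 (MSS) / 2 (MSI)")
    m1, m2 = labels == 1, labels == 2
    if m1.sum() < 2 or m2.sum() < 2:
        raise ValueError("each class needs at least 2 samples")
    return m1, m2


def _center_within_class(X, m1, m2):
    Xc = X.astype(float).copy()
    Xc[m1] -= Xc[m1].mean(axis=0)
    Xc[m2] -= Xc[m2].mean(axis=0)
    return Xc


def _solve_spd(S, B, what: str, ridge: float = 0.0):
    """Solve S x = B for symmetric S, with optional ridge and a clear error."""
    q = S.shape[0]
    if ridge:
        S = S + ridge * np.eye(q)
    try:
        c, low = _cho_factor(S)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            f"{what} is singular or not positive definite; pass a ridge "
            "(e.g. ridge='auto') to regularize"
        ) from None
    return _cho_solve((c, low), B)


def estimate_alpha(tensors, covariates, labels, ridge: float = 0.0) -> np.ndarray:
    """Covariate coefficient tensor alpha_hat (d1, d2, q).

    Pooled within-class least squares of every tensor cell on G: class means
    are removed from both sides, so alpha captures the metabolite-gene
    relationship free of the class contrast. Equivalent to
    ``alpha[i, j, :] = S_G^-1 @ cov(G, M[i, j])`` with pooled moments.
    """
    tensors = np.asarray(tensors, dtype=float)
    covariates = np.asarray(covariates, dtype=float)
    n, d1, d2 = tensors.shape
    q = covariates.shape[1]
    if q == 0:
        return np.zeros((d1, d2, 0))
    if n <= q + 2 and not ridge:
        raise ValueError(
            f"n = {n} <= q + 2 = {q + 2}: covariate covariance not invertible; "
            "use a ridge"
        )
    m1, m2 = _class_masks(labels)
    Gc = _center_within_class(covariates, m1, m2)
    Mc = _center_within_class(tensors.reshape(n, d1 * d2), m1, m2)
    S = Gc.T @ Gc
    C = Gc.T @ Mc
    alpha_flat = _solve_spd(S, C, "pooled covariate covariance S_G", ridge=ridge)
    return alpha_flat.T.reshape(d1, d2, q)


def adjust(tensors, covariates, alpha) -> np.ndarray:
    """M_adj = M - alpha x3 G, per sample."""
    tensors = np.asarray(tensors, dtype=float)
    covariates = np.asarray(covariates, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    n, d1, d2 = tensors.shape
    if alpha.shape[2] == 0:
        return tensors.copy()
    contribution = covariates @ alpha.reshape(d1 * d2, -1).T
    return tensors - contribution.reshape(n, d1, d2)


def estimate_moments(adjusted, labels):
    """Class means, separable mode covariances, and priors.

    Returns ``(mu1, mu2, sigma1, sigma2, priors)``. The row covariance is the
    pooled outer product of residual rows, normalized to sigma1[0, 0] = 1 for
    identifiability; the column covariance is then a flip-flop step
    ``sigma2 = sum_s R_s' sigma1^-1 R_s / ((n - 2) d1)``, which puts the
    whole scale of the Kronecker product into sigma2.
    """
    adjusted = np.asarray(adjusted, dtype=float)
    n, d1, d2 = adjusted.shape
    m1, m2 = _class_masks(labels)
    mu1 = adjusted[m1].mean(axis=0)
    mu2 = adjusted[m2].mean(axis=0)
    R = adjusted.copy()
    R[m1] -= mu1
    R[m2] -= mu2
    S1 = np.einsum("nij,nkj->ik", R, R) / ((n - 2) * d2)
    scale = S1[0, 0]
    if scale <= 0 or not np.isfinite(scale):
        raise ValueError(
            "degenerate residuals: zero variance at cell (0, 0); "
            "are all samples duplicates?"
        )
    sigma1 = S1 / scale
    W = _solve_spd(sigma1, R.reshape(n, d1, d2).transpose(1, 0, 2).reshape(d1, -1),
                   "row covariance sigma1")
    W = W.reshape(d1, n, d2).transpose(1, 0, 2)
    sigma2 = np.einsum("nij,nik->jk", R, W) / ((n - 2) * d1)
    sigma2 = (sigma2 + sigma2.T) / 2.0
    priors = (float(m1.mean()), float(m2.mean()))
    return mu1, mu2, sigma1, sigma2, priors


def _check_pd(S, name):
    try:
        _cho_factor(S)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(f"{name} is not positive definite") from None


def lambda_max(mu1, mu2, mask=None) -> float:
    """Smallest l1 penalty at which the sparse discriminant is exactly zero
    (KKT subgradient condition at B = 0)."""
    D = np.abs(np.asarray(mu2, dtype=float) - np.asarray(mu1, dtype=float))
    if mask is not None:
        D = np.where(mask, 0.0, D)
    return float(D.max())


def _soft(x: float, t: float) -> float:
    if x > t:
        return x - t
    if x < -t:
        return x + t
    return 0.0


def solve_sparse_discriminant(mu1, mu2, sigma1, sigma2, penalty: float,
                              mask=None, tol: float = 1e-8,
                              max_iter: int = 10000, B0=None,
                              return_info: bool = False):
    """l1-penalized tensor discriminant by cyclic coordinate descent.

    Minimizes ``0.5 <B, sigma1 B sigma2> - <B, mu2 - mu1> + penalty * |B|_1``
    with the exact univariate soft-threshold update per cell; ``mask`` pins
    padded cells at zero. Convergence when the largest cell change in a sweep
    drops below ``tol``. With ``return_info=True`` also returns a dict with
    the per-sweep objective (non-increasing by construction) and sweep count.
    """
    sigma1 = np.asarray(sigma1, dtype=float)
    sigma2 = np.asarray(sigma2, dtype=float)
    D = np.asarray(mu2, dtype=float) - np.asarray(mu1, dtype=float)
    d1, d2 = D.shape
    if penalty < 0:
        raise ValueError("penalty must be >= 0")
    _check_pd(sigma1, "sigma1")
    _check_pd(sigma2, "sigma2")

    active = np.ones((d1, d2), dtype=bool)
    if mask is not None:
        active &= ~np.asarray(mask, dtype=bool)
    cells = [(i, j) for i in range(d1) for j in range(d2) if active[i, j]]

    B = np.zeros((d1, d2)) if B0 is None else np.asarray(B0, dtype=float).copy()
    B[~active] = 0.0
    T = sigma1 @ B @ sigma2
    denom = np.outer(np.diag(sigma1), np.diag(sigma2))

    def objective(Bm):
        return (0.5 * float(np.sum(Bm * (sigma1 @ Bm @ sigma2)))
                - float(np.sum(Bm * D)) + penalty * float(np.abs(Bm).sum()))

    history = []
    converged = False
    for sweep in range(max_iter):
        max_delta = 0.0
        for i, j in cells:
            partial = T[i, j] - denom[i, j] * B[i, j]
            new = _soft(D[i, j] - partial, penalty) / denom[i, j]
            db = new - B[i, j]
            if db != 0.0:
                B[i, j] = new
                T += db * np.outer(sigma1[:, i], sigma2[j, :])
                ad = abs(db)
                if ad > max_delta:
                    max_delta = ad
        if return_info:
            history.append(objective(B))
        if max_delta < tol:
            converged = True
            break
        if (sweep + 1) % 64 == 0:  # refresh T to cap accumulated drift
            T = sigma1 @ B @ sigma2
    if not converged:
        raise ConvergenceError(
            f"coordinate descent did not converge in {max_iter} sweeps; "
            f"last objective {objective(B):.6g}"
        )
    if return_info:
        return B, {"objective": history, "n_sweeps": sweep + 1}
    return B


def fit_covariate_discriminant(covariates, labels, ridge: float = 0.0):
    """Covariate LDA: ``gamma2 = Psi^-1 (phi2 - phi1)`` with pooled
    within-class covariance Psi; gamma1 = 0 by the reference-class
    convention. Returns ``(gamma2, phi1, phi2, psi)``."""
    G = np.asarray(covariates, dtype=float)
    n, q = G.shape
    if q == 0:
        return np.zeros(0), np.zeros(0), np.zeros(0), np.zeros((0, 0))
    if n <= q + 2 and not ridge:
        raise ValueError(
            f"n = {n} <= q + 2 = {q + 2}: pooled covariate covariance "
            "not invertible; use a ridge"
        )
    m1, m2 = _class_masks(labels)
    phi1, phi2 = G[m1].mean(axis=0), G[m2].mean(axis=0)
    Gc = _center_within_class(G, m1, m2)
    psi = Gc.T @ Gc / (n - 2)
    if ridge:
        psi = psi + ridge * np.eye(q)
    gamma = _solve_spd(psi, phi2 - phi1, "pooled covariate covariance Psi")
    return gamma, phi1, phi2, psi


def compute_intercept(B, mu1, mu2, gamma, phi1, phi2, priors) -> float:
    """LDA intercept a2 (a1 = 0 by convention):
    ``a2 = log(pi2/pi1) - 0.5 gamma'(phi1 + phi2) - 0.5 <B, mu1 + mu2>``."""
    pi1, pi2 = priors
    if pi1 <= 0 or pi2 <= 0:
        raise ValueError("both class priors must be positive")
    a2 = float(np.log(pi2 / pi1))
    if len(gamma):
        a2 -= 0.5 * float(gamma @ (np.asarray(phi1) + np.asarray(phi2)))
    a2 -= 0.5 * float(np.sum(np.asarray(B) * (np.asarray(mu1) + np.asarray(mu2))))
    return a2


def catch_score(tensors, covariates, alpha, B, gamma, intercept) -> np.ndarray:
    """Per-sample discriminant score a2 + gamma'G + <B, M_adj>."""
    adjusted = adjust(tensors, covariates, alpha)
    score = intercept + np.einsum("ij,nij->n", np.asarray(B, dtype=float), adjusted)
    gamma = np.asarray(gamma, dtype=float)
    if gamma.size:
        score = score + np.asarray(covariates, dtype=float) @ gamma
    return score


def predict_from_score(score) -> np.ndarray:
    """2 (MSI) where score > 0, else 1 (MSS); ties at exactly 0 go to MSS."""
    return np.where(np.asarray(score) > 0, 2, 1)
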