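"""Synthetic cohorts with the statistical structure the classifier assumes.

Each sample in a generated cohort has:

* a class label (1 = MSS control, 2 = MSI case) with fixed counts
  ``n_cases`` and ``control_ratio * n_cases`` (the matched-cohort design);
* stratum labels (lineage group, APC flag, TP53 flag) drawn from a
  class-specific frequency table — these exist to exercise matching and are
  independent of the molecular data given class;
* a covariate vector G ~ N(phi_k, I_q), whose class-dependent mean makes the
  genes genuine confounders;
* a metabolite tensor M = mu_k + alpha_true x3 G + E, with E matrix-normal
  with AR(1) row/column covariances (unit diagonal, so ``delta`` is an
  effect size in noise-sd units), a sparse class-mean difference
  mu_2 - mu_1 = delta * (alternating +/-1) on the s support cells, and a
  sparse alpha_true coupling tensor cells to genes.

The generator returns the cohort together with the :class:`GroundTruth`
parameters, so estimator-recovery and Bayes-consistency tests are exact.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .io import CODE_LABELS, CohortTable

__all__ = [
    "LINEAGES", "MUTATION_STATES", "SimulationConfig", "GroundTruth",
    "default_stratum_freqs", "generate_cohort", "make_confounded_feature",
    "support_cells", "support_f1",
]

LINEAGES = ("GI", "Breast/GYN", "Hema", "GU", "other")
MUTATION_STATES = ("M", "W")

# Matched-cohort composition of the study this emulates: lineage frequencies
# shared by both arms (GI 33.3%, breast/GYN 34.7%, hematologic 17.3%, the
# remainder split between GU and other), APC mutation 25.3% in cases vs
# 20.4% in controls, TP53 mutation 32% in both.
_LINEAGE_P = np.array([0.333, 0.347, 0.173, 0.0735, 0.0735])
_APC_M = {1: 0.204, 2: 0.253}
_TP53_M = {1: 0.32, 2: 0.32}


def default_stratum_freqs() -> np.ndarray:
    """Per-class joint probabilities over lineage x APC x TP53, shape
    (2, 5, 2, 2); axis 0 is class index (0 = MSS, 1 = MSI), mutation axes
    are ordered (M, W). Marginals are independent within class."""
    freqs = np.zeros((2, 5, 2, 2))
    for ci, k in enumerate((1, 2)):
        apc = np.array([_APC_M[k], 1 - _APC_M[k]])
        tp53 = np.array([_TP53_M[k], 1 - _TP53_M[k]])
        freqs[ci] = _LINEAGE_P[:, None, None] * apc[None, :, None] * tp53[None, None, :]
    return freqs


@dataclass
class SimulationConfig:
    """Generating parameters of a synthetic cohort.

    Defaults are the emulated study's conditions: 75 cases matched 1:3
    (n = 300), 225 metabolites folded 15 x 15, 87 covariate genes, 8 signal
    cells. ``delta`` is the class-mean difference per signal cell in
    noise-sd units; ``covariate_shift`` is the Euclidean norm of
    phi_2 - phi_1 and controls confounding strength; ``rho1``/``rho2`` are
    the AR(1) correlations of the row/column noise covariances.
    """

    n_cases: int = 75
    control_ratio: int = 3
    d1: int = 15
    d2: int = 15
    q: int = 87
    s: int = 8
    delta: float = 1.0
    alpha_density: float = 0.1
    alpha_scale: float = 0.3
    covariate_shift: float = 1.0
    rho1: float = 0.3
    rho2: float = 0.3
    stratum_freqs: np.ndarray = None
    seed: int = 0
    ridge_ok: bool = False
    confound_cell: tuple = None  # set via make_confounded_feature

    def __post_init__(self) -> None:
        if self.stratum_freqs is None:
            self.stratum_freqs = default_stratum_freqs()
        self.stratum_freqs = np.asarray(self.stratum_freqs, dtype=float)
        if self.stratum_freqs.shape != (2, len(LINEAGES), 2, 2):
            raise ValueError("stratum_freqs must have shape (2, 5, 2, 2)")
        sums = self.stratum_freqs.reshape(2, -1).sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-12):
            raise ValueError("stratum_freqs rows must sum to 1 within 1e-12")
        if self.n_cases < 1 or self.control_ratio < 1:
            raise ValueError("n_cases and control_ratio must be >= 1")
        if not (0 <= self.s <= self.d1 * self.d2):
            raise ValueError("need d1*d2 >= s >= 0")
        if not (0.0 <= self.alpha_density <= 1.0):
            raise ValueError("alpha_density must be in [0, 1]")
        if not (abs(self.rho1) < 1 and abs(self.rho2) < 1):
            raise ValueError("|rho1|, |rho2| must be < 1")
        if self.confound_cell is not None:
            i, j = self.confound_cell
            if not (0 <= i < self.d1 and 0 <= j < self.d2):
                raise ValueError(f"confound_cell {self.confound_cell} out of range")

    @property
    def n_samples(self) -> int:
        return self.n_cases * (1 + self.control_ratio)


def _ar1(rho: float, d: int) -> np.ndarray:
    idx = np.arange(d)
    return rho ** np.abs(idx[:, None] - idx[None, :])


@dataclass
class GroundTruth:
    """Generating parameters of a synthetic cohort, for recovery tests."""

    alpha_true: np.ndarray        # (d1, d2, q)
    B_true: np.ndarray            # (d1, d2) sparse direct-effect pattern
    mu1_true: np.ndarray
    mu2_true: np.ndarray
    phi1_true: np.ndarray
    phi2_true: np.ndarray
    Sigma1_true: np.ndarray
    Sigma2_true: np.ndarray
    priors_true: tuple

    @property
    def support(self) -> set:
        return support_cells(self.B_true)

    def bayes_discriminant(self) -> np.ndarray:
        """Population discriminant tensor Sigma1^-1 (mu2 - mu1) Sigma2^-1."""
        D = self.mu2_true - self.mu1_true
        return np.linalg.solve(
            self.Sigma1_true, np.linalg.solve(self.Sigma2_true, D.T).T
        )

    def bayes_rule(self):
        """(alpha, B, gamma, a2) of the population Bayes rule on (M, G)."""
        from . import core

        B = self.bayes_discriminant()
        gamma = self.phi2_true - self.phi1_true  # Psi = I_q
        a2 = core.compute_intercept(B, self.mu1_true, self.mu2_true, gamma,
                                    self.phi1_true, self.phi2_true,
                                    self.priors_true)
        return self.alpha_true, B, gamma, a2

    def mahalanobis_sq(self) -> float:
        D = self.mu2_true - self.mu1_true
        dphi = self.phi2_true - self.phi1_true
        return float(dphi @ dphi) + float(np.sum(D * self.bayes_discriminant()))

    def bayes_accuracy(self) -> float:
        """Closed-form accuracy of the population Bayes rule.

        The score is Gaussian within class with means c -/+ Delta^2/2 and
        variance Delta^2, where Delta^2 is the total Mahalanobis separation
        and c = log(pi2/pi1)."""
        pi1, pi2 = self.priors_true
        d2 = self.mahalanobis_sq()
        if d2 == 0:
            return max(pi1, pi2)
        delta = np.sqrt(d2)
        c = np.log(pi2 / pi1)
        return float(pi2 * norm.cdf((c + d2 / 2) / delta)
                     + pi1 * norm.cdf((d2 / 2 - c) / delta))


def support_cells(B: np.ndarray) -> set:
    return {(int(i), int(j)) for i, j in zip(*np.nonzero(B))}


def support_f1(selected, true) -> float:
    """Set-overlap F1 between selected and true support cells."""
    selected, true = set(map(tuple, selected)), set(map(tuple, true))
    if not selected and not true:
        return 1.0
    tp = len(selected & true)
    if tp == 0:
        return 0.0
    prec, rec = tp / len(selected), tp / len(true)
    return 2 * prec * rec / (prec + rec)


def generate_cohort(config: SimulationConfig):
    """Generate a cohort and its ground truth; deterministic given the seed.

    Returns ``(CohortTable, GroundTruth)``. Exactly ``n_cases`` samples are
    MSI and ``control_ratio * n_cases`` MSS, in seed-shuffled order, so the
    class priors are the design frequencies exactly.
    """
    cfg = config
    n, q = cfg.n_samples, cfg.q
    if q >= n and not cfg.ridge_ok:
        raise ValueError(
            f"q = {q} >= n = {n}: covariate covariance will not be invertible "
            "downstream; set ridge_ok=True to generate anyway"
        )
    rng = np.random.default_rng(cfg.seed)

    labels = np.concatenate([np.full(cfg.n_cases, 2),
                             np.full(cfg.n_cases * cfg.control_ratio, 1)])
    rng.shuffle(labels)

    # sparse direct-effect pattern: s support cells, alternating +/-1 signs
    flat_support = np.sort(rng.choice(cfg.d1 * cfg.d2, size=cfg.s, replace=False))
    if cfg.confound_cell is not None:
        flat_cc = cfg.confound_cell[0] * cfg.d2 + cfg.confound_cell[1]
        if flat_cc not in flat_support:
            flat_support[0] = flat_cc
            flat_support = np.sort(flat_support)
    B_pattern = np.zeros(cfg.d1 * cfg.d2)
    B_pattern[flat_support] = [(-1.0) ** k for k in range(len(flat_support))]
    B_pattern = B_pattern.reshape(cfg.d1, cfg.d2)

    mu1 = np.zeros((cfg.d1, cfg.d2))
    mu2 = cfg.delta * B_pattern

    phi1 = np.zeros(q)
    phi2 = (cfg.covariate_shift / np.sqrt(q)) * np.ones(q) if q else np.zeros(0)

    mask = rng.random((cfg.d1, cfg.d2, q)) < cfg.alpha_density
    signs = rng.choice([-1.0, 1.0], size=(cfg.d1, cfg.d2, q))
    alpha = cfg.alpha_scale * signs * mask

    if cfg.confound_cell is not None:
        i, j = cfg.confound_cell
        dphi = phi2 - phi1
        nrm = float(dphi @ dphi)
        if nrm == 0 or cfg.alpha_scale == 0:
            raise ValueError(
                "confounded feature needs covariate_shift != 0 and "
                "alpha_scale != 0"
            )
        # cancel the marginal contrast: alpha[cell] . (phi2 - phi1) = -(mu2-mu1)[cell]
        alpha[i, j, :] = -(mu2[i, j] - mu1[i, j]) * dphi / nrm

    Sigma1, Sigma2 = _ar1(cfg.rho1, cfg.d1), _ar1(cfg.rho2, cfg.d2)
    L1, L2 = np.linalg.cholesky(Sigma1), np.linalg.cholesky(Sigma2)

    is_case = labels == 2
    G = rng.standard_normal((n, q))
    G[is_case] += phi2
    G[~is_case] += phi1

    Z = rng.standard_normal((n, cfg.d1, cfg.d2))
    E = np.einsum("ik,nkl,jl->nij", L1, Z, L2)
    M = np.where(is_case[:, None, None], mu2, mu1)
    M = M + np.einsum("ijg,ng->nij", alpha, G) + E

    # stratum labels: drawn from the class-specific joint frequency table
    flat_freqs = cfg.stratum_freqs.reshape(2, -1)
    strat_idx = np.empty(n, dtype=int)
    for ci, m in ((0, ~is_case), (1, is_case)):
        strat_idx[m] = rng.choice(flat_freqs.shape[1], size=m.sum(),
                                  p=flat_freqs[ci] / flat_freqs[ci].sum())
    li, ai, ti = np.unravel_index(strat_idx, cfg.stratum_freqs.shape[1:])

    ids = pd.Index([f"S{k:04d}" for k in range(n)], name="sample_id")
    annotation = pd.DataFrame(
        {
            "label": [CODE_LABELS[int(l)] for l in labels],
            "lineage": [LINEAGES[k] for k in li],
            "apc": [MUTATION_STATES[k] for k in ai],
            "tp53": [MUTATION_STATES[k] for k in ti],
        },
        index=ids,
    )
    met_cols = [f"M{k:03d}" for k in range(cfg.d1 * cfg.d2)]
    gene_cols = [f"G{k:03d}" for k in range(q)]
    cohort = CohortTable(
        annotation=annotation,
        metabolites=pd.DataFrame(M.reshape(n, -1), index=ids, columns=met_cols),
        covariates=pd.DataFrame(G, index=ids, columns=gene_cols),
    )
    ratio = cfg.control_ratio
    truth = GroundTruth(
        alpha_true=alpha, B_true=B_pattern, mu1_true=mu1, mu2_true=mu2,
        phi1_true=phi1, phi2_true=phi2, Sigma1_true=Sigma1,
        Sigma2_true=Sigma2, priors_true=(ratio / (1 + ratio), 1 / (1 + ratio)),
    )
    return cohort, truth


def make_confounded_feature(config: SimulationConfig, cell) -> SimulationConfig:
    """Return a config whose marginal class contrast at ``cell`` is exactly
    cancelled by the covariates while the direct effect stays nonzero.

    The cell is forced into the support of B_true and alpha_true[cell, :] is
    set so ``alpha[cell] . (phi2 - phi1) = -(mu2 - mu1)[cell]``: the raw
    two-sample contrast at the cell is ~0 but the adjusted contrast is
    ``delta`` — the signature of a confounded metabolite feature.
    """
    i, j = cell
    if not (0 <= i < config.d1 and 0 <= j < config.d2):
        raise ValueError(f"cell {cell} outside {config.d1}x{config.d2} tensor")
    if config.alpha_scale == 0:
        raise ValueError("cancellation impossible with alpha_scale = 0")
    if config.covariate_shift == 0:
        raise ValueError("cancellation impossible with covariate_shift = 0")
    if config.delta == 0 or config.s == 0:
        raise ValueError("confounded feature needs delta != 0 and s >= 1")
    return dataclasses.replace(config, confound_cell=(int(i), int(j)))
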