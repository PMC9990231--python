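"""The :class:`CatchClassifier` estimator and its reporting helpers.

A scikit-learn-compatible classifier for covariate-adjusted tensor
discriminant analysis. The design matrix X holds, per sample, the p
metabolite columns followed by ``n_covariates`` gene-expression columns;
``fit`` standardizes the metabolite block (training data only), folds it
into d1 x d2 tensors, regresses every tensor cell on the covariates to
remove their confounding contribution, and estimates a sparse discriminant
on the adjusted tensors together with an LDA on the covariates themselves.

The l1 penalty can be fixed (``penalty=``), chosen by stratified K-fold
cross-validation (``cv=``), or bisected so that exactly ``n_features``
tensor cells are selected — the analogue of reporting a fixed-size metabolite
signature.
"""

from __future__ import annotations

import numbers
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from . import core
from .io import LABEL_CODES
from .tensorize import FeatureMap, default_dims

__all__ = ["CatchClassifier", "fit_catch", "select_features",
           "association_matrix", "feature_gene_correlations"]


def _coerce_labels(y):
    y = np.asarray(y)
    if y.dtype.kind in "OUS":
        try:
            return np.asarray([LABEL_CODES[str(v)] for v in y], dtype=int)
        except KeyError as exc:
            raise ValueError(
                f"string labels must be 'MSI'/'MSS', got {exc.args[0]!r}"
            ) from None
    y = y.astype(int)
    if set(np.unique(y)) <= {0, 1}:
        y = y + 1
    if not np.isin(y, (1, 2)).all():
        raise ValueError("numeric labels must be {1, 2} (or {0, 1})")
    return y


class CatchClassifier(ClassifierMixin, BaseEstimator):
    """Covariate-adjusted sparse tensor discriminant classifier.

    Parameters
    ----------
    d1, d2 : int, optional
        Tensor dimensions for folding the metabolite block; default is the
        square-ish ``ceil(sqrt(p))`` on both modes, with zero-padded,
        selection-excluded cells when ``d1*d2 > p``.
    n_covariates : int
        Number of trailing X columns that are confounding covariates
        (gene expression). 0 disables adjustment and the covariate
        discriminant, reducing the model to sparse tensor LDA.
    penalty : float, optional
        Fixed l1 penalty for the discriminant. Exactly one of ``penalty``,
        ``cv``, ``n_features`` drives the choice; with none given, 5-fold
        CV is used.
    cv : int, optional
        Number of stratified folds for penalty selection over
        ``n_penalties`` log-spaced values from lambda_max down to
        ``penalty_min_ratio * lambda_max`` (ties prefer the sparser model).
    n_features : int, optional
        Bisect the penalty so exactly this many cells are selected.
    standardize : bool
        z-score the metabolite block on the training data (default). Turn
        off when the input is already standardized.
    ridge : 'auto', float, or 0
        Regularization added to near-singular covariate covariances;
        'auto' uses ``1e-6 * trace/dim`` only when needed, and logs it.
    tol, max_iter : float, int
        Coordinate-descent stopping rule (max cell change) and sweep cap.
    random_state : int, optional
        Seeds the CV fold shuffle.

    Attributes (after fit)
    ----------------------
    alpha_ : (d1, d2, q) covariate coefficient tensor.
    B_ : (d1, d2) sparse direct-effect tensor (MSI relative to MSS).
    gamma_ : (q,) covariate discriminant direction.
    intercept_ : float, LDA intercept a2.
    priors_, mu1_, mu2_, sigma1_, sigma2_, psi_, phi1_, phi2_ : moments.
    penalty_ : the l1 penalty actually used.
    feature_map_ : metabolite-name <-> tensor-cell bijection.
    """

    def __init__(self, d1=None, d2=None, n_covariates=0, penalty=None,
                 cv=None, n_penalties=20, penalty_min_ratio=0.01,
                 n_features=None, standardize=True, ridge=0.0,
                 tol=1e-8, max_iter=10000, random_state=None):
        self.d1 = d1
        self.d2 = d2
        self.n_covariates = n_covariates
        self.penalty = penalty
        self.cv = cv
        self.n_penalties = n_penalties
        self.penalty_min_ratio = penalty_min_ratio
        self.n_features = n_features
        self.standardize = standardize
        self.ridge = ridge
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    # ------------------------------------------------------------------ fit

    def fit(self, X, y):
        Xm, G, feat_names, cov_names = self._split_design(X, fitting=True)
        y = _coerce_labels(y)
        if len(y) != Xm.shape[0]:
            raise ValueError("X and y disagree on n")
        if {1, 2} - set(np.unique(y)):
            raise ValueError("both classes must be present in y")
        self.classes_ = np.array([1, 2])
        self.covariate_names_ = cov_names

        Xm, feat_names = self._fit_scaler(Xm, feat_names)
        d1, d2 = (self.d1, self.d2)
        if d1 is None or d2 is None:
            d1, d2 = default_dims(Xm.shape[1])
        self.feature_map_ = FeatureMap(names=feat_names, d1=d1, d2=d2)
        tensors = self._fold(Xm)

        modes = (self.penalty is not None) + (self.cv is not None) + (
            self.n_features is not None)
        if modes > 1:
            raise ValueError("give at most one of penalty=, cv=, n_features=")

        if self.cv is not None or modes == 0:
            self.penalty_ = self._select_penalty_cv(
                tensors, G, y, n_folds=self.cv if self.cv is not None else 5)
        elif self.n_features is not None:
            self.penalty_ = self._select_penalty_count(tensors, G, y)
        else:
            if not isinstance(self.penalty, numbers.Real) or self.penalty < 0:
                raise ValueError("penalty must be a nonnegative number")
            self.penalty_ = float(self.penalty)

        parts = self._fit_components(tensors, G, y, self.penalty_,
                                     return_info=True)
        (self.alpha_, self.B_, self.gamma_, self.intercept_, self.priors_,
         self.mu1_, self.mu2_, self.sigma1_, self.sigma2_, self.phi1_,
         self.phi2_, self.psi_, self.objective_history_) = parts
        self.n_features_in_ = X.shape[1]
        return self

    # ------------------------------------------------------- fit internals

    def _split_design(self, X, fitting=False):
        if isinstance(X, pd.DataFrame):
            names = [str(c) for c in X.columns]
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            if X.ndim != 2:
                raise ValueError("X must be 2-dimensional")
            names = None
        q = int(self.n_covariates)
        p = X.shape[1] - q
        if p <= 0:
            raise ValueError(
                f"X has {X.shape[1]} columns but n_covariates = {q}")
        if not np.isfinite(X).all():
            raise ValueError("X contains non-finite values")
        if names is None:
            names = [f"m{k:03d}" for k in range(p)] + [f"g{k:03d}" for k in range(q)]
        if fitting:
            return X[:, :p], X[:, p:], names[:p], names[p:]
        return X[:, :p], X[:, p:], names[:p], names[p:]

    def _fit_scaler(self, Xm, names):
        if self.standardize:
            mean = Xm.mean(axis=0)
            sd = Xm.std(axis=0, ddof=1) if Xm.shape[0] > 1 else np.ones(Xm.shape[1])
            keep = sd > 0
            dropped = [n for n, k in zip(names, keep) if not k]
            if dropped:
                warnings.warn(
                    f"dropped {len(dropped)} constant metabolite column(s)",
                    stacklevel=2)
            self.scaler_mean_ = mean[keep]
            self.scaler_scale_ = sd[keep]
            self.dropped_features_ = dropped
            self._keep_mask = keep
            names = [n for n, k in zip(names, keep) if k]
            Xm = (Xm[:, keep] - self.scaler_mean_) / self.scaler_scale_
        else:
            self.scaler_mean_ = np.zeros(Xm.shape[1])
            self.scaler_scale_ = np.ones(Xm.shape[1])
            self.dropped_features_ = []
            self._keep_mask = np.ones(Xm.shape[1], dtype=bool)
        return Xm, names

    def _fold(self, Xm):
        fm = self.feature_map_
        flat = np.zeros((Xm.shape[0], fm.d1 * fm.d2))
        flat[:, :Xm.shape[1]] = Xm
        return flat.reshape(-1, fm.d1, fm.d2)

    def _ridge_eps(self, G, y):
        """Fallback ridge for near-singular covariate covariances:
        1e-6 * trace(S_G)/q on the pooled within-class covariance."""
        y = np.asarray(y)
        var = 0.0
        for k in (1, 2):
            Gk = G[y == k]
            var += float(((Gk - Gk.mean(axis=0)) ** 2).sum())
        q = max(G.shape[1], 1)
        return 1e-6 * var / max(len(y) - 2, 1) / q

    def _ridge_numeric(self):
        if isinstance(self.ridge, numbers.Real):
            return float(self.ridge)
        return 0.0

    def _estimate_alpha_safe(self, tensors, G, y):
        ridge = self._ridge_numeric()
        try:
            return core.estimate_alpha(tensors, G, y, ridge=ridge)
        except (ValueError, np.linalg.LinAlgError):
            if self.ridge != "auto":
                raise
            eps = self._ridge_eps(G, y)
            warnings.warn(f"covariate covariance near-singular; ridge {eps:.3g}",
                          stacklevel=2)
            return core.estimate_alpha(tensors, G, y, ridge=eps)

    def _fit_components(self, tensors, G, y, penalty, B0=None,
                        return_info=False):
        alpha = self._estimate_alpha_safe(tensors, G, y)
        adjusted = core.adjust(tensors, G, alpha)
        mu1, mu2, s1, s2, priors = core.estimate_moments(adjusted, y)
        mask = self.feature_map_.padded_mask
        out = core.solve_sparse_discriminant(
            mu1, mu2, s1, s2, penalty, mask=mask, tol=self.tol,
            max_iter=self.max_iter, B0=B0, return_info=return_info)
        if return_info:
            B, info = out
            history = info["objective"]
        else:
            B, history = out, None
        try:
            gamma, phi1, phi2, psi = core.fit_covariate_discriminant(
                G, y, ridge=self._ridge_numeric())
        except (ValueError, np.linalg.LinAlgError):
            if self.ridge != "auto":
                raise
            eps = self._ridge_eps(G, y)
            warnings.warn(f"Psi near-singular; ridge {eps:.3g}", stacklevel=2)
            gamma, phi1, phi2, psi = core.fit_covariate_discriminant(
                G, y, ridge=eps)
        a2 = core.compute_intercept(B, mu1, mu2, gamma, phi1, phi2, priors)
        return (alpha, B, gamma, a2, priors, mu1, mu2, s1, s2, phi1, phi2,
                psi, history)

    def _penalty_path(self, tensors, G, y):
        alpha = self._estimate_alpha_safe(tensors, G, y)
        adjusted = core.adjust(tensors, G, alpha)
        mu1, mu2, *_ = core.estimate_moments(adjusted, y)
        lmax = core.lambda_max(mu1, mu2, mask=self.feature_map_.padded_mask)
        if lmax == 0:
            return np.array([0.0])
        return np.geomspace(lmax, self.penalty_min_ratio * lmax,
                            self.n_penalties)

    def _select_penalty_cv(self, tensors, G, y, n_folds):
        path = self._penalty_path(tensors, G, y)
        if len(path) == 1:
            return float(path[0])
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                              random_state=self.random_state)
        acc = np.zeros(len(path))
        for tr, va in skf.split(tensors, y):
            B0 = None
            for k, lam in enumerate(path):
                parts = self._fit_components(tensors[tr], G[tr], y[tr], lam,
                                             B0=B0)
                alpha, B, gamma, a2 = parts[0], parts[1], parts[2], parts[3]
                B0 = B
                score = core.catch_score(tensors[va], G[va], alpha, B, gamma, a2)
                acc[k] += float((core.predict_from_score(score) == y[va]).mean())
        best = int(np.argmax(acc))  # path is descending: ties go to sparser
        return float(path[best])

    def _select_penalty_count(self, tensors, G, y):
        target = int(self.n_features)
        mask = self.feature_map_.padded_mask
        n_real = int((~mask).sum())
        if not (0 <= target <= n_real):
            raise ValueError(
                f"n_features must be in [0, {n_real}], got {target}")
        alpha = self._estimate_alpha_safe(tensors, G, y)
        adjusted = core.adjust(tensors, G, alpha)
        mu1, mu2, s1, s2, _ = core.estimate_moments(adjusted, y)
        lmax = core.lambda_max(mu1, mu2, mask=mask)
        if target == 0 or lmax == 0:
            return float(lmax)

        def count(lam):
            B = core.solve_sparse_discriminant(
                mu1, mu2, s1, s2, lam, mask=mask, tol=self.tol,
                max_iter=self.max_iter)
            return int(np.count_nonzero(B)), B

        lo, hi = 0.0, float(lmax)   # count(lo) >= count(hi) = 0
        best_lam, best_gap = hi, n_real + 1
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            c, _B = count(mid)
            gap = abs(c - target)
            if gap < best_gap or (gap == best_gap and mid > best_lam):
                best_lam, best_gap = mid, gap
            if c == target:
                return float(mid)
            if c > target:
                lo = mid
            else:
                hi = mid
        warnings.warn(
            f"could not bisect to exactly {target} features; using penalty "
            f"giving {best_gap} off-target cells", stacklevel=2)
        return float(best_lam)

    # -------------------------------------------------------------- predict

    def _transform_for_predict(self, X):
        check_is_fitted(self, "B_")
        Xm, G, _, _ = self._split_design(X)
        Xm = Xm[:, self._keep_mask] if hasattr(self, "_keep_mask") else Xm
        Xm = (Xm - self.scaler_mean_) / self.scaler_scale_
        return self._fold(Xm), G

    def decision_function(self, X):
        """Linear score a2 + gamma'G + <B, M_adj>; positive favors MSI."""
        tensors, G = self._transform_for_predict(X)
        return core.catch_score(tensors, G, self.alpha_, self.B_,
                                self.gamma_, self.intercept_)

    def predict(self, X):
        return core.predict_from_score(self.decision_function(X))

    def predict_proba(self, X):
        """Model posterior P(class | x) via the logistic of the score."""
        p2 = 1.0 / (1.0 + np.exp(-self.decision_function(X)))
        return np.column_stack([1.0 - p2, p2])

    def adjusted_tensors(self, X):
        """Covariate-adjusted standardized tensors M_adj for samples in X."""
        tensors, G = self._transform_for_predict(X)
        return core.adjust(tensors, G, self.alpha_)


# ------------------------------------------------------------------ helpers


def fit_catch(dataset, **params) -> CatchClassifier:
    """Fit a :class:`CatchClassifier` on a pre-built
    :class:`~catchmsi.tensorize.TensorDataset` (already standardized)."""
    fm = dataset.feature_map
    n = dataset.tensors.shape[0]
    flat = dataset.tensors.reshape(n, fm.d1 * fm.d2)[:, :fm.n_real]
    X = pd.DataFrame(
        np.hstack([flat, dataset.covariates]),
        columns=list(fm.names) + [f"g{k:03d}" for k in range(dataset.covariates.shape[1])],
    )
    clf = CatchClassifier(d1=fm.d1, d2=fm.d2,
                          n_covariates=dataset.covariates.shape[1],
                          standardize=False, **params)
    return clf.fit(X, dataset.labels)


def select_features(model: CatchClassifier) -> pd.DataFrame:
    """Selected metabolite features and their direct effects.

    One row per nonzero, non-padded cell of B, sorted by coefficient
    ascending (MSS-associated negatives first, strongest MSI association
    last). Columns: feature, row, col, coefficient.
    """
    check_is_fitted(model, "B_")
    fm = model.feature_map_
    rows = []
    for i in range(fm.d1):
        for j in range(fm.d2):
            if fm.padded_mask[i, j] or model.B_[i, j] == 0:
                continue
            rows.append((fm.name_of((i, j)), i, j, float(model.B_[i, j])))
    out = pd.DataFrame(rows, columns=["feature", "row", "col", "coefficient"])
    return out.sort_values("coefficient", kind="stable").reset_index(drop=True)


def association_matrix(model: CatchClassifier, cells=None) -> pd.DataFrame:
    """Feature x gene matrix of alpha slices for the selected cells.

    Row f is ``alpha[cell_f, :]``; columns follow the input gene order.
    ``cells`` defaults to the nonzero cells of B (the selected features).
    """
    check_is_fitted(model, "alpha_")
    fm = model.feature_map_
    if cells is None:
        sel = select_features(model)
        cells = list(zip(sel["row"], sel["col"]))
    names = [fm.name_of(c) for c in cells]
    q = model.alpha_.shape[2]
    data = np.zeros((len(cells), q))
    for r, (i, j) in enumerate(cells):
        data[r] = model.alpha_[i, j, :]
    return pd.DataFrame(data, index=names, columns=model.covariate_names_)


def feature_gene_correlations(model: CatchClassifier, X,
                              cells=None) -> pd.DataFrame:
    """Pearson correlation of each selected raw metabolite feature with each
    gene across the samples in X (companion to :func:`association_matrix`)."""
    check_is_fitted(model, "alpha_")
    fm = model.feature_map_
    Xm, G, _, _ = model._split_design(X)
    if cells is None:
        sel = select_features(model)
        cells = list(zip(sel["row"], sel["col"]))
    names = [fm.name_of(c) for c in cells]
    out = np.zeros((len(cells), G.shape[1]))
    for r, (i, j) in enumerate(cells):
        feat = Xm[:, i * fm.d2 + j]
        for c in range(G.shape[1]):
            out[r, c] = np.corrcoef(feat, G[:, c])[0, 1]
    return pd.DataFrame(out, index=names, columns=model.covariate_names_)
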