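"""Standardization and tensor folding of metabolite matrices.

Each sample's p-vector of metabolite abundances is z-scored (mean 0, sd 1,
sample standard deviation, estimated on a designated training subset only)
and folded row-major into a d1 x d2 matrix so the classifier can exploit a
separable row/column covariance. The folding is recorded in an invertible
:class:`FeatureMap`; when d1*d2 > p the trailing cells are zero-padded and
masked out of estimation and selection.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class StandardizationParams:
    """Per-metabolite mean/sd estimated on a training subset.

    Metabolites with zero sd on the fitting subset carry no information and
    are dropped (recorded in ``dropped``).
    """

    mean: pd.Series
    sd: pd.Series
    dropped: list = field(default_factory=list)

    @property
    def columns(self) -> pd.Index:
        return self.mean.index


@dataclass
class FeatureMap:
    """Bijection metabolite name <-> (row, col) cell, row-major.

    Cell (i, j) holds the metabolite with flat index i*d2 + j; cells with
    flat index >= len(names) are padding.
    """

    names: list
    d1: int
    d2: int

    def __post_init__(self) -> None:
        if self.d1 * self.d2 < len(self.names):
            raise ValueError(
                f"tensor {self.d1}x{self.d2} too small for {len(self.names)} features"
            )

    @property
    def n_real(self) -> int:
        return len(self.names)

    @property
    def padded_mask(self) -> np.ndarray:
        """Boolean (d1, d2) mask, True on padded cells."""
        flat = np.arange(self.d1 * self.d2) >= self.n_real
        return flat.reshape(self.d1, self.d2)

    def cell_of(self, name: str) -> tuple:
        idx = self.names.index(name)
        return divmod(idx, self.d2)

    def name_of(self, cell) -> str:
        i, j = cell
        if not (0 <= i < self.d1 and 0 <= j < self.d2):
            raise IndexError(f"cell {cell} outside {self.d1}x{self.d2} tensor")
        flat = i * self.d2 + j
        if flat >= self.n_real:
            raise ValueError(f"cell {cell} is padding, not a metabolite")
        return self.names[flat]

    def to_frame(self) -> pd.DataFrame:
        rows, cols = np.divmod(np.arange(self.n_real), self.d2)
        return pd.DataFrame({"name": self.names, "row": rows, "col": cols})


def default_dims(p: int) -> tuple:
    """Square-ish default folding: d1 = d2 = ceil(sqrt(p))."""
    d = math.ceil(math.sqrt(p))
    return d, d


def fit_standardizer(metabolites: pd.DataFrame, subset=None) -> StandardizationParams:
    """Column means/sds over ``subset`` only (leakage-free).

    Sample standard deviation (ddof=1). Constant columns are dropped with a
    warning and recorded.
    """
    X = metabolites if subset is None else metabolites.loc[subset]
    if len(X) == 0:
        raise ValueError("standardization subset is empty")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    constant = sd.index[(sd == 0) | sd.isna()].tolist()
    if constant:
        warnings.warn(
            f"dropped {len(constant)} constant metabolite column(s): "
            f"{constant[:5]}",
            stacklevel=2,
        )
    keep = sd.index.difference(constant, sort=False)
    return StandardizationParams(mean=mean[keep], sd=sd[keep], dropped=constant)


def apply_standardizer(metabolites: pd.DataFrame,
                       params: StandardizationParams) -> pd.DataFrame:
    cols = params.columns
    return (metabolites[cols] - params.mean) / params.sd


def to_tensor(metabolites: pd.DataFrame, params: StandardizationParams = None,
              d1: int = None, d2: int = None):
    """Standardize and fold into (n, d1, d2) tensors.

    Returns ``(tensors, feature_map)``. With ``params=None`` the values are
    folded as-is (used when the caller standardized already).
    """
    X = metabolites if params is None else apply_standardizer(metabolites, params)
    names = list(X.columns)
    p = len(names)
    if d1 is None or d2 is None:
        d1, d2 = default_dims(p)
    if d1 * d2 < p:
        raise ValueError(f"d1*d2 = {d1 * d2} < p = {p}")
    fmap = FeatureMap(names=names, d1=d1, d2=d2)
    flat = np.zeros((len(X), d1 * d2))
    flat[:, :p] = X.to_numpy()
    return flat.reshape(len(X), d1, d2), fmap


def feature_name(fmap: FeatureMap, cell) -> str:
    """Metabolite name at a tensor cell (errors on padded cells)."""
    return fmap.name_of(cell)


@dataclass
class TensorDataset:
    """Standardized tensors + covariates + labels ready for the classifier."""

    tensors: np.ndarray            # (n, d1, d2)
    covariates: np.ndarray         # (n, q)
    labels: np.ndarray             # (n,) in {1, 2}; 1 = MSS, 2 = MSI
    feature_map: FeatureMap
    standardization: StandardizationParams

    def __post_init__(self) -> None:
        self.tensors = np.asarray(self.tensors, dtype=float)
        self.covariates = np.asarray(self.covariates, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        n = self.tensors.shape[0]
        if self.covariates.shape[0] != n or self.labels.shape[0] != n:
            raise ValueError("tensors, covariates and labels disagree on n")
        if not np.isin(self.labels, (1, 2)).all():
            raise ValueError("labels must be 1 (MSS) or 2 (MSI)")
        if not np.isfinite(self.tensors).all() or not np.isfinite(self.covariates).all():
            raise ValueError("non-finite values in tensors or covariates")


def make_tensor_dataset(cohort, train_ids=None, d1: int = None,
                        d2: int = None) -> TensorDataset:
    """Build a TensorDataset from a cohort, fitting the standardizer on
    ``train_ids`` (all samples when None) and applying it to every sample."""
    params = fit_standardizer(cohort.metabolites, subset=train_ids)
    tensors, fmap = to_tensor(cohort.metabolites, params, d1=d1, d2=d2)
    return TensorDataset(
        tensors=tensors,
        covariates=cohort.covariates.to_numpy(dtype=float),
        labels=cohort.labels.to_numpy(),
        feature_map=fmap,
        standardization=params,
    )
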