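"""Cohort tables, validation, and result serialization.

The pipeline's universal input is a cohort of samples described by three
aligned tables keyed by sample id:

* ``annotation`` — MSI/MSS outcome label, cancer-cell lineage group, and
  *APC* / *TP53* mutation flags (``M`` mutant, ``W`` wild type);
* ``metabolites`` — samples x p metabolite abundance matrix;
* ``covariates`` — samples x q metabolic-gene expression matrix.

All three tables are plain CSV on disk (comma, UTF-8, header row, sample id
in the first column), matching DepMap-style exports without binding to them.
Model and configuration artifacts are JSON, with tensors flattened row-major
next to explicit shape fields.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

#: Numeric outcome codes used throughout: class 1 = MSS, class 2 = MSI.
LABEL_CODES = {"MSS": 1, "MSI": 2}
CODE_LABELS = {1: "MSS", 2: "MSI"}
ANNOTATION_COLUMNS = ("label", "lineage", "apc", "tp53")


class CohortError(ValueError):
    """Raised when cohort tables fail validation."""


@dataclass
class CohortTable:
    """Aligned annotation, metabolite, and covariate tables for one cohort.

    All three frames are indexed by sample id and must share the same index
    in the same order. Labels are the strings ``"MSI"`` / ``"MSS"``.
    """

    annotation: pd.DataFrame
    metabolites: pd.DataFrame
    covariates: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ANNOTATION_COLUMNS:
            if col not in self.annotation.columns:
                raise CohortError(f"annotation is missing column {col!r}")
        ids = self.annotation.index
        if ids.has_duplicates:
            dups = ids[ids.duplicated()].unique().tolist()
            raise CohortError(f"duplicate sample ids: {dups[:10]}")
        for name, frame in (("metabolites", self.metabolites),
                            ("covariates", self.covariates)):
            if not frame.index.equals(ids):
                raise CohortError(
                    f"{name} index does not match annotation index; "
                    "use read_cohort() to align tables"
                )
            values = frame.to_numpy()
            if not np.issubdtype(values.dtype, np.number):
                bad = _first_non_numeric(frame)
                raise CohortError(
                    f"non-numeric cell in {name} at sample {bad[0]!r}, "
                    f"column {bad[1]!r}: {bad[2]!r}"
                )
            if not np.isfinite(values).all():
                r, c = np.argwhere(~np.isfinite(values))[0]
                raise CohortError(
                    f"non-finite cell in {name} at sample {ids[r]!r}, "
                    f"column {frame.columns[c]!r}"
                )
        bad_labels = set(self.annotation["label"]) - set(LABEL_CODES)
        if bad_labels:
            raise CohortError(f"labels must be MSI/MSS, got {sorted(bad_labels)}")

    @property
    def sample_ids(self) -> pd.Index:
        return self.annotation.index

    @property
    def n_samples(self) -> int:
        return len(self.annotation)

    @property
    def labels(self) -> pd.Series:
        """Numeric outcome codes (1 = MSS, 2 = MSI) indexed by sample id."""
        return self.annotation["label"].map(LABEL_CODES).astype(int)

    def subset(self, ids) -> "CohortTable":
        ids = pd.Index(ids)
        missing = ids.difference(self.annotation.index)
        if len(missing):
            raise CohortError(f"unknown sample ids: {missing.tolist()[:10]}")
        return CohortTable(
            annotation=self.annotation.loc[ids].copy(),
            metabolites=self.metabolites.loc[ids].copy(),
            covariates=self.covariates.loc[ids].copy(),
        )

    def design_matrix(self) -> pd.DataFrame:
        """Flat [metabolites | covariates] matrix fed to classifiers."""
        return pd.concat([self.metabolites, self.covariates], axis=1)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.annotation.to_csv(outdir / "annotation.csv", index_label="sample_id")
        self.metabolites.to_csv(outdir / "metabolites.csv", index_label="sample_id")
        self.covariates.to_csv(outdir / "genes.csv", index_label="sample_id")

    @classmethod
    def read(cls, indir) -> "CohortTable":
        indir = Path(indir)
        return read_cohort(
            indir / "annotation.csv",
            indir / "metabolites.csv",
            indir / "genes.csv",
        )


def _first_non_numeric(frame: pd.DataFrame):
    for col in frame.columns:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna() & frame[col].notna()
        if bad.any():
            sid = frame.index[bad.to_numpy().argmax()]
            return sid, col, frame.loc[sid, col]
        if frame[col].isna().any():
            sid = frame.index[frame[col].isna().to_numpy().argmax()]
            return sid, col, frame.loc[sid, col]
    return frame.index[0], frame.columns[0], None


def _read_indexed_csv(path, name: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise CohortError(f"{name} file not found: {path}")
    frame = pd.read_csv(path, index_col=0)
    frame.index = frame.index.astype(str)
    if frame.index.has_duplicates:
        dups = frame.index[frame.index.duplicated()].unique().tolist()
        raise CohortError(f"duplicate sample ids in {name}: {dups[:10]}")
    return frame


def read_cohort(annotation_path, metabolite_path, gene_path) -> CohortTable:
    """Read and align the three cohort CSVs.

    Samples missing from any table are dropped with a warning that counts
    them; an empty id intersection is an error. Tables are sorted by sample
    id so the alignment is deterministic.
    """
    annotation = _read_indexed_csv(annotation_path, "annotation")
    metabolites = _read_indexed_csv(metabolite_path, "metabolites")
    covariates = _read_indexed_csv(gene_path, "genes")

    common = annotation.index.intersection(metabolites.index)
    common = common.intersection(covariates.index).sort_values()
    if len(common) == 0:
        raise CohortError("no sample ids shared by all three tables")
    n_dropped = (
        len(set(annotation.index) | set(metabolites.index) | set(covariates.index))
        - len(common)
    )
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} sample(s) missing from at least one table",
            stacklevel=2,
        )
    for name, frame in (("metabolites", metabolites), ("genes", covariates)):
        values = frame.loc[common]
        coerced = values.apply(pd.to_numeric, errors="coerce")
        bad = coerced.isna()
        if bad.to_numpy().any():
            r, c = np.argwhere(bad.to_numpy())[0]
            raise CohortError(
                f"non-numeric cell in {name} at sample {common[r]!r}, "
                f"column {values.columns[c]!r}: {values.iloc[r, c]!r}"
            )
    return CohortTable(
        annotation=annotation.loc[common],
        metabolites=metabolites.loc[common].astype(float),
        covariates=covariates.loc[common].astype(float),
    )


# ---------------------------------------------------------------------------
# JSON artifacts


def _tensor_to_json(arr: np.ndarray) -> dict:
    arr = np.asarray(arr)
    return {"shape": list(arr.shape), "data": arr.ravel(order="C").tolist()}


def _tensor_from_json(obj) -> np.ndarray:
    return np.asarray(obj["data"], dtype=float).reshape(obj["shape"], order="C")


def model_to_dict(model) -> dict:
    """Serialize a fitted :class:`~catchmsi.model.CatchClassifier`."""
    from .model import CatchClassifier  # local import to avoid a cycle

    if not isinstance(model, CatchClassifier):
        raise TypeError("model_to_dict expects a CatchClassifier")
    fm = model.feature_map_
    return {
        "params": model.get_params(),
        "alpha": _tensor_to_json(model.alpha_),
        "B": _tensor_to_json(model.B_),
        "gamma": _tensor_to_json(model.gamma_),
        "intercept": float(model.intercept_),
        "priors": list(map(float, model.priors_)),
        "mu1": _tensor_to_json(model.mu1_),
        "mu2": _tensor_to_json(model.mu2_),
        "sigma1": _tensor_to_json(model.sigma1_),
        "sigma2": _tensor_to_json(model.sigma2_),
        "psi": _tensor_to_json(model.psi_),
        "phi1": _tensor_to_json(model.phi1_),
        "phi2": _tensor_to_json(model.phi2_),
        "penalty": float(model.penalty_),
        "scaler_mean": _tensor_to_json(model.scaler_mean_),
        "scaler_scale": _tensor_to_json(model.scaler_scale_),
        "feature_names": list(fm.names),
        "covariate_names": list(model.covariate_names_),
        "dropped_features": list(model.dropped_features_),
        "keep_mask": np.asarray(model._keep_mask, dtype=bool).tolist(),
        "d1": int(fm.d1),
        "d2": int(fm.d2),
        "classes": [int(c) for c in model.classes_],
    }


def model_from_dict(payload: dict):
    """Rebuild a fitted classifier from :func:`model_to_dict` output."""
    from .model import CatchClassifier
    from .tensorize import FeatureMap

    model = CatchClassifier(**payload["params"])
    model.alpha_ = _tensor_from_json(payload["alpha"])
    model.B_ = _tensor_from_json(payload["B"])
    model.gamma_ = _tensor_from_json(payload["gamma"])
    model.intercept_ = float(payload["intercept"])
    model.priors_ = tuple(payload["priors"])
    model.mu1_ = _tensor_from_json(payload["mu1"])
    model.mu2_ = _tensor_from_json(payload["mu2"])
    model.sigma1_ = _tensor_from_json(payload["sigma1"])
    model.sigma2_ = _tensor_from_json(payload["sigma2"])
    model.psi_ = _tensor_from_json(payload["psi"])
    model.phi1_ = _tensor_from_json(payload["phi1"])
    model.phi2_ = _tensor_from_json(payload["phi2"])
    model.penalty_ = float(payload["penalty"])
    model.scaler_mean_ = _tensor_from_json(payload["scaler_mean"])
    model.scaler_scale_ = _tensor_from_json(payload["scaler_scale"])
    model.feature_map_ = FeatureMap(
        names=list(payload["feature_names"]),
        d1=payload["d1"],
        d2=payload["d2"],
    )
    model.covariate_names_ = list(payload["covariate_names"])
    model.dropped_features_ = list(payload["dropped_features"])
    model._keep_mask = np.asarray(payload["keep_mask"], dtype=bool)
    model.classes_ = np.asarray(payload["classes"])
    model.n_features_in_ = len(payload["keep_mask"]) + len(
        payload["covariate_names"]
    )
    return model


def save_model(model, path) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model)))


def load_model(path):
    return model_from_dict(json.loads(Path(path).read_text()))


def write_results(outdir, model=None, report=None, significance=None,
                  run_config=None) -> list:
    """Write the standard result CSVs/JSONs; returns the paths written.

    ``direct_effects.csv`` — selected metabolite features and their direct
    effects (sparse discriminant coefficients); ``metrics.csv`` — one row per
    method of averaged repeated-split metrics; ``alpha_associations.csv`` —
    feature x gene coefficient matrix; ``significance.csv`` — Wilcoxon p per
    feature and data variant; plus ``model.json`` / ``run_config.json``.
    """
    from .model import association_matrix, select_features

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    if model is not None:
        effects = select_features(model)
        effects.to_csv(outdir / "direct_effects.csv", index=False)
        association_matrix(model).to_csv(outdir / "alpha_associations.csv")
        save_model(model, outdir / "model.json")
        written += [outdir / "direct_effects.csv",
                    outdir / "alpha_associations.csv", outdir / "model.json"]
    if report is not None:
        report.summary.to_csv(outdir / "metrics.csv")
        report.per_iteration.to_csv(outdir / "metrics_per_iteration.csv",
                                    index=False)
        written += [outdir / "metrics.csv", outdir / "metrics_per_iteration.csv"]
    if significance is not None:
        significance.to_csv(outdir / "significance.csv")
        written.append(outdir / "significance.csv")
    if run_config is not None:
        (outdir / "run_config.json").write_text(
            json.dumps(run_config, indent=2, sort_keys=True)
        )
        written.append(outdir / "run_config.json")
    return written
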