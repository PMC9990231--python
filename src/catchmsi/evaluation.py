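"""Repeated-split evaluation and adjusted-vs-raw significance testing.

The evaluation protocol: repeatedly split the cohort into 90% training /
10% testing with the MSI:MSS ratio preserved per class, refit the whole
pipeline (standardization, adjustment, discriminant) on each training
split, score the held-out split, and average confusion-derived metrics over
iterations. A flat-feature random forest on [metabolites | genes] serves as
the simultaneous-integration baseline and consumes identical splits.

Significance of individual metabolite features is assessed with two-sided
Wilcoxon rank-sum (Mann-Whitney) tests on three data variants: the raw
column, the standardized column, and the covariate-adjusted tensor cell —
the divergence between raw and adjusted p-values is the confounding
signature this pipeline exists to expose.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier

from .model import CatchClassifier, select_features

__all__ = [
    "SplitSpec", "EvaluationReport", "stratified_split", "confusion_metrics",
    "repeated_evaluation", "wilcoxon_feature_test",
    "adjustment_significance_table",
]

METRICS = ("accuracy", "sensitivity", "specificity", "precision", "f1")


@dataclass
class SplitSpec:
    """Repeated stratified-split protocol (default: 100 x 90/10)."""

    test_fraction: float = 0.10
    iterations: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.test_fraction < 1.0):
            raise ValueError("test_fraction must be in (0, 1)")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


@dataclass
class EvaluationReport:
    """Per-iteration confusion counts/metrics and their averages."""

    per_iteration: pd.DataFrame
    summary: pd.DataFrame


def stratified_split(labels, spec: SplitSpec, iteration: int):
    """(train, test) index split preserving the per-class ratio.

    Per class, round-half-up of ``n_k * test_fraction`` samples go to the
    test partition. Deterministic given ``(spec.seed, iteration)``; distinct
    iterations give distinct partitions. With a pandas Series input the
    returned arrays hold index labels, otherwise positional indices.
    """
    if isinstance(labels, pd.Series):
        index = labels.index.to_numpy()
        y = labels.to_numpy()
    else:
        y = np.asarray(labels)
        index = np.arange(len(y))
    rng = np.random.default_rng([int(spec.seed), int(iteration)])
    train, test = [], []
    for cls in np.unique(y):
        members = index[y == cls]
        n_k = len(members)
        n_test = int(math.floor(n_k * spec.test_fraction + 0.5))
        if n_test < 1 or n_test >= n_k:
            raise ValueError(
                f"class {cls!r} has {n_k} members: too few for "
                f"test_fraction {spec.test_fraction}"
            )
        perm = rng.permutation(n_k)
        test.append(members[perm[:n_test]])
        train.append(members[perm[n_test:]])
    return np.concatenate(train), np.concatenate(test)


def confusion_metrics(y_true, y_pred, positive: int = 2) -> dict:
    """Confusion counts and derived metrics with MSI (class 2) positive.

    0/0 ratios are reported as 0.0 and flagged in the ``degenerate`` field.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("truth and prediction must have equal length")
    pos_t, pos_p = y_true == positive, y_pred == positive
    tp = int(np.sum(pos_t & pos_p))
    fp = int(np.sum(~pos_t & pos_p))
    fn = int(np.sum(pos_t & ~pos_p))
    tn = int(np.sum(~pos_t & ~pos_p))
    degenerate = []

    def ratio(num, den, name):
        if den == 0:
            degenerate.append(name)
            return 0.0
        return num / den

    sens = ratio(tp, tp + fn, "sensitivity")
    spec = ratio(tn, tn + fp, "specificity")
    prec = ratio(tp, tp + fp, "precision")
    acc = (tp + tn) / max(len(y_true), 1)
    f1 = ratio(2 * prec * sens, prec + sens, "f1")
    return {"tp": tp, "fp": fp, "tn": tn, "fn": fn, "accuracy": acc,
            "sensitivity": sens, "specificity": spec, "precision": prec,
            "f1": f1, "degenerate": tuple(degenerate)}


def default_baseline(random_state=None) -> RandomForestClassifier:
    """The simultaneous-integration comparator: a 500-tree random forest on
    the flat [metabolites | genes] matrix."""
    return RandomForestClassifier(n_estimators=500, random_state=random_state)


def repeated_evaluation(cohort, spec: SplitSpec = None, catch_params=None,
                        baseline="rf") -> EvaluationReport:
    """Run the repeated-split protocol on a cohort.

    ``catch_params`` are forwarded to :class:`CatchClassifier` (e.g.
    ``dict(d1=5, d2=5, penalty=0.1)``); ``n_covariates`` is filled in from
    the cohort. ``baseline`` is ``"rf"`` (default 500-tree forest), ``None``
    (no comparator), or any scikit-learn classifier to be cloned per
    iteration. Both methods consume identical splits.
    """
    spec = spec or SplitSpec()
    y = cohort.labels
    X = cohort.design_matrix()
    q = cohort.covariates.shape[1]
    params = dict(catch_params or {})
    params.setdefault("n_covariates", q)

    base_proto = default_baseline() if baseline == "rf" else baseline
    rows = []
    for it in range(spec.iterations):
        train, test = stratified_split(y, spec, it)
        it_seed = int((spec.seed * 100003 + it) % (2**31 - 1))
        try:
            clf = CatchClassifier(random_state=it_seed, **params)
            clf.fit(X.loc[train], y.loc[train])
            pred = clf.predict(X.loc[test])
        except Exception as exc:
            raise RuntimeError(
                f"CATCH failed on iteration {it} (seed {spec.seed}): {exc}"
            ) from exc
        m = confusion_metrics(y.loc[test].to_numpy(), pred)
        rows.append({"iteration": it, "method": "catch", **m})
        if base_proto is not None:
            base = clone(base_proto)
            if "random_state" in base.get_params():
                base.set_params(random_state=it_seed)
            base.fit(X.loc[train].to_numpy(), y.loc[train].to_numpy())
            bpred = base.predict(X.loc[test].to_numpy())
            mb = confusion_metrics(y.loc[test].to_numpy(), bpred)
            rows.append({"iteration": it, "method": "baseline", **mb})

    per_iteration = pd.DataFrame(rows)
    summary = (per_iteration.groupby("method")[list(METRICS)].mean()
               .sort_index(ascending=False))
    return EvaluationReport(per_iteration=per_iteration, summary=summary)


def wilcoxon_feature_test(values, labels) -> float:
    """Two-sided Wilcoxon rank-sum p for one feature between the classes.

    Exact enumeration when both groups have <= 12 members and the pooled
    values are tie-free; otherwise the normal approximation with tie and
    continuity corrections. Constant pooled values give p = 1 with a
    warning.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    x = values[labels == np.unique(labels)[0]]
    y = values[labels != np.unique(labels)[0]]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    if np.ptp(values) == 0:
        warnings.warn("constant feature: Wilcoxon p set to 1", stacklevel=2)
        return 1.0
    no_ties = len(np.unique(values)) == len(values)
    method = "exact" if (len(x) <= 12 and len(y) <= 12 and no_ties) else "asymptotic"
    return float(mannwhitneyu(x, y, alternative="two-sided", method=method,
                              use_continuity=True).pvalue)


VARIANTS = ("non_adjusted", "standardized", "adjusted")


def feature_variant_values(cohort, model: CatchClassifier, cell,
                           variant: str) -> np.ndarray:
    """Per-sample values of one selected feature under a data variant:
    the raw metabolite column, its standardized version, or the
    covariate-adjusted tensor cell."""
    fm = model.feature_map_
    name = fm.name_of(cell)
    if variant == "non_adjusted":
        return cohort.metabolites[name].to_numpy(dtype=float)
    X = cohort.design_matrix()
    tensors, _G = model._transform_for_predict(X)
    if variant == "standardized":
        return tensors[:, cell[0], cell[1]]
    if variant == "adjusted":
        return model.adjusted_tensors(X)[:, cell[0], cell[1]]
    raise ValueError(f"variant must be one of {VARIANTS}, got {variant!r}")


def adjustment_significance_table(cohort, model: CatchClassifier,
                                  return_values: bool = False):
    """Wilcoxon p per selected feature under each data variant.

    Rows are the model's selected features; columns are the three variants.
    With ``return_values=True`` also returns the per-variant value arrays
    for external plotting.
    """
    sel = select_features(model)
    y = cohort.labels.to_numpy()
    rows, values = {}, {}
    for _, r in sel.iterrows():
        cell = (int(r["row"]), int(r["col"]))
        pvals = {}
        for variant in VARIANTS:
            v = feature_variant_values(cohort, model, cell, variant)
            pvals[variant] = wilcoxon_feature_test(v, y)
            values[(r["feature"], variant)] = v
        rows[r["feature"]] = pvals
    table = pd.DataFrame.from_dict(rows, orient="index", columns=list(VARIANTS))
    table.index.name = "feature"
    if return_values:
        return table, values
    return table
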