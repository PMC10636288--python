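"""Confusion matrices, macro per-class metrics, stratified CV, marker ranking."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .data_io import ExpressionMatrix, LabelTable
from .deg import _ranksum_p, log2_fold_change
from .errors import ConfigError, FormatError
from .network import TrainedModel, fit_classifier
from .search_space import Individual


@dataclass
class MetricsReport:
    class_names: list[str]
    confusion: np.ndarray  # rows = truth, columns = prediction
    per_class_sensitivity: list[float]
    per_class_specificity: list[float]
    per_class_accuracy: list[float]
    macro_sensitivity: float
    macro_specificity: float
    macro_accuracy: float  # mean per-class recall ("average accuracy per class")
    overall_accuracy: float
    n: int
    undefined_rates: int = 0

    def to_dict(self) -> dict:
        def clean(x):
            if isinstance(x, list):
                return [clean(v) for v in x]
            if isinstance(x, float) and math.isnan(x):
                return None
            return x

        return {
            "class_names": self.class_names,
            "confusion": self.confusion.tolist(),
            "per_class_sensitivity": clean(self.per_class_sensitivity),
            "per_class_specificity": clean(self.per_class_specificity),
            "per_class_accuracy": clean(self.per_class_accuracy),
            "macro_sensitivity": clean(self.macro_sensitivity),
            "macro_specificity": clean(self.macro_specificity),
            "macro_accuracy": clean(self.macro_accuracy),
            "overall_accuracy": self.overall_accuracy,
            "n": self.n,
            "undefined_rates": self.undefined_rates,
        }


def confusion_matrix(
    y_true: Sequence[str], y_pred: Sequence[str], class_names: Sequence[str]
) -> np.ndarray:
    """Entry (i, j) counts truth class i predicted as class j."""
    if len(y_true) != len(y_pred):
        raise FormatError("y_true and y_pred lengths differ")
    lut = {c: i for i, c in enumerate(class_names)}
    unknown = (set(y_true) | set(y_pred)) - set(lut)
    if unknown:
        raise FormatError(f"labels outside class set: {sorted(unknown)}")
    m = np.zeros((len(class_names), len(class_names)), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        m[lut[t], lut[p]] += 1
    return m


def classification_metrics(
    confusion: np.ndarray, class_names: Sequence[str] | None = None
) -> MetricsReport:
    """One-vs-rest sensitivity/specificity per class, overall and macro accuracy.

    Rates with a zero denominator are reported as NaN and excluded from the
    macro averages; ``undefined_rates`` counts them.
    """
    m = np.asarray(confusion, dtype=np.int64)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise FormatError("confusion matrix must be square")
    if (m < 0).any():
        raise FormatError("confusion entries must be >= 0")
    n = int(m.sum())
    if n == 0:
        raise FormatError("empty confusion matrix")
    c = m.shape[0]
    if class_names is None:
        class_names = [str(i) for i in range(c)]
    sens, spec, acc = [], [], []
    undefined = 0
    for i in range(c):
        tp = m[i, i]
        fn = m[i, :].sum() - tp
        fp = m[:, i].sum() - tp
        tn = n - tp - fn - fp
        if tp + fn == 0:
            sens.append(float("nan"))
            acc.append(float("nan"))
            undefined += 1
        else:
            sens.append(float(tp / (tp + fn)))
            acc.append(float(tp / (tp + fn)))
        if tn + fp == 0:
            spec.append(float("nan"))
            undefined += 1
        else:
            spec.append(float(tn / (tn + fp)))
    return MetricsReport(
        class_names=list(class_names),
        confusion=m,
        per_class_sensitivity=sens,
        per_class_specificity=spec,
        per_class_accuracy=acc,
        macro_sensitivity=float(np.nanmean(sens)),
        macro_specificity=float(np.nanmean(spec)),
        macro_accuracy=float(np.nanmean(acc)),
        overall_accuracy=float(np.trace(m) / n),
        n=n,
        undefined_rates=undefined,
    )


def cross_validate(
    expr: ExpressionMatrix,
    labels: LabelTable,
    individual: Individual,
    k: int = 10,
    seed: int = 0,
    gene_selector: Callable[[ExpressionMatrix, LabelTable], list[str]] | None = None,
    patience: int = 50,
    batch_size: int = 32,
) -> tuple[list[MetricsReport], MetricsReport]:
    """Stratified k-fold CV of the classifier realized from ``individual``.

    ``gene_selector`` (when given) is re-fit inside each training fold only,
    as is the per-gene standardization, so no information from a test fold
    leaks into feature selection or scaling.  Returns per-fold reports plus
    a pooled report over the concatenated test-fold predictions.
    """
    aligned = labels.aligned_to(expr.sample_ids)
    y = aligned.encoded()
    counts = np.bincount(y, minlength=len(aligned.class_names))
    if counts.min() < k:
        raise ConfigError(
            f"smallest class has {counts.min()} samples < k={k}; use a smaller k"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_reports = []
    pooled_true: list[str] = []
    pooled_pred: list[str] = []
    for fold, (tr, te) in enumerate(skf.split(expr.values, y)):
        tr_expr = expr.subset_samples(tr)
        tr_labels = LabelTable(
            tr_expr.sample_ids, [aligned.labels[i] for i in tr], list(aligned.class_names)
        )
        if gene_selector is not None:
            genes = gene_selector(tr_expr, tr_labels)
            tr_expr = tr_expr.subset_genes(genes)
        model = fit_classifier(
            tr_expr, tr_labels, individual,
            patience=patience, seed=seed + fold, batch_size=batch_size,
        )
        te_expr = expr.subset_samples(te)
        _, pred = model.predict(te_expr)
        truth = [aligned.labels[i] for i in te]
        fold_reports.append(
            classification_metrics(
                confusion_matrix(truth, pred, aligned.class_names), aligned.class_names
            )
        )
        pooled_true.extend(truth)
        pooled_pred.extend(pred)
    pooled = classification_metrics(
        confusion_matrix(pooled_true, pooled_pred, aligned.class_names), aligned.class_names
    )
    return fold_reports, pooled


def evaluate_model(
    model: TrainedModel, expr: ExpressionMatrix, labels: LabelTable
) -> MetricsReport:
    """Score a trained model on an expression matrix with known labels."""
    aligned = labels.aligned_to(expr.sample_ids)
    _, pred = model.predict(expr)
    return classification_metrics(
        confusion_matrix(aligned.labels, pred, model.class_names), model.class_names
    )


def rank_marker_genes(
    expr: ExpressionMatrix, predicted_labels: Sequence[str], top_n: int = 10
) -> pd.DataFrame:
    """Per predicted class, genes ranked by ascending one-vs-rest rank-sum p.

    Ties break by |log2fc| descending, then gene_id.  Returns a table with
    columns (class, rank, gene_id, p, log2fc), ``top_n`` rows per class.
    """
    pred = list(predicted_labels)
    if len(pred) != expr.n_samples:
        raise FormatError("one predicted label per sample required")
    present = sorted(set(pred))
    if len(present) < 2:
        raise FormatError("marker ranking needs >=2 predicted classes")
    rows = []
    for cname in present:
        mask = np.array([l == cname for l in pred])
        p = _ranksum_p(expr.values[mask], expr.values[~mask])
        fc = log2_fold_change(expr, mask)
        tbl = pd.DataFrame(
            {"class": cname, "gene_id": expr.gene_ids, "p": p, "log2fc": fc}
        )
        tbl["abs_fc"] = tbl["log2fc"].abs()
        tbl = tbl.sort_values(
            ["p", "abs_fc", "gene_id"], ascending=[True, False, True], kind="mergesort"
        ).head(top_n)
        tbl["rank"] = np.arange(1, len(tbl) + 1)
        rows.append(tbl.drop(columns="abs_fc"))
    out = pd.concat(rows, ignore_index=True)
    return out[["class", "rank", "gene_id", "p", "log2fc"]]
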