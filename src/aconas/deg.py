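"""One-vs-rest differential-expression gene filter.

For every class the member samples are compared against the pooled rest with
a Welch t-test and a two-sided Wilcoxon rank-sum test.  Within each
comparison both p-value vectors are Benjamini-Hochberg adjusted; a gene is
selected when |log2 fold-change| exceeds ``fc_threshold`` AND both adjusted
values fall below ``q_threshold``.  The final gene list is the union over
the per-class selections, deduplicated in original gene order.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_io import ExpressionMatrix, LabelTable
from .errors import ConfigError, FormatError

DEG_COLUMNS = ["class", "gene_id", "log2fc", "p_t", "q_t", "p_w", "q_w", "selected"]


def log2_fold_change(expr: ExpressionMatrix, in_group: np.ndarray) -> np.ndarray:
    """Per-gene mean(in_group) - mean(rest); values are already log2 scale."""
    mask = np.asarray(in_group, dtype=bool)
    if mask.shape != (expr.n_samples,):
        raise FormatError("in_group mask must have one entry per sample")
    if not mask.any():
        raise FormatError("in_group is empty")
    if mask.all():
        raise FormatError("rest group is empty")
    return expr.values[mask].mean(axis=0) - expr.values[~mask].mean(axis=0)


def _welch_p(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorized Welch t-test p-values with a documented zero-variance convention."""
    with np.errstate(divide="ignore", invalid="ignore"):
        p = stats.ttest_ind(a, b, axis=0, equal_var=False).pvalue
    p = np.asarray(p, dtype=float)
    var0 = (a.var(axis=0) == 0) & (b.var(axis=0) == 0)
    if var0.any():
        same_mean = np.isclose(a.mean(axis=0), b.mean(axis=0))
        # both groups constant: p=1 when means coincide, p=0 for a perfect split
        p[var0 & same_mean] = 1.0
        p[var0 & ~same_mean] = 0.0
    p[~np.isfinite(p)] = 1.0
    return p


def _ranksum_p(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Two-sided Mann-Whitney rank-sum p, normal approximation with tie correction."""
    with np.errstate(divide="ignore", invalid="ignore"):
        p = stats.mannwhitneyu(a, b, axis=0, alternative="two-sided", method="asymptotic").pvalue
    p = np.asarray(p, dtype=float)
    # all observations tied within a gene -> no evidence either way
    allsame = np.ptp(np.vstack([a, b]), axis=0) == 0
    p[allsame] = 1.0
    p[~np.isfinite(p)] = 1.0
    return np.clip(p, 0.0, 1.0)


def differential_test_one_vs_rest(
    expr: ExpressionMatrix, labels: LabelTable, class_name: str
) -> pd.DataFrame:
    """Per-gene Welch-t and rank-sum p-values plus log2fc for one class vs rest."""
    if class_name not in labels.class_names:
        raise FormatError(f"unknown class {class_name!r}")
    aligned = labels.aligned_to(expr.sample_ids)
    mask = np.array([l == class_name for l in aligned.labels])
    if mask.sum() < 2 or (~mask).sum() < 2:
        raise FormatError(f"class {class_name!r} needs >=2 samples on each side")
    a, b = expr.values[mask], expr.values[~mask]
    return pd.DataFrame(
        {
            "class": class_name,
            "gene_id": expr.gene_ids,
            "log2fc": log2_fold_change(expr, mask),
            "p_t": _welch_p(a, b),
            "p_w": _ranksum_p(a, b),
        }
    )


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if not np.all(np.isfinite(p)) or p.min() < 0 or p.max() > 1:
        raise ConfigError("p-values must be finite and within [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_degs(
    expr: ExpressionMatrix,
    labels: LabelTable,
    fc_threshold: float = 1.0,
    q_threshold: float = 0.05,
) -> tuple[list[str], pd.DataFrame]:
    """Run every one-vs-rest comparison and gate on |log2fc| and both FDRs.

    Returns the union of selected genes (original gene order) and the full
    per-(class, gene) statistics table.
    """
    if len(labels.class_names) < 2:
        raise FormatError("need at least 2 classes")
    frames = []
    for cname in labels.class_names:
        tbl = differential_test_one_vs_rest(expr, labels, cname)
        tbl["q_t"] = bh_adjust(tbl["p_t"].to_numpy())
        tbl["q_w"] = bh_adjust(tbl["p_w"].to_numpy())
        tbl["selected"] = (
            (tbl["log2fc"].abs() > fc_threshold)
            & (tbl["q_t"] < q_threshold)
            & (tbl["q_w"] < q_threshold)
        )
        frames.append(tbl)
    table = pd.concat(frames, ignore_index=True)[DEG_COLUMNS]
    chosen = set(table.loc[table["selected"], "gene_id"])
    ordered = [g for g in expr.gene_ids if g in chosen]
    return ordered, table
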