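"""Readers/writers for expression matrices, label tables, configs and run reports.

Canonical on-disk dialect: tab-separated, UTF-8, '.' decimal, first column
named ``sample_id``.  Values are assumed already log2-transformed/normalized;
nothing here re-normalizes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, FormatError, ParseError

logger = logging.getLogger("aconas")


def setup_logging(logfile: str | Path | None = None, level: int = logging.INFO) -> None:
    """Route package logs to stderr (and optionally a file) with ISO timestamps."""
    fmt = logging.Formatter(
        "%(asctime)s %(levelname)s %(name)s: %(message)s", datefmt="%Y-%m-%dT%H:%M:%S"
    )
    logger.setLevel(level)
    logger.handlers.clear()
    sh = logging.StreamHandler(sys.stderr)
    sh.setFormatter(fmt)
    logger.addHandler(sh)
    if logfile is not None:
        fh = logging.FileHandler(logfile)
        fh.setFormatter(fmt)
        logger.addHandler(fh)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Samples x genes matrix of finite log2-scale expression values."""

    sample_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise FormatError("expression values must be a 2-D array")
        n, g = self.values.shape
        if n != len(self.sample_ids) or g != len(self.gene_ids):
            raise FormatError(
                f"shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.gene_ids)} genes"
            )
        if len(set(self.sample_ids)) != n:
            raise FormatError("duplicate sample identifiers")
        if len(set(self.gene_ids)) != g:
            raise FormatError("duplicate gene identifiers")
        if not np.all(np.isfinite(self.values)):
            raise FormatError("non-finite expression values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in idx]
        if missing:
            raise FormatError(f"genes not present in matrix: {missing[:5]}")
        cols = [idx[g] for g in gene_ids]
        return ExpressionMatrix(list(self.sample_ids), list(gene_ids), self.values[:, cols])

    def subset_samples(self, indices: Sequence[int]) -> "ExpressionMatrix":
        idx = list(indices)
        return ExpressionMatrix(
            [self.sample_ids[i] for i in idx], list(self.gene_ids), self.values[idx]
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.gene_ids == other.gene_ids
            and np.array_equal(self.values, other.values)
        )


@dataclass
class LabelTable:
    """Per-sample class labels with an explicit class ordering."""

    sample_ids: list[str]
    labels: list[str]
    class_names: list[str]

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.labels):
            raise FormatError("sample_ids and labels length mismatch")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample identifiers in label table")
        if len(self.class_names) < 2:
            raise FormatError("need at least 2 classes")
        if len(set(self.class_names)) != len(self.class_names):
            raise FormatError("duplicate class names")
        unknown = set(self.labels) - set(self.class_names)
        if unknown:
            raise FormatError(f"labels outside class set: {sorted(unknown)}")

    def encoded(self) -> np.ndarray:
        """Labels as integer indices into ``class_names``."""
        lut = {c: i for i, c in enumerate(self.class_names)}
        return np.array([lut[l] for l in self.labels], dtype=np.int64)

    def aligned_to(self, sample_ids: Sequence[str]) -> "LabelTable":
        lut = dict(zip(self.sample_ids, self.labels))
        missing = [s for s in sample_ids if s not in lut]
        if missing:
            raise FormatError(f"samples without labels: {missing[:5]}")
        return LabelTable(list(sample_ids), [lut[s] for s in sample_ids], list(self.class_names))


@dataclass
class RunConfig:
    """Everything needed to reproduce a run; see ``from_file``."""

    pools: dict[str, Any] = field(default_factory=dict)
    aco: dict[str, Any] = field(default_factory=dict)
    deg: dict[str, float] = field(default_factory=lambda: {"fc_threshold": 1.0, "q_threshold": 0.05})
    cv_folds: int = 10
    seed: int = 0
    paths: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cv_folds < 2:
            raise ConfigError("cv_folds must be >= 2")
        for key in ("fc_threshold", "q_threshold"):
            if self.deg.get(key, 1.0) <= 0:
                raise ConfigError(f"deg.{key} must be positive")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) if path.suffix in {".yaml", ".yml"} else json.load(fh)
        if raw is None:
            raw = {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression_matrix(
    path: str | Path,
    orientation: str = "samples_in_rows",
    missing: str = "reject",
) -> ExpressionMatrix:
    """Load a delimited expression matrix.

    Parameters
    ----------
    orientation:
        ``samples_in_rows`` (canonical) or ``genes_in_rows`` (transposed on load).
    missing:
        ``reject`` (default) fails on any non-numeric/missing cell;
        ``mean`` imputes missing cells with the gene mean.
    """
    if orientation not in {"samples_in_rows", "genes_in_rows"}:
        raise ConfigError(f"unknown orientation: {orientation!r}")
    if missing not in {"reject", "mean"}:
        raise ConfigError(f"unknown missing policy: {missing!r}")
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=str, keep_default_na=False)
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise FormatError(f"{path}: duplicate identifiers")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & (df.astype(str).values != "")
    blank = df.astype(str).values == ""
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"{path}: non-numeric value {df.iat[i, j]!r} at row {df.index[i]!r}, "
            f"column {df.columns[j]!r}"
        )
    values = numeric.to_numpy(dtype=np.float64)
    if blank.any():
        if missing == "reject":
            i, j = np.argwhere(blank)[0]
            raise ParseError(
                f"{path}: missing value at row {df.index[i]!r}, column {df.columns[j]!r}"
            )
        col_means = np.nanmean(np.where(blank, np.nan, values), axis=0)
        values = np.where(blank, col_means[None, :], values)
    row_ids = [str(x) for x in df.index]
    col_ids = [str(x) for x in df.columns]
    if orientation == "genes_in_rows":
        return ExpressionMatrix(col_ids, row_ids, values.T)
    return ExpressionMatrix(row_ids, col_ids, values)


def write_expression_matrix(expr: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(expr.values, index=expr.sample_ids, columns=expr.gene_ids)
    df.index.name = "sample_id"
    df.to_csv(path, sep=_sep_for(path))


def read_labels(path: str | Path, class_order: Sequence[str] | None = None) -> LabelTable:
    """Load a two-column (sample_id, label) table."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    if df.shape[1] != 2:
        raise FormatError(f"{path}: expected exactly 2 columns, got {df.shape[1]}")
    sample_ids = [str(x) for x in df.iloc[:, 0]]
    labels = [str(x) for x in df.iloc[:, 1]]
    if class_order is not None:
        names = list(class_order)
    else:
        names = sorted(set(labels))
    return LabelTable(sample_ids, labels, names)


def write_labels(table: LabelTable, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame({"sample_id": table.sample_ids, "label": table.labels}).to_csv(
        path, sep=_sep_for(path), index=False
    )


# ---------------------------------------------------------------------------
# run report
# ---------------------------------------------------------------------------


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def write_run_report(result: Any, metrics: Any, path: str | Path, seed: int | None = None) -> None:
    """Serialize a search result plus evaluation metrics to JSON (round-trips)."""
    report = {
        "best_individual": _jsonable(result.best.individual.to_dict()),
        "best_fitness": _jsonable(result.best.f),
        "fitness_trace": _jsonable(result.iteration_best),
        "mean_trace": _jsonable(result.iteration_mean),
        "surrogate_scores": _jsonable(result.surrogate_scores),
        "seed": int(result.seed if seed is None else seed),
        "metrics": _jsonable(metrics.to_dict() if hasattr(metrics, "to_dict") else metrics),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_run_report(path: str | Path) -> dict[str, Any]:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
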