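"""Synthetic multiclass expression data with planted class-informative genes.

Background genes are iid Normal(baseline, noise_sd) on the log2 scale; each
class owns a disjoint block of informative genes whose mean is shifted by
``effect_size`` in that class only.  Everything is deterministic given the
spec seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import ExpressionMatrix, LabelTable
from .errors import ConfigError

BASELINE = 7.0  # typical microarray log2 intensity


@dataclass
class SyntheticSpec:
    n_classes: int = 4
    n_per_class: int = 50
    n_genes: int = 1000
    n_informative_per_class: int = 10
    effect_size: float = 2.0
    noise_sd: float = 1.0
    seed: int = 0
    class_proportions: list[float] | None = None  # optional imbalance

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ConfigError("need at least 2 classes")
        if self.n_informative_per_class * self.n_classes > self.n_genes:
            raise ConfigError("informative genes exceed total genes")
        if self.effect_size < 0:
            raise ConfigError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be > 0")
        if self.class_proportions is not None:
            if len(self.class_proportions) != self.n_classes:
                raise ConfigError("class_proportions length mismatch")
            if any(p <= 0 for p in self.class_proportions):
                raise ConfigError("class_proportions must be positive")


@dataclass
class SyntheticDataset:
    expression: ExpressionMatrix
    labels: LabelTable
    truth_informative: dict[str, list[str]] = field(default_factory=dict)


def _ids(prefix: str, n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


def generate_classification_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Draw a dataset per ``spec``; truth gene sets are disjoint across classes."""
    rng = np.random.default_rng(spec.seed)
    class_names = [f"C{i + 1}" for i in range(spec.n_classes)]
    if spec.class_proportions is None:
        counts = [spec.n_per_class] * spec.n_classes
    else:
        total = spec.n_per_class * spec.n_classes
        weights = np.asarray(spec.class_proportions, dtype=float)
        counts = np.maximum(1, np.round(weights / weights.sum() * total).astype(int)).tolist()
    n_samples = int(sum(counts))
    gene_ids = _ids("G", spec.n_genes)
    sample_ids = _ids("S", n_samples)

    values = rng.normal(BASELINE, spec.noise_sd, size=(n_samples, spec.n_genes))
    labels: list[str] = []
    for cname, cnt in zip(class_names, counts):
        labels.extend([cname] * cnt)

    # disjoint informative blocks, placement randomized by the same seed
    perm = rng.permutation(spec.n_genes)
    truth: dict[str, list[str]] = {}
    offsets = np.cumsum([0] + counts)
    for c, cname in enumerate(class_names):
        cols = perm[c * spec.n_informative_per_class : (c + 1) * spec.n_informative_per_class]
        rows = slice(offsets[c], offsets[c + 1])
        values[rows, cols] += spec.effect_size
        truth[cname] = sorted(gene_ids[j] for j in cols)

    expr = ExpressionMatrix(sample_ids, gene_ids, values)
    table = LabelTable(sample_ids, labels, class_names)
    return SyntheticDataset(expr, table, truth)


def generate_null_dataset(
    n_samples: int, n_genes: int, n_classes: int, seed: int, noise_sd: float = 1.0
) -> SyntheticDataset:
    """Expression independent of labels; truth_informative is empty."""
    if n_samples < 2 * n_classes:
        raise ConfigError("need at least 2 samples per class")
    rng = np.random.default_rng(seed)
    class_names = [f"C{i + 1}" for i in range(n_classes)]
    values = rng.normal(BASELINE, noise_sd, size=(n_samples, n_genes))
    # round-robin assignment guarantees >=2 per class and is independent of values
    labels = [class_names[i % n_classes] for i in range(n_samples)]
    expr = ExpressionMatrix(_ids("S", n_samples), _ids("G", n_genes), values)
    return SyntheticDataset(expr, LabelTable(expr.sample_ids, labels, class_names), {})
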