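"""Pheromone-guided architecture search with a tree-ensemble surrogate.

Each iteration: ants walk the layered search graph sampling successors in
proportion to pheromone^alpha * heuristic^beta (local evaporation applied per
step), every constructed candidate is scored by stratified-CV accuracy of the
trained network, a gradient-boosted-tree surrogate is re-fit on all encoded
candidates seen so far, its per-column importances (scaled by fit quality)
become the new edge heuristics, and the globally best path receives the only
pheromone deposit.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.ensemble import GradientBoostingRegressor
from sklearn.model_selection import StratifiedKFold

from .data_io import ExpressionMatrix, LabelTable, logger
from .errors import ConfigError, TrainingDivergedError
from .network import fit_classifier
from .search_space import (
    SINK,
    SOURCE,
    HyperparameterPool,
    Individual,
    Node,
    SearchGraph,
    build_search_graph,
    encode_individual,
)

ETA_FLOOR = 1e-6


@dataclass
class ACOConfig:
    population_size: int = 10
    iterations: int = 10
    alpha: float = 1.0   # pheromone exponent
    beta: float = 1.0    # heuristic exponent
    phi: float = 0.3     # global decay
    psi: float = 0.1     # local decay
    xi0: float = 0.02    # initial pheromone / local-update target
    surrogate_trees: int = 1000
    deposit: str = "eta_times_f"  # or "f_only"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.phi <= 1) or not (0 < self.psi <= 1):
            raise ConfigError("phi and psi must lie in (0, 1]")
        if self.alpha < 0 or self.beta < 0:
            raise ConfigError("alpha and beta must be >= 0")
        if self.xi0 <= 0:
            raise ConfigError("xi0 must be > 0")
        if self.population_size < 2:
            raise ConfigError("population_size must be >= 2")
        if self.deposit not in {"eta_times_f", "f_only"}:
            raise ConfigError(f"unknown deposit mode {self.deposit!r}")


@dataclass
class FitnessRecord:
    individual: Individual
    encoded: np.ndarray
    f: float
    fold_accuracies: list[float] = field(default_factory=list)
    aborted: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.f <= 1.0):
            raise ConfigError("fitness must lie in [0, 1]")
        if self.aborted and self.f != 0.0:
            raise ConfigError("aborted evaluations must score 0")


@dataclass
class SearchResult:
    best: FitnessRecord
    iteration_best: list[float]
    iteration_mean: list[float]
    records: list[FitnessRecord]
    surrogate_scores: list[float]
    seed: int


# ---------------------------------------------------------------------------
# transition + pheromone rules
# ---------------------------------------------------------------------------


def transition_probabilities(
    graph: SearchGraph, node: Node, depth: int | None, alpha: float, beta: float
) -> tuple[list[Node], np.ndarray]:
    """Feasible successors of ``node`` and their selection probabilities.

    P(s) = xi_rs^alpha * eta_rs^beta / sum over feasible l; a uniform
    fallback (with warning) applies when every feasible weight is zero.
    """
    candidates = graph.candidate_edges(node, depth)
    if not candidates:
        raise ConfigError(f"node {node} has no feasible successors")
    weights = np.array([(e.xi**alpha) * (e.eta**beta) for _, e in candidates])
    total = weights.sum()
    if total <= 0 or not np.isfinite(total):
        logger.warning("all feasible transition weights zero at %s; uniform fallback", node)
        probs = np.full(len(candidates), 1.0 / len(candidates))
    else:
        probs = weights / total
    return [n for n, _ in candidates], probs


def local_pheromone_update(
    graph: SearchGraph, edge_key: tuple[Node, Node], psi: float, xi0: float
) -> None:
    """xi <- (1-psi)*xi + psi*xi0 on the traversed edge (evaporation toward xi0)."""
    edge = graph.edges[edge_key]
    edge.xi = (1.0 - psi) * edge.xi + psi * xi0


def global_pheromone_update(
    graph: SearchGraph, best: FitnessRecord, phi: float, deposit: str = "eta_times_f"
) -> None:
    """Strengthen only the globally best path: xi <- (1-phi)*xi + phi*delta."""
    path = graph.path_of(best.individual)
    for u, v in zip(path[:-1], path[1:]):
        edge = graph.edges[(u, v)]
        delta = best.f if deposit == "f_only" else edge.eta * best.f
        edge.xi = (1.0 - phi) * edge.xi + phi * delta


def construct_individual(
    graph: SearchGraph,
    config: ACOConfig,
    rng: np.random.Generator,
    update_local: bool = True,
) -> tuple[Individual, list[Node]]:
    """One source->sink walk; local evaporation is applied per step taken."""
    path: list[Node] = [SOURCE]
    depth: int | None = None
    node: Node = SOURCE
    while node != SINK:
        succ, probs = transition_probabilities(graph, node, depth, config.alpha, config.beta)
        nxt = succ[rng.choice(len(succ), p=probs)]
        if update_local:
            local_pheromone_update(graph, (node, nxt), config.psi, config.xi0)
        if nxt != SINK and graph.slots[nxt[0]].name == "depth":
            depth = graph.slots[nxt[0]].values[nxt[1]]
        path.append(nxt)
        node = nxt
    return graph.individual_of(path), path


# ---------------------------------------------------------------------------
# fitness
# ---------------------------------------------------------------------------


def _record_seed(base_seed: int, encoded: np.ndarray) -> int:
    """Per-candidate seed that is stable across iterations (cache-consistent)."""
    return (base_seed + zlib.crc32(encoded.tobytes())) % (2**32)


def cv_fitness(
    individual: Individual,
    expr: ExpressionMatrix,
    labels: LabelTable,
    cv_folds: int,
    seed: int,
    patience: int = 50,
    batch_size: int = 32,
) -> tuple[float, list[float], bool]:
    """Mean stratified k-fold validation accuracy of the trained network.

    Each fold's held-out part doubles as the early-stopping validation set;
    a diverging fold scores 0 and sets the aborted flag.
    """
    aligned = labels.aligned_to(expr.sample_ids)
    y = aligned.encoded()
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed % (2**32))
    accs: list[float] = []
    aborted = False
    for tr, te in skf.split(expr.values, y):
        tr_expr = expr.subset_samples(tr)
        tr_lab = LabelTable(
            tr_expr.sample_ids, [aligned.labels[i] for i in tr], list(aligned.class_names)
        )
        te_expr = expr.subset_samples(te)
        te_lab = LabelTable(
            te_expr.sample_ids, [aligned.labels[i] for i in te], list(aligned.class_names)
        )
        try:
            model = fit_classifier(
                tr_expr, tr_lab, individual,
                val_expr=te_expr, val_labels=te_lab,
                patience=patience, seed=seed, batch_size=batch_size,
            )
            _, pred = model.predict(te_expr)
            accs.append(float(np.mean([p == t for p, t in zip(pred, te_lab.labels)])))
        except TrainingDivergedError:
            logger.warning("training diverged for %s; fold scored 0", individual)
            accs.append(0.0)
            aborted = True
    return float(np.mean(accs)), accs, aborted


def evaluate_population(
    population: Sequence[Individual],
    pool: HyperparameterPool,
    expr: ExpressionMatrix | None,
    labels: LabelTable | None,
    cv_folds: int,
    seed: int,
    cache: dict[bytes, FitnessRecord] | None = None,
    fitness_fn: Callable[[Individual], float] | None = None,
    patience: int = 50,
    batch_size: int = 32,
) -> list[FitnessRecord]:
    """Score every Individual; duplicates share one evaluation via the cache.

    ``fitness_fn`` short-circuits network training with a deterministic
    objective (used for search diagnostics and tests).
    """
    cache = cache if cache is not None else {}
    out: list[FitnessRecord] = []
    for ind in population:
        enc = encode_individual(ind, pool)
        key = enc.tobytes()
        if key in cache:
            out.append(cache[key])
            continue
        if fitness_fn is not None:
            f = float(fitness_fn(ind))
            rec = FitnessRecord(ind, enc, f)
        else:
            f, accs, aborted = cv_fitness(
                ind, expr, labels, cv_folds, _record_seed(seed, enc),
                patience=patience, batch_size=batch_size,
            )
            if aborted:
                f = 0.0
            rec = FitnessRecord(ind, enc, f, accs, aborted)
        cache[key] = rec
        out.append(rec)
    return out


# ---------------------------------------------------------------------------
# surrogate
# ---------------------------------------------------------------------------


def fit_surrogate_and_weights(
    records: Sequence[FitnessRecord], trees: int = 1000, seed: int = 0
) -> tuple[float, np.ndarray]:
    """Gradient-boosted-tree regressor on encoded vectors -> fitness.

    Returns (nu, phi): nu is the training R^2 clipped to [0.01, 1]; phi is
    the per-encoding-column importance normalized to sum 1.  Degenerate
    fitness (fewer than 2 distinct values) falls back to nu=0.01, uniform phi.
    """
    X = np.array([r.encoded for r in records])
    y = np.array([r.f for r in records])
    n_cols = X.shape[1]
    uniform = np.full(n_cols, 1.0 / n_cols)
    if len(np.unique(y)) < 2:
        return 0.01, uniform
    model = GradientBoostingRegressor(
        n_estimators=trees, max_depth=3, learning_rate=0.1, random_state=seed % (2**32)
    )
    model.fit(X, y)
    nu = float(np.clip(model.score(X, y), 0.01, 1.0))
    phi = np.asarray(model.feature_importances_, dtype=float)
    total = phi.sum()
    phi = uniform if total <= 0 else phi / total
    return nu, phi


def update_heuristic(graph: SearchGraph, nu: float, phi: np.ndarray) -> None:
    """eta(r,s) = nu * importance of the destination node's encoding column.

    Categorical destinations read their own one-hot column; numeric
    destinations share their slot's single column.  Sink edges keep eta=1
    (the sink is never a choice).  All values are floored at 1e-6.
    """
    for (u, v), edge in graph.edges.items():
        if v == SINK:
            edge.eta = 1.0
            continue
        slot = graph.slots[v[0]]
        col = slot.columns_for(v[1])[0]
        edge.eta = max(nu * float(phi[col]), ETA_FLOOR)


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------


def run_search(
    expr: ExpressionMatrix | None,
    labels: LabelTable | None,
    pool: HyperparameterPool,
    config: ACOConfig,
    cv_folds: int = 10,
    fitness_fn: Callable[[Individual], float] | None = None,
    patience: int = 50,
    batch_size: int = 32,
) -> SearchResult:
    """Iterate construct -> evaluate -> surrogate -> heuristic -> global update.

    Heuristics are uniform (eta=1) in iteration 1 before any surrogate
    exists.  Fully reproducible given ``config.seed``.
    """
    if fitness_fn is None and (expr is None or labels is None):
        raise ConfigError("expression and labels are required without a fitness_fn")
    graph = build_search_graph(pool, xi0=config.xi0, eta0=1.0)
    rng = np.random.default_rng(config.seed)
    cache: dict[bytes, FitnessRecord] = {}
    all_records: list[FitnessRecord] = []
    iteration_best: list[float] = []
    iteration_mean: list[float] = []
    surrogate_scores: list[float] = []
    best: FitnessRecord | None = None
    for it in range(config.iterations):
        population = [
            construct_individual(graph, config, rng)[0]
            for _ in range(config.population_size)
        ]
        records = evaluate_population(
            population, pool, expr, labels, cv_folds, config.seed,
            cache=cache, fitness_fn=fitness_fn,
            patience=patience, batch_size=batch_size,
        )
        all_records.extend(records)
        for rec in records:
            if best is None or rec.f > best.f:
                best = rec
        iteration_best.append(best.f)
        iteration_mean.append(float(np.mean([r.f for r in records])))
        nu, phi = fit_surrogate_and_weights(
            list(cache.values()), trees=config.surrogate_trees, seed=config.seed
        )
        surrogate_scores.append(nu)
        update_heuristic(graph, nu, phi)
        global_pheromone_update(graph, best, config.phi, config.deposit)
        logger.info(
            "iteration %d/%d: best=%.4f mean=%.4f nu=%.3f",
            it + 1, config.iterations, iteration_best[-1], iteration_mean[-1], nu,
        )
    return SearchResult(
        best=best,
        iteration_best=iteration_best,
        iteration_mean=iteration_mean,
        records=all_records,
        surrogate_scores=surrogate_scores,
        seed=config.seed,
    )


def random_search(
    pool: HyperparameterPool,
    budget: int,
    fitness_fn: Callable[[Individual], float],
    seed: int = 0,
) -> tuple[Individual, float]:
    """Uniform-sampling baseline with the same evaluation budget."""
    rng = np.random.default_rng(seed)
    best_ind, best_f = None, -np.inf
    for _ in range(budget):
        ind = pool.random_individual(rng)
        f = float(fitness_fn(ind))
        if f > best_f:
            best_ind, best_f = ind, f
    return best_ind, best_f
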