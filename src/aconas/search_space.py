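"""Hyperparameter pool, candidate encoding, and the layered search graph.

A candidate configuration (``Individual``) is an ordered assignment
[epochs, optimizer, learning rate, depth, then per-layer
(width, activation, dropout, batch-norm, l1, l2)].  Candidates map 1:1 onto
source->sink paths of a layered DAG whose edges carry pheromone and heuristic
values, and onto fixed-length hybrid vectors: one-hot blocks for categorical
slots, raw numeric entries for numeric slots, zero padding for unused layers.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .errors import DecodingError, EncodingError, ConfigError

SOURCE = ("source",)
SINK = ("sink",)

LAYER_FIELDS = ("width", "activation", "dropout", "batch_norm", "l1", "l2")


@dataclass(frozen=True)
class LayerSpec:
    width: int
    activation: str
    dropout: float
    batch_norm: bool
    l1: float
    l2: float


@dataclass(frozen=True)
class Individual:
    epochs: int
    optimizer: str
    learning_rate: float
    layers: tuple[LayerSpec, ...]

    @property
    def depth(self) -> int:
        return len(self.layers)

    def to_dict(self) -> dict:
        return {
            "epochs": self.epochs,
            "optimizer": self.optimizer,
            "learning_rate": self.learning_rate,
            "layers": [vars(l).copy() for l in self.layers],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Individual":
        return cls(
            epochs=int(d["epochs"]),
            optimizer=str(d["optimizer"]),
            learning_rate=float(d["learning_rate"]),
            layers=tuple(LayerSpec(**l) for l in d["layers"]),
        )


@dataclass
class HyperparameterPool:
    epochs_choices: list[int]
    optimizer_choices: list[str]
    lr_choices: list[float]
    depth_choices: list[int]
    width_choices: list[int]
    activation_choices: list[str]
    dropout_choices: list[float]
    bn_choices: list[bool] = field(default_factory=lambda: [True, False])
    l1_choices: list[float] = field(default_factory=lambda: [0.0])
    l2_choices: list[float] = field(default_factory=lambda: [0.0])

    def __post_init__(self) -> None:
        for name, choices in vars(self).items():
            if len(choices) == 0:
                raise ConfigError(f"{name} is empty")
            if len(set(choices)) != len(choices):
                raise ConfigError(f"{name} has duplicates")
        if any(w <= 0 for w in self.width_choices):
            raise ConfigError("widths must be positive")
        if any(not (0 <= r < 1) for r in self.dropout_choices):
            raise ConfigError("dropout rates must lie in [0, 1)")
        if any(k < 1 for k in self.depth_choices):
            raise ConfigError("depths must be >= 1")
        if any(g < 0 for g in self.l1_choices + self.l2_choices):
            raise ConfigError("penalty coefficients must be >= 0")

    @property
    def max_depth(self) -> int:
        return max(self.depth_choices)

    def layer_choices(self, fld: str) -> list:
        return {
            "width": self.width_choices,
            "activation": self.activation_choices,
            "dropout": self.dropout_choices,
            "batch_norm": self.bn_choices,
            "l1": self.l1_choices,
            "l2": self.l2_choices,
        }[fld]

    def n_configurations(self) -> int:
        """Total enumerable configurations over all depths."""
        per_layer = 1
        for fld in LAYER_FIELDS:
            per_layer *= len(self.layer_choices(fld))
        head = (
            len(self.epochs_choices) * len(self.optimizer_choices) * len(self.lr_choices)
        )
        return head * sum(per_layer**k for k in self.depth_choices)

    def to_dict(self) -> dict:
        return {k: list(v) for k, v in vars(self).items()}

    @classmethod
    def from_dict(cls, d: dict) -> "HyperparameterPool":
        return cls(**d)

    def random_individual(self, rng: np.random.Generator) -> Individual:
        """Uniform draw: depth uniform, then each slot uniform."""
        k = int(rng.choice(self.depth_choices))
        layers = tuple(
            LayerSpec(
                width=int(rng.choice(self.width_choices)),
                activation=str(rng.choice(self.activation_choices)),
                dropout=float(rng.choice(self.dropout_choices)),
                batch_norm=bool(self.bn_choices[rng.integers(len(self.bn_choices))]),
                l1=float(rng.choice(self.l1_choices)),
                l2=float(rng.choice(self.l2_choices)),
            )
            for _ in range(k)
        )
        return Individual(
            epochs=int(rng.choice(self.epochs_choices)),
            optimizer=str(rng.choice(self.optimizer_choices)),
            learning_rate=float(rng.choice(self.lr_choices)),
            layers=layers,
        )

    def iter_individuals(self) -> Iterator[Individual]:
        """Exhaustive enumeration (use only on small pools)."""
        layer_opts = [
            LayerSpec(*combo)
            for combo in itertools.product(*(self.layer_choices(f) for f in LAYER_FIELDS))
        ]
        for e, tau, alpha in itertools.product(
            self.epochs_choices, self.optimizer_choices, self.lr_choices
        ):
            for k in self.depth_choices:
                for layers in itertools.product(layer_opts, repeat=k):
                    yield Individual(e, tau, alpha, tuple(layers))


def default_pool() -> HyperparameterPool:
    """Documented default search pool (config-overridable)."""
    return HyperparameterPool(
        epochs_choices=[50, 100, 200, 400],
        optimizer_choices=["sgd", "adam", "rmsprop"],
        lr_choices=[1e-2, 1e-3, 1e-4],
        depth_choices=[1, 2, 3],
        width_choices=[30, 100, 500, 1000],
        activation_choices=["relu", "tanh", "sigmoid"],
        dropout_choices=[0.0, 0.2, 0.5],
        bn_choices=[True, False],
        l1_choices=[0.0, 1e-5, 1e-3],
        l2_choices=[0.0, 1e-5, 1e-3],
    )


# ---------------------------------------------------------------------------
# slot layout
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Slot:
    """One decision position: its candidate values and encoding columns."""

    name: str
    kind: str  # "numeric" | "categorical"
    values: tuple
    col_start: int
    n_cols: int
    layer: int | None = None  # 1-based layer index for per-layer slots
    fld: str | None = None

    def columns_for(self, value_idx: int) -> list[int]:
        if self.kind == "numeric":
            return [self.col_start]
        return [self.col_start + value_idx]


def build_slots(pool: HyperparameterPool) -> list[Slot]:
    """Fixed decision order: e, tau, alpha, k, then per-layer field slots."""
    slots: list[Slot] = []
    col = 0

    def add(name: str, kind: str, values: Sequence, layer=None, fld=None) -> None:
        nonlocal col
        n_cols = 1 if kind == "numeric" else len(values)
        slots.append(Slot(name, kind, tuple(values), col, n_cols, layer, fld))
        col += n_cols

    add("epochs", "numeric", pool.epochs_choices)
    add("optimizer", "categorical", pool.optimizer_choices)
    add("learning_rate", "numeric", pool.lr_choices)
    add("depth", "categorical", pool.depth_choices)
    kinds = {
        "width": "numeric",
        "activation": "categorical",
        "dropout": "numeric",
        "batch_norm": "categorical",
        "l1": "numeric",
        "l2": "numeric",
    }
    for d in range(1, pool.max_depth + 1):
        for fld in LAYER_FIELDS:
            add(f"L{d}.{fld}", kinds[fld], pool.layer_choices(fld), layer=d, fld=fld)
    return slots


def encoding_length(pool: HyperparameterPool) -> int:
    slots = build_slots(pool)
    last = slots[-1]
    return last.col_start + last.n_cols


def _value_index(slot: Slot, value) -> int:
    for i, v in enumerate(slot.values):
        if v == value or (
            isinstance(v, float) and isinstance(value, float) and np.isclose(v, value)
        ):
            return i
    raise EncodingError(f"value {value!r} not in pool for slot {slot.name}")


def _slot_values_of(p: Individual, slot: Slot):
    if slot.layer is None:
        return getattr(p, slot.name) if slot.name != "depth" else p.depth
    if slot.layer > p.depth:
        return None
    return getattr(p.layers[slot.layer - 1], slot.fld)


def encode_individual(p: Individual, pool: HyperparameterPool) -> np.ndarray:
    """Fixed-length hybrid vector; unused layer slots are zero-filled."""
    if not (1 <= p.depth <= pool.max_depth) or p.depth not in pool.depth_choices:
        raise EncodingError(f"depth {p.depth} not in pool")
    slots = build_slots(pool)
    vec = np.zeros(encoding_length(pool))
    for slot in slots:
        value = _slot_values_of(p, slot)
        if value is None:
            continue  # padding for layers beyond p.depth
        idx = _value_index(slot, value)
        if slot.kind == "numeric":
            vec[slot.col_start] = float(slot.values[idx])
        else:
            vec[slot.col_start + idx] = 1.0
    return vec


def _decode_categorical(vec: np.ndarray, slot: Slot):
    block = vec[slot.col_start : slot.col_start + slot.n_cols]
    ones = np.flatnonzero(block == 1.0)
    if len(ones) != 1 or not np.all(np.isin(block, (0.0, 1.0))):
        raise DecodingError(f"malformed one-hot block for slot {slot.name}")
    return slot.values[ones[0]]


def _decode_numeric(vec: np.ndarray, slot: Slot):
    raw = vec[slot.col_start]
    for v in slot.values:
        if raw == float(v) or np.isclose(raw, float(v), rtol=0, atol=0):
            return v
    raise DecodingError(f"value {raw!r} not in pool for slot {slot.name}")


def decode_individual(vec: np.ndarray, pool: HyperparameterPool) -> Individual:
    """Inverse of :func:`encode_individual`; rejects malformed vectors."""
    vec = np.asarray(vec, dtype=float)
    if vec.shape != (encoding_length(pool),):
        raise DecodingError(f"expected length {encoding_length(pool)}, got {vec.shape}")
    slots = {s.name: s for s in build_slots(pool)}
    depth = _decode_categorical(vec, slots["depth"])
    layers = []
    for d in range(1, depth + 1):
        fields = {}
        for fld in LAYER_FIELDS:
            slot = slots[f"L{d}.{fld}"]
            fields[fld] = (
                _decode_categorical(vec, slot)
                if slot.kind == "categorical"
                else _decode_numeric(vec, slot)
            )
        layers.append(LayerSpec(**fields))
    return Individual(
        epochs=int(_decode_numeric(vec, slots["epochs"])),
        optimizer=str(_decode_categorical(vec, slots["optimizer"])),
        learning_rate=float(_decode_numeric(vec, slots["learning_rate"])),
        layers=tuple(layers),
    )


# ---------------------------------------------------------------------------
# search graph
# ---------------------------------------------------------------------------

Node = tuple  # ("source",) | ("sink",) | (slot_index, value_index)


@dataclass
class Edge:
    xi: float
    eta: float


class SearchGraph:
    """Layered DAG over slot values; edges carry pheromone xi and heuristic eta.

    The depth slot decides how many layer blocks a walk traverses: after the
    last field slot of layer d the walk continues to layer d+1 when d < depth,
    otherwise it jumps to the sink.
    """

    def __init__(self, pool: HyperparameterPool, xi0: float = 1.0, eta0: float = 1.0):
        if xi0 <= 0:
            raise ConfigError("xi0 must be > 0")
        self.pool = pool
        self.slots = build_slots(pool)
        self._slot_index = {s.name: i for i, s in enumerate(self.slots)}
        self.xi0 = xi0
        self.edges: dict[tuple[Node, Node], Edge] = {}
        self._build(xi0, eta0)

    # -- construction -------------------------------------------------------

    def _slot_nodes(self, slot_idx: int) -> list[Node]:
        return [(slot_idx, j) for j in range(len(self.slots[slot_idx].values))]

    def _connect(self, frm: list[Node], to: list[Node], xi0: float, eta0: float) -> None:
        for u in frm:
            for v in to:
                self.edges[(u, v)] = Edge(xi0, eta0)

    def _build(self, xi0: float, eta0: float) -> None:
        s = self._slot_index
        self._connect([SOURCE], self._slot_nodes(s["epochs"]), xi0, eta0)
        self._connect(self._slot_nodes(s["epochs"]), self._slot_nodes(s["optimizer"]), xi0, eta0)
        self._connect(
            self._slot_nodes(s["optimizer"]), self._slot_nodes(s["learning_rate"]), xi0, eta0
        )
        self._connect(
            self._slot_nodes(s["learning_rate"]), self._slot_nodes(s["depth"]), xi0, eta0
        )
        self._connect(self._slot_nodes(s["depth"]), self._slot_nodes(s["L1.width"]), xi0, eta0)
        max_d = self.pool.max_depth
        for d in range(1, max_d + 1):
            chain = [f"L{d}.{fld}" for fld in LAYER_FIELDS]
            for a, b in zip(chain[:-1], chain[1:]):
                self._connect(self._slot_nodes(s[a]), self._slot_nodes(s[b]), xi0, eta0)
            last = self._slot_nodes(s[f"L{d}.l2"])
            if d in self.pool.depth_choices:
                self._connect(last, [SINK], xi0, eta0)
            if d < max_d:
                self._connect(last, self._slot_nodes(s[f"L{d + 1}.width"]), xi0, eta0)

    # -- navigation ---------------------------------------------------------

    def next_slot(self, node: Node, depth: int | None) -> int | None:
        """Slot index the walk moves to from ``node``; None means sink."""
        if node == SOURCE:
            return self._slot_index["epochs"]
        slot = self.slots[node[0]]
        if slot.name == "depth":
            return self._slot_index["L1.width"]
        if slot.fld == "l2":
            assert depth is not None
            if slot.layer == depth:
                return None
            return self._slot_index[f"L{slot.layer + 1}.width"]
        return node[0] + 1

    def candidate_edges(self, node: Node, depth: int | None) -> list[tuple[Node, Edge]]:
        """Feasible outgoing (successor, edge) pairs given the chosen depth."""
        nxt = self.next_slot(node, depth)
        targets = [SINK] if nxt is None else self._slot_nodes(nxt)
        return [(t, self.edges[(node, t)]) for t in targets]

    def path_of(self, p: Individual) -> list[Node]:
        """Source->sink node sequence realizing ``p``."""
        s = self._slot_index
        path: list[Node] = [SOURCE]

        def node_for(name: str, value) -> Node:
            slot = self.slots[s[name]]
            return (s[name], _value_index(slot, value))

        path.append(node_for("epochs", p.epochs))
        path.append(node_for("optimizer", p.optimizer))
        path.append(node_for("learning_rate", p.learning_rate))
        path.append(node_for("depth", p.depth))
        for d, layer in enumerate(p.layers, start=1):
            for fld in LAYER_FIELDS:
                path.append(node_for(f"L{d}.{fld}", getattr(layer, fld)))
        path.append(SINK)
        return path

    def individual_of(self, path: Sequence[Node]) -> Individual:
        """Inverse of :func:`path_of`."""
        values: dict[str, object] = {}
        for node in path:
            if node in (SOURCE, SINK):
                continue
            slot = self.slots[node[0]]
            values[slot.name] = slot.values[node[1]]
        depth = values["depth"]
        layers = tuple(
            LayerSpec(**{fld: values[f"L{d}.{fld}"] for fld in LAYER_FIELDS})
            for d in range(1, depth + 1)
        )
        return Individual(
            epochs=values["epochs"],
            optimizer=values["optimizer"],
            learning_rate=values["learning_rate"],
            layers=layers,
        )

    def iter_paths(self) -> Iterator[list[Node]]:
        """Enumerate all source->sink paths (small pools only)."""

        def extend(path: list[Node], depth: int | None) -> Iterator[list[Node]]:
            node = path[-1]
            if node != SOURCE and self.slots[node[0]].name == "depth":
                depth = self.slots[node[0]].values[node[1]]
            nxt = self.next_slot(node, depth)
            if nxt is None:
                yield path + [SINK]
                return
            for succ in self._slot_nodes(nxt):
                yield from extend(path + [succ], depth)

        yield from extend([SOURCE], None)

    def n_paths(self) -> int:
        """Closed-form path count (equals pool.n_configurations())."""
        return self.pool.n_configurations()


def build_search_graph(
    pool: HyperparameterPool, xi0: float = 1.0, eta0: float = 1.0
) -> SearchGraph:
    return SearchGraph(pool, xi0=xi0, eta0=eta0)
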