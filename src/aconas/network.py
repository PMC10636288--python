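"""Feed-forward classifier realized from an Individual, in plain numpy.

Each hidden block applies dense -> (batch norm) -> activation -> dropout;
the head is a dense layer with softmax.  The loss is mean negative
log-likelihood plus per-layer L1/L2 weight penalties.  Training runs the
configured optimizer for at most ``epochs`` epochs with early stopping on
validation accuracy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

from .data_io import ExpressionMatrix, LabelTable, logger
from .errors import AlignmentError, ConfigError, TrainingDivergedError
from .search_space import Individual

BN_EPS = 1e-5
PROB_CLIP = 1e-12
BN_MOMENTUM = 0.1


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def _relu(z: np.ndarray) -> np.ndarray:
    return np.maximum(z, 0.0)


def _relu_grad(z: np.ndarray, a: np.ndarray) -> np.ndarray:
    return (z > 0).astype(z.dtype)


def _tanh(z: np.ndarray) -> np.ndarray:
    return np.tanh(z)


def _tanh_grad(z: np.ndarray, a: np.ndarray) -> np.ndarray:
    return 1.0 - a * a


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * z))


def _sigmoid_grad(z: np.ndarray, a: np.ndarray) -> np.ndarray:
    return a * (1.0 - a)


ACTIVATIONS: dict[str, tuple[Callable, Callable]] = {
    "relu": (_relu, _relu_grad),
    "tanh": (_tanh, _tanh_grad),
    "sigmoid": (_sigmoid, _sigmoid_grad),
}


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def dropout_forward(
    x: np.ndarray, rate: float, training: bool, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray | None]:
    """Inverted dropout: Bernoulli(keep=1-rate) mask scaled by 1/(1-rate).

    Identity at inference or rate 0.  Returns (output, mask) where mask is
    None when no dropping happened.
    """
    if not (0.0 <= rate < 1.0):
        raise ConfigError("dropout rate must lie in [0, 1)")
    if not training or rate == 0.0:
        return x, None
    if rng is None:
        rng = np.random.default_rng()
    keep = 1.0 - rate
    mask = (rng.random(x.shape) < keep).astype(x.dtype) / keep
    return x * mask, mask


def batchnorm_forward(
    x: np.ndarray, gamma: np.ndarray, beta: np.ndarray, eps: float = BN_EPS
) -> np.ndarray:
    """Standardize each feature by batch statistics, then affine (gamma, beta)."""
    x = np.asarray(x, dtype=float)
    if x.shape[0] < 2:
        raise ConfigError("batch normalization needs batch size >= 2 in training")
    mean = x.mean(axis=0)
    var = x.var(axis=0)
    return gamma * (x - mean) / np.sqrt(var + eps) + beta


def compute_loss(
    probs: np.ndarray,
    y_onehot: np.ndarray,
    weights: list[np.ndarray],
    l1: list[float],
    l2: list[float],
) -> float:
    """Mean NLL plus sum_l l1_l*||W_l||_1 + l2_l*||W_l||_F^2."""
    p = np.asarray(probs, dtype=float)
    if np.any(p[y_onehot.astype(bool)] <= 0):
        logger.warning("zero probability at a true class; clipping at %g", PROB_CLIP)
    p = np.clip(p, PROB_CLIP, 1.0)
    nll = -np.sum(y_onehot * np.log(p)) / p.shape[0]
    penalty = 0.0
    for W, g1, g2 in zip(weights, l1, l2):
        if g1:
            penalty += g1 * np.abs(W).sum()
        if g2:
            penalty += g2 * np.square(W).sum()
    return float(nll + penalty)


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------


@dataclass
class _Block:
    W: np.ndarray          # (n_out, n_in)
    theta: np.ndarray      # (n_out,)
    activation: str | None  # None for the output head
    dropout: float = 0.0
    batch_norm: bool = False
    l1: float = 0.0
    l2: float = 0.0
    gamma: np.ndarray | None = None
    beta: np.ndarray | None = None
    run_mean: np.ndarray | None = None
    run_var: np.ndarray | None = None

    def params(self) -> list[np.ndarray]:
        out = [self.W, self.theta]
        if self.batch_norm:
            out += [self.gamma, self.beta]
        return out


class Network:
    """Untrained/trainable realization of an Individual's architecture."""

    def __init__(self, individual: Individual, n_inputs: int, n_classes: int, seed: int):
        if n_inputs < 1 or n_classes < 1:
            raise ConfigError("n_inputs and n_classes must be >= 1")
        if individual.depth < 1:
            raise ConfigError("at least one hidden layer is required")
        for layer in individual.layers:
            if layer.activation not in ACTIVATIONS:
                raise ConfigError(f"unknown activation {layer.activation!r}")
        self.individual = individual
        self.n_inputs = n_inputs
        self.n_classes = n_classes
        rng = np.random.default_rng(seed)
        self.blocks: list[_Block] = []
        fan_in = n_inputs
        for layer in individual.layers:
            self.blocks.append(self._make_block(rng, fan_in, layer.width, layer))
            fan_in = layer.width
        self.blocks.append(self._make_block(rng, fan_in, n_classes, None))

    @staticmethod
    def _make_block(rng: np.random.Generator, n_in: int, n_out: int, layer) -> _Block:
        scale = np.sqrt(2.0 / (n_in + n_out))  # Glorot
        W = rng.normal(0.0, scale, size=(n_out, n_in))
        theta = np.zeros(n_out)
        if layer is None:
            return _Block(W, theta, activation=None)
        blk = _Block(
            W,
            theta,
            activation=layer.activation,
            dropout=layer.dropout,
            batch_norm=layer.batch_norm,
            l1=layer.l1,
            l2=layer.l2,
        )
        if blk.batch_norm:
            blk.gamma = np.ones(n_out)
            blk.beta = np.zeros(n_out)
            blk.run_mean = np.zeros(n_out)
            blk.run_var = np.ones(n_out)
        return blk

    # -- forward ------------------------------------------------------------

    def forward(
        self, x: np.ndarray, training: bool = False, rng: np.random.Generator | None = None
    ) -> tuple[np.ndarray, list[dict]]:
        """Return (probabilities, per-block caches for backprop)."""
        caches = []
        a = np.asarray(x, dtype=float)
        for blk in self.blocks:
            cache: dict = {"a_in": a}
            z = a @ blk.W.T - blk.theta
            cache["z"] = z
            if blk.activation is None:
                probs = softmax(z)
                cache["probs"] = probs
                caches.append(cache)
                return probs, caches
            if blk.batch_norm:
                if training:
                    if z.shape[0] < 2:
                        raise ConfigError("batch normalization needs batch size >= 2")
                    mean = z.mean(axis=0)
                    var = z.var(axis=0)
                    blk.run_mean = (1 - BN_MOMENTUM) * blk.run_mean + BN_MOMENTUM * mean
                    blk.run_var = (1 - BN_MOMENTUM) * blk.run_var + BN_MOMENTUM * var
                else:
                    mean, var = blk.run_mean, blk.run_var
                inv_std = 1.0 / np.sqrt(var + BN_EPS)
                z_hat = (z - mean) * inv_std
                u = blk.gamma * z_hat + blk.beta
                cache.update(z_hat=z_hat, inv_std=inv_std)
            else:
                u = z
            act, _ = ACTIVATIONS[blk.activation]
            a = act(u)
            cache["u"] = u
            cache["a_out"] = a
            a, mask = dropout_forward(a, blk.dropout, training, rng)
            cache["mask"] = mask
            caches.append(cache)
        raise AssertionError("unreachable")

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x, training=False)[0]

    # -- backward -----------------------------------------------------------

    def backward(
        self, caches: list[dict], y_onehot: np.ndarray
    ) -> list[list[np.ndarray]]:
        """Gradients of the penalized mean-NLL loss w.r.t. each block's params."""
        n = y_onehot.shape[0]
        grads: list[list[np.ndarray]] = [None] * len(self.blocks)
        head = self.blocks[-1]
        dz = (caches[-1]["probs"] - y_onehot) / n
        dW = dz.T @ caches[-1]["a_in"]
        dtheta = -dz.sum(axis=0)
        grads[-1] = [dW, dtheta]
        da = dz @ head.W
        for i in range(len(self.blocks) - 2, -1, -1):
            blk = self.blocks[i]
            cache = caches[i]
            if cache["mask"] is not None:
                da = da * cache["mask"]
            _, act_grad = ACTIVATIONS[blk.activation]
            du = da * act_grad(cache["u"], cache["a_out"])
            if blk.batch_norm:
                z_hat, inv_std = cache["z_hat"], cache["inv_std"]
                m = z_hat.shape[0]
                dgamma = (du * z_hat).sum(axis=0)
                dbeta = du.sum(axis=0)
                dzh = du * blk.gamma
                dz = (inv_std / m) * (
                    m * dzh - dzh.sum(axis=0) - z_hat * (dzh * z_hat).sum(axis=0)
                )
            else:
                dz = du
            dW = dz.T @ cache["a_in"] + blk.l1 * np.sign(blk.W) + 2.0 * blk.l2 * blk.W
            dtheta = -dz.sum(axis=0)
            grads[i] = [dW, dtheta] + ([dgamma, dbeta] if blk.batch_norm else [])
            da = dz @ blk.W
        return grads

    # -- (de)serialization --------------------------------------------------

    def get_state(self) -> list[dict[str, np.ndarray]]:
        state = []
        for blk in self.blocks:
            d = {"W": blk.W.copy(), "theta": blk.theta.copy()}
            if blk.batch_norm:
                d.update(
                    gamma=blk.gamma.copy(),
                    beta=blk.beta.copy(),
                    run_mean=blk.run_mean.copy(),
                    run_var=blk.run_var.copy(),
                )
            state.append(d)
        return state

    def set_state(self, state: list[dict[str, np.ndarray]]) -> None:
        for blk, d in zip(self.blocks, state):
            blk.W = d["W"].copy()
            blk.theta = d["theta"].copy()
            if blk.batch_norm:
                blk.gamma = d["gamma"].copy()
                blk.beta = d["beta"].copy()
                blk.run_mean = d["run_mean"].copy()
                blk.run_var = d["run_var"].copy()


def build_network(p: Individual, n_inputs: int, n_classes: int, seed: int) -> Network:
    return Network(p, n_inputs, n_classes, seed)


# ---------------------------------------------------------------------------
# optimizers
# ---------------------------------------------------------------------------


class _Optimizer:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.lr = lr
        self.state = [{} for _ in params]

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        raise NotImplementedError


class _SGD(_Optimizer):
    def __init__(self, params, lr, momentum=0.9):
        super().__init__(params, lr)
        self.momentum = momentum

    def step(self, params, grads):
        for p, g, st in zip(params, grads, self.state):
            v = st.get("v", 0.0)
            v = self.momentum * v - self.lr * g
            st["v"] = v
            p += v


class _RMSProp(_Optimizer):
    def step(self, params, grads):
        for p, g, st in zip(params, grads, self.state):
            s = st.get("s", np.zeros_like(p))
            s = 0.9 * s + 0.1 * g * g
            st["s"] = s
            p -= self.lr * g / (np.sqrt(s) + 1e-8)


class _Adam(_Optimizer):
    def step(self, params, grads):
        for p, g, st in zip(params, grads, self.state):
            t = st.get("t", 0) + 1
            m = 0.9 * st.get("m", np.zeros_like(p)) + 0.1 * g
            v = 0.999 * st.get("v", np.zeros_like(p)) + 0.001 * g * g
            st.update(t=t, m=m, v=v)
            m_hat = m / (1 - 0.9**t)
            v_hat = v / (1 - 0.999**t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + 1e-8)


def _make_optimizer(name: str, params: list[np.ndarray], lr: float, momentum: float) -> _Optimizer:
    if name == "sgd":
        return _SGD(params, lr, momentum=momentum)
    if name == "rmsprop":
        return _RMSProp(params, lr)
    if name == "adam":
        return _Adam(params, lr)
    raise ConfigError(f"unknown optimizer {name!r}")


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


@dataclass
class TrainedModel:
    """Trained network plus everything needed to predict on raw matrices."""

    individual: Individual
    network: Network
    class_names: list[str]
    gene_ids: list[str]
    feat_mean: np.ndarray
    feat_sd: np.ndarray
    history: dict[str, list[float]] = field(default_factory=dict)
    best_epoch: int = 0

    def _transform(self, expr: ExpressionMatrix) -> np.ndarray:
        missing = set(self.gene_ids) - set(expr.gene_ids)
        if missing:
            raise AlignmentError(f"missing genes: {sorted(missing)[:5]}")
        x = expr.subset_genes(self.gene_ids).values
        return (x - self.feat_mean) / self.feat_sd

    def predict(self, expr: ExpressionMatrix) -> tuple[np.ndarray, list[str]]:
        """Per-sample class probabilities and argmax labels (lowest index wins ties)."""
        probs = self.network.predict_proba(self._transform(expr))
        idx = probs.argmax(axis=1)  # argmax returns the first (lowest) max index
        return probs, [self.class_names[i] for i in idx]

    # -- serialization (architecture JSON + weight arrays) ------------------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "individual": self.individual.to_dict(),
            "class_names": self.class_names,
            "gene_ids": self.gene_ids,
            "feat_mean": self.feat_mean.tolist(),
            "feat_sd": self.feat_sd.tolist(),
            "best_epoch": self.best_epoch,
            "history": self.history,
        }
        with open(directory / "architecture.json", "w", encoding="utf-8") as fh:
            json.dump(meta, fh, indent=2)
        arrays = {}
        for i, d in enumerate(self.network.get_state()):
            for key, arr in d.items():
                arrays[f"b{i}_{key}"] = arr
        np.savez(directory / "weights.npz", **arrays)

    @classmethod
    def load(cls, directory: str | Path) -> "TrainedModel":
        directory = Path(directory)
        with open(directory / "architecture.json", encoding="utf-8") as fh:
            meta = json.load(fh)
        individual = Individual.from_dict(meta["individual"])
        net = Network(individual, len(meta["gene_ids"]), len(meta["class_names"]), seed=0)
        arrays = np.load(directory / "weights.npz")
        state = []
        for i in range(len(net.blocks)):
            d = {k[len(f"b{i}_") :]: arrays[k] for k in arrays.files if k.startswith(f"b{i}_")}
            state.append(d)
        net.set_state(state)
        return cls(
            individual=individual,
            network=net,
            class_names=list(meta["class_names"]),
            gene_ids=list(meta["gene_ids"]),
            feat_mean=np.asarray(meta["feat_mean"]),
            feat_sd=np.asarray(meta["feat_sd"]),
            history=meta.get("history", {}),
            best_epoch=int(meta.get("best_epoch", 0)),
        )


def _accuracy(net: Network, x: np.ndarray, y: np.ndarray) -> float:
    return float((net.predict_proba(x).argmax(axis=1) == y).mean())


def train_network(
    net: Network,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    p: Individual,
    patience: int = 50,
    seed: int = 0,
    batch_size: int = 32,
    momentum: float = 0.9,
    shuffle: bool = True,
) -> tuple[Network, dict[str, list[float]], int]:
    """Minimize the penalized loss for at most ``p.epochs`` epochs.

    Stops early when validation accuracy has not improved for ``patience``
    epochs; the returned network carries the best-validation-epoch weights.
    Raises TrainingDivergedError on non-finite loss.
    """
    if x_val.shape[0] == 0:
        raise ConfigError("validation split must be non-empty")
    rng = np.random.default_rng(seed)
    n = x_train.shape[0]
    onehot = np.eye(net.n_classes)[y_train]
    params = [q for blk in net.blocks for q in blk.params()]
    opt = _make_optimizer(p.optimizer, params, p.learning_rate, momentum)
    l1s = [blk.l1 for blk in net.blocks]
    l2s = [blk.l2 for blk in net.blocks]
    history: dict[str, list[float]] = {
        "train_loss": [], "train_acc": [], "val_loss": [], "val_acc": []
    }
    best_acc, best_epoch, best_state, stale = -np.inf, 0, net.get_state(), 0
    for epoch in range(p.epochs):
        order = rng.permutation(n) if shuffle else np.arange(n)
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            if len(idx) < 2 and any(blk.batch_norm for blk in net.blocks[:-1]):
                continue  # BN cannot normalize a singleton batch
            probs, caches = net.forward(x_train[idx], training=True, rng=rng)
            if not np.all(np.isfinite(probs)):
                raise TrainingDivergedError(f"non-finite activations at epoch {epoch}")
            grads = net.backward(caches, onehot[idx])
            flat = [g for gs in grads for g in gs]
            opt.step(params, flat)
        probs = net.predict_proba(x_train)
        train_loss = compute_loss(probs, onehot, [b.W for b in net.blocks], l1s, l2s)
        if not np.isfinite(train_loss):
            raise TrainingDivergedError(f"non-finite loss at epoch {epoch}")
        val_probs = net.predict_proba(x_val)
        val_onehot = np.eye(net.n_classes)[y_val]
        val_loss = compute_loss(val_probs, val_onehot, [b.W for b in net.blocks], l1s, l2s)
        val_acc = float((val_probs.argmax(axis=1) == y_val).mean())
        history["train_loss"].append(train_loss)
        history["train_acc"].append(_accuracy(net, x_train, y_train))
        history["val_loss"].append(val_loss)
        history["val_acc"].append(val_acc)
        if val_acc > best_acc:
            best_acc, best_epoch, best_state, stale = val_acc, epoch, net.get_state(), 0
        else:
            stale += 1
            if stale > patience:
                break
    net.set_state(best_state)
    return net, history, best_epoch


def fit_classifier(
    expr: ExpressionMatrix,
    labels: LabelTable,
    individual: Individual,
    val_expr: ExpressionMatrix | None = None,
    val_labels: LabelTable | None = None,
    patience: int = 50,
    seed: int = 0,
    batch_size: int = 32,
    val_fraction: float = 0.2,
) -> TrainedModel:
    """Standardize per gene on the training split, train, return a TrainedModel.

    When no explicit validation set is given, a stratified ``val_fraction``
    of the training samples is held out for early stopping.
    """
    aligned = labels.aligned_to(expr.sample_ids)
    y = aligned.encoded()
    x = expr.values
    if val_expr is None:
        rng = np.random.default_rng(seed)
        val_idx: list[int] = []
        for c in range(len(aligned.class_names)):
            members = np.flatnonzero(y == c)
            if len(members) == 0:
                continue
            n_val = max(1, int(round(val_fraction * len(members))))
            val_idx.extend(rng.permutation(members)[:n_val])
        val_mask = np.zeros(len(y), dtype=bool)
        val_mask[val_idx] = True
        x_tr, y_tr = x[~val_mask], y[~val_mask]
        x_va, y_va = x[val_mask], y[val_mask]
    else:
        v = val_labels.aligned_to(val_expr.sample_ids)
        x_tr, y_tr = x, y
        x_va = val_expr.subset_genes(expr.gene_ids).values
        y_va = np.array([aligned.class_names.index(l) for l in v.labels])
    mean = x_tr.mean(axis=0)
    sd = x_tr.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    net = build_network(individual, x.shape[1], len(aligned.class_names), seed=seed)
    net, history, best_epoch = train_network(
        net,
        (x_tr - mean) / sd,
        y_tr,
        (x_va - mean) / sd,
        y_va,
        individual,
        patience=patience,
        seed=seed,
        batch_size=batch_size,
    )
    return TrainedModel(
        individual=individual,
        network=net,
        class_names=list(aligned.class_names),
        gene_ids=list(expr.gene_ids),
        feat_mean=mean,
        feat_sd=sd,
        history=history,
        best_epoch=best_epoch,
    )
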