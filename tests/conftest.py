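import logging

import numpy as np
import pytest

from aconas.data_io import ExpressionMatrix, LabelTable
from aconas.search_space import HyperparameterPool, Individual, LayerSpec
from aconas.synthetic import SyntheticSpec, generate_classification_dataset

logging.getLogger("aconas").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def tiny_pool() -> HyperparameterPool:
    """64 enumerable configurations (2 choices in six slots, depth fixed at 1)."""
    return HyperparameterPool(
        epochs_choices=[50, 100],
        optimizer_choices=["sgd", "adam"],
        lr_choices=[1e-2, 1e-3],
        depth_choices=[1],
        width_choices=[30, 100],
        activation_choices=["relu", "tanh"],
        dropout_choices=[0.0, 0.2],
        bn_choices=[True],
        l1_choices=[0.0],
        l2_choices=[0.0],
    )


@pytest.fixture(scope="session")
def deep_pool() -> HyperparameterPool:
    """Small pool with variable depth up to 3 (padding / skip edges exercised)."""
    return HyperparameterPool(
        epochs_choices=[50],
        optimizer_choices=["sgd", "adam"],
        lr_choices=[1e-2],
        depth_choices=[1, 2, 3],
        width_choices=[8, 16],
        activation_choices=["relu", "tanh"],
        dropout_choices=[0.0, 0.5],
        bn_choices=[True, False],
        l1_choices=[0.0, 1e-3],
        l2_choices=[0.0, 1e-3],
    )


@pytest.fixture(scope="session")
def planted_dataset():
    """4 classes x 50, 1000 genes, 10 informative per class, effect 2, sd 1."""
    return generate_classification_dataset(SyntheticSpec(seed=11))


@pytest.fixture(scope="session")
def separable_dataset():
    """Strongly separable data (effect 3) for learner sanity checks."""
    return generate_classification_dataset(SyntheticSpec(effect_size=3.0, seed=5))


@pytest.fixture
def toy_expr() -> ExpressionMatrix:
    values = np.array([[5.0, 1.0], [5.0, 2.0], [3.0, 3.0], [3.0, 4.0]])
    return ExpressionMatrix(["s1", "s2", "s3", "s4"], ["g1", "g2"], values)


@pytest.fixture
def toy_labels() -> LabelTable:
    return LabelTable(["s1", "s2", "s3", "s4"], ["A", "A", "B", "B"], ["A", "B"])


@pytest.fixture
def simple_individual() -> Individual:
    return Individual(
        epochs=50,
        optimizer="adam",
        learning_rate=1e-2,
        layers=(LayerSpec(16, "tanh", 0.0, False, 0.0, 0.0),),
    )
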