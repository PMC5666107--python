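"""Shared fixtures and independent oracles.

The enumeration oracles here deliberately avoid the package's pruning and
reconstruction code paths: they compute tree likelihoods by brute-force
summation over all internal-node state assignments, with transition matrices
taken straight from scipy's expm.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy.linalg import expm

from odontree.ctmc import RateModel
from odontree.fixtures import loricarioid_fixture
from odontree.treeio import Chronogram


@pytest.fixture(scope="session")
def fixture_bundle():
    return loricarioid_fixture()


# ------------------------------------------------------------------ oracles
def enumeration_loglik(
    tree: Chronogram,
    tip_states: dict[str, int | None],
    model: RateModel,
    rate_multiplier: float = 1.0,
) -> float:
    """Brute-force likelihood: sum over all unobserved-node state combos."""
    nodes = list(tree.postorder())
    k = model.n_states
    q = model.generator()
    p = {
        id(n): expm(rate_multiplier * q * (n.parent.age - n.age))
        for n in nodes
        if n.parent is not None
    }
    free = [n for n in nodes if not n.is_tip or tip_states.get(n.label) is None]
    fixed = {
        id(n): tip_states[n.label]
        for n in nodes
        if n.is_tip and tip_states.get(n.label) is not None
    }
    root_w = model.root_weights()
    root = tree.root
    total = 0.0
    for combo in itertools.product(range(k), repeat=len(free)):
        assign = dict(fixed)
        for n, s in zip(free, combo):
            assign[id(n)] = s
        prob = root_w[assign[id(root)]]
        for n in nodes:
            if n.parent is not None:
                prob *= p[id(n)][assign[id(n.parent)], assign[id(n)]]
        total += prob
    return float(np.log(total))


def enumeration_posterior(
    tree: Chronogram,
    tip_states: dict[str, int | None],
    model: RateModel,
    node,
) -> np.ndarray:
    """Brute-force marginal posterior of one node's state."""
    k = model.n_states
    nodes = list(tree.postorder())
    q = model.generator()
    p = {
        id(n): expm(q * (n.parent.age - n.age))
        for n in nodes
        if n.parent is not None
    }
    free = [n for n in nodes if not n.is_tip or tip_states.get(n.label) is None]
    fixed = {
        id(n): tip_states[n.label]
        for n in nodes
        if n.is_tip and tip_states.get(n.label) is not None
    }
    root_w = model.root_weights()
    root = tree.root
    mass = np.zeros(k)
    for combo in itertools.product(range(k), repeat=len(free)):
        assign = dict(fixed)
        for n, s in zip(free, combo):
            assign[id(n)] = s
        prob = root_w[assign[id(root)]]
        for n in nodes:
            if n.parent is not None:
                prob *= p[id(n)][assign[id(n.parent)], assign[id(n)]]
        mass[assign[id(node)]] += prob
    return mass / mass.sum()


def random_rate_model(k: int, rng: np.random.Generator, root_rule="uniform") -> RateModel:
    """A fully parameterized random k-state model (one class per pair)."""
    pairs = [(i, j) for i in range(k) for j in range(k) if i != j]
    class_map = {p: c for c, p in enumerate(pairs)}
    values = rng.uniform(0.001, 0.05, size=len(pairs))
    return RateModel(
        labels=[str(i) for i in range(k)],
        class_map=class_map,
        values=values,
        root_rule=root_rule,
    )
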