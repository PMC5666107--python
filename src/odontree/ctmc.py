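"""Continuous-time Markov machinery for discrete characters on chronograms.

This is the shared engine behind both the ancestral-state reconstruction and
the site-rate classification stages: rate matrices defined by rate-equality
classes, discrete-gamma rate mixtures, matrix exponentials, and the pruning
(post-order partial likelihood) algorithm.

Rates are expressed per Myr because branch lengths are in Myr.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.linalg import expm
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .treeio import Chronogram, Node

__all__ = [
    "RateModel",
    "GammaMixture",
    "discretize_gamma",
    "transition_matrix",
    "transition_matrices",
    "prune_loglik",
    "TreeIndex",
]

ROOT_RULES = ("uniform", "stationary", "custom")


@dataclass
class RateModel:
    """A k-state generator defined by rate-equality classes.

    ``class_map`` assigns every ordered off-diagonal pair ``(i, j)`` either a
    rate-class id (contiguous from 0) or ``None`` for a structurally zero
    rate.  ``values`` holds one nonnegative rate (per Myr) per class.
    """

    labels: Sequence[str]
    class_map: Mapping[tuple[int, int], int | None]
    values: np.ndarray
    root_rule: str = "uniform"
    root_weights_custom: np.ndarray | None = None
    class_names: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k = self.n_states
        pairs = {(i, j) for i in range(k) for j in range(k) if i != j}
        if set(self.class_map) != pairs:
            raise ValueError("class_map must cover every ordered pair (i, j), i != j")
        ids = sorted({c for c in self.class_map.values() if c is not None})
        if ids != list(range(len(ids))):
            raise ValueError("class identifiers must be contiguous from 0")
        if len(self.values) != len(ids):
            raise ValueError(
                f"{len(ids)} rate classes but {len(self.values)} values supplied"
            )
        if np.any(self.values < 0):
            raise ValueError("rates must be nonnegative")
        if self.root_rule not in ROOT_RULES:
            raise ValueError(f"root_rule must be one of {ROOT_RULES}")
        if self.root_rule == "custom":
            w = np.asarray(self.root_weights_custom, dtype=float)
            if w.shape != (k,) or not np.isclose(w.sum(), 1.0):
                raise ValueError("custom root weights must be a length-k simplex vector")
            self.root_weights_custom = w

    @property
    def n_states(self) -> int:
        return len(self.labels)

    @property
    def n_classes(self) -> int:
        return len(self.values)

    def with_values(self, values: Iterable[float]) -> "RateModel":
        return replace(self, values=np.asarray(list(values), dtype=float))

    def generator(self) -> np.ndarray:
        """The generator matrix Q (rows sum to zero)."""
        k = self.n_states
        q = np.zeros((k, k))
        for (i, j), cls in self.class_map.items():
            if cls is not None:
                q[i, j] = self.values[cls]
        np.fill_diagonal(q, -q.sum(axis=1))
        return q

    def stationary(self) -> np.ndarray:
        """Stationary distribution of the chain (left null vector of Q)."""
        q = self.generator()
        k = self.n_states
        a = np.vstack([q.T, np.ones(k)])
        b = np.zeros(k + 1)
        b[-1] = 1.0
        pi, *_ = np.linalg.lstsq(a, b, rcond=None)
        pi = np.clip(pi, 0.0, None)
        total = pi.sum()
        if total <= 0:
            return np.full(k, 1.0 / k)
        return pi / total

    def root_weights(self) -> np.ndarray:
        if self.root_rule == "uniform":
            return np.full(self.n_states, 1.0 / self.n_states)
        if self.root_rule == "stationary":
            return self.stationary()
        return self.root_weights_custom

    # --------------------------------------------------------- serialization
    def to_text(self) -> str:
        """Plain-text model spec: state labels, class map, class values."""
        lines = ["states: " + " ".join(self.labels)]
        names = list(self.class_names or [f"class{c}" for c in range(self.n_classes)])
        for c in range(self.n_classes):
            pairs = sorted(p for p, cls in self.class_map.items() if cls == c)
            pair_txt = " ".join(f"{i}->{j}" for i, j in pairs)
            lines.append(f"class {names[c]} = {self.values[c]!r} : {pair_txt}")
        zero = sorted(p for p, cls in self.class_map.items() if cls is None)
        if zero:
            lines.append("zero: " + " ".join(f"{i}->{j}" for i, j in zero))
        lines.append(f"root_rule: {self.root_rule}")
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class GammaMixture:
    """Discretized gamma distribution of relative rates, equal-weight bins."""

    alpha: float
    rates: np.ndarray

    @property
    def n_categories(self) -> int:
        return len(self.rates)

    @property
    def weights(self) -> np.ndarray:
        k = self.n_categories
        return np.full(k, 1.0 / k)


def discretize_gamma(alpha: float, K: int) -> GammaMixture:
    """Mean-of-bin discretization of a mean-1 gamma into K equal-weight bins.

    The bins are delimited by the ``i/K`` quantiles of Gamma(alpha, 1/alpha);
    each category rate is the conditional mean of the distribution within its
    bin, so the mixture mean is exactly 1.
    """
    if alpha <= 0:
        raise ValueError("gamma shape alpha must be > 0")
    if K < 1:
        raise ValueError("category count K must be >= 1")
    if K == 1:
        return GammaMixture(alpha=alpha, rates=np.array([1.0]))
    # quantile boundaries of Gamma(shape=alpha, scale=1/alpha)
    edges = gamma_dist.ppf(np.arange(1, K) / K, a=alpha, scale=1.0 / alpha)
    edges = np.concatenate([[0.0], edges, [np.inf]])
    # integral of x f(x) over a bin equals mean * F_{alpha+1}(x) increments
    upper = np.where(np.isinf(edges[1:]), 1.0, gammainc(alpha + 1.0, edges[1:] * alpha))
    lower = gammainc(alpha + 1.0, edges[:-1] * alpha)
    rates = K * (upper - lower)
    rates /= rates.mean()  # exact mean-1 normalization
    if np.any(np.diff(rates) <= 0):
        raise RuntimeError("gamma category rates are not strictly increasing")
    return GammaMixture(alpha=alpha, rates=rates)


# ----------------------------------------------------------------- matrices
def transition_matrices(
    q: np.ndarray, times: np.ndarray, multiplier: float = 1.0
) -> np.ndarray:
    """P(t) = exp(multiplier * Q * t) for a batch of elapsed times.

    Uses one eigendecomposition for all times, falling back to
    scaling-and-squaring (scipy expm) per time when Q is defective or the
    reconstruction is numerically poor.
    """
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError("elapsed times must be nonnegative")
    if multiplier < 0:
        raise ValueError("rate multiplier must be nonnegative")
    k = q.shape[0]
    scaled = multiplier * q
    out = np.empty(times.shape + (k, k))
    try:
        w, v = np.linalg.eig(scaled)
        vinv = np.linalg.inv(v)
        ill = np.linalg.cond(v) > 1e10
    except np.linalg.LinAlgError:
        ill = True
    if not ill:
        ew = np.exp(np.multiply.outer(times, w))  # (..., k)
        out = np.einsum("ij,...j,jl->...il", v, ew, vinv)
        out = np.real_if_close(out, tol=1e6)
        if np.iscomplexobj(out):
            out = out.real
        resid = np.abs(out.sum(axis=-1) - 1.0).max()
        if resid > 1e-9 or out.min() < -1e-9:
            ill = True
    if ill:
        flat = times.reshape(-1)
        out = np.stack([expm(scaled * t) for t in flat]).reshape(times.shape + (k, k))
    out = np.clip(out, 0.0, None)
    out /= out.sum(axis=-1, keepdims=True)
    return out


def transition_matrix(
    model: RateModel, t: float, rate_multiplier: float = 1.0
) -> np.ndarray:
    """Stochastic matrix exp(rate_multiplier * Q * t) for one elapsed time."""
    return transition_matrices(model.generator(), np.array([t]), rate_multiplier)[0]


# ------------------------------------------------------------------ pruning
class TreeIndex:
    """Flat post-order arrays for a chronogram, reused across likelihood calls."""

    def __init__(self, tree: Chronogram):
        self.tree = tree
        self.nodes: list[Node] = list(tree.postorder())
        self.index = {id(n): i for i, n in enumerate(self.nodes)}
        self.parent = np.array(
            [self.index[id(n.parent)] if n.parent is not None else -1 for n in self.nodes]
        )
        self.children: list[list[int]] = [
            [self.index[id(c)] for c in n.children] for n in self.nodes
        ]
        self.branch_lengths = np.array(
            [n.parent.age - n.age if n.parent is not None else 0.0 for n in self.nodes]
        )
        self.is_tip = np.array([n.is_tip for n in self.nodes])
        self.tip_rows = {n.label: i for i, n in enumerate(self.nodes) if n.is_tip}
        self.root_index = self.index[id(tree.root)]

    def tip_partials(
        self, states: Mapping[str, int | None], k: int, n_sites: int = 1
    ) -> np.ndarray:
        """Initial partial-likelihood array, shape (n_nodes, n_sites, k)."""
        unknown = set(states) - set(self.tip_rows)
        if unknown:
            raise KeyError(
                f"taxa in character data but not in tree: {sorted(unknown)}"
            )
        partials = np.ones((len(self.nodes), n_sites, k))
        for label, row in self.tip_rows.items():
            s = states.get(label)
            if s is not None:
                vec = np.zeros(k)
                vec[s] = 1.0
                partials[row, :, :] = vec
        return partials


def _edge_matrices(idx: TreeIndex, q: np.ndarray, multiplier: float) -> np.ndarray:
    return transition_matrices(q, idx.branch_lengths, multiplier)


def prune_partials(
    idx: TreeIndex, partials: np.ndarray, p_edge: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Run the post-order recursion in place.

    Returns ``(partials, log_scale)`` where ``log_scale`` has shape
    ``(n_sites,)`` and accumulates per-site rescaling factors applied to keep
    the recursion in floating range.
    """
    n_sites = partials.shape[1]
    log_scale = np.zeros(n_sites)
    for i, kids in enumerate(idx.children):
        if not kids:
            continue
        acc = np.ones_like(partials[i])
        for c in kids:
            # P_c @ L_c summed over child states
            acc *= partials[c] @ p_edge[c].T
        norm = acc.max(axis=1)
        norm = np.where(norm > 0, norm, 1.0)
        acc /= norm[:, None]
        log_scale += np.log(norm)
        partials[i] = acc
    return partials, log_scale


def prune_loglik(
    tree: Chronogram | TreeIndex,
    tip_states: Mapping[str, int | None],
    model: RateModel,
    rate_multiplier: float = 1.0,
) -> float:
    """Log-probability of tip data under the model (Felsenstein pruning).

    ``tip_states`` maps tip labels to state indices (``None`` = missing; a
    missing tip contributes a vector of ones).  The root is weighted by the
    model's root rule.
    """
    idx = tree if isinstance(tree, TreeIndex) else TreeIndex(tree)
    k = model.n_states
    partials = idx.tip_partials(tip_states, k)
    p_edge = _edge_matrices(idx, model.generator(), rate_multiplier)
    partials, log_scale = prune_partials(idx, partials, p_edge)
    root = partials[idx.root_index, 0]
    lik = float(root @ model.root_weights())
    if lik <= 0:
        return -np.inf
    return float(np.log(lik) + log_scale[0])
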