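"""Synthetic-data generators mirroring the statistical structure of the
analysis: pure-birth chronograms, multi-gene alignments evolved under
GTR+Gamma with known per-site rate categories, and discrete characters
evolved under constrained Markov models.

All generators are deterministic under a fixed seed (numpy Generator,
PCG64).  Characters are sampled edge-wise from the exact transition matrix
(endpoint-conditioned path detail is never needed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .charmatrix import CharacterMatrix
from .ctmc import RateModel, TreeIndex, discretize_gamma, transition_matrices
from .satred import NUCLEOTIDES, Gene, GtrGammaParams, PartitionedAlignment
from .treeio import Chronogram, Node

__all__ = [
    "simulate_chronogram",
    "SimulatedSites",
    "simulate_sites",
    "simulate_multigene_alignment",
    "SimulatedCharacter",
    "simulate_discrete_character",
]


def simulate_chronogram(n_tips: int, root_age: float, seed: int) -> Chronogram:
    """Pure-birth (Yule) chronogram conditioned on ``n_tips``, root age exact.

    Split epochs are drawn from the Yule process (rate 1) until ``n_tips``
    lineages exist; node depths are then rescaled so the root sits exactly at
    ``root_age`` Ma and all tips at 0.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    if root_age <= 0:
        raise ValueError("root age must be positive")
    rng = np.random.default_rng(seed)
    root = Node(age=0.0)  # ages temporarily hold depths from the root
    active = [root.add_child(Node()), root.add_child(Node())]
    depth = 0.0
    while len(active) < n_tips:
        depth += rng.exponential(1.0 / len(active))
        lineage = active.pop(rng.integers(len(active)))
        lineage.age = depth
        active.append(lineage.add_child(Node()))
        active.append(lineage.add_child(Node()))
    total = depth + rng.exponential(1.0 / n_tips)
    for i, tip in enumerate(active):
        tip.age = total
        tip.label = f"t{i + 1}"
    # depths -> ages, root exactly at root_age
    for node in Chronogram(root, validate=False).preorder():
        node.age = root_age * (total - node.age) / total
    for tip in active:
        tip.age = 0.0
    return Chronogram(root)


# ------------------------------------------------------------------- sites
@dataclass
class SimulatedSites:
    alignment: PartitionedAlignment
    true_categories: np.ndarray  # 1..K per site
    params: GtrGammaParams
    seed: int


def _evolve_columns(
    idx: TreeIndex,
    q: np.ndarray,
    freqs: np.ndarray,
    scale: float,
    site_rates: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Simulate one nucleotide per (tip, site); site_rates is per-site."""
    n_sites = len(site_rates)
    n_nodes = len(idx.nodes)
    states = np.empty((n_nodes, n_sites), dtype=np.int64)
    order = list(reversed(range(n_nodes)))  # parents before children
    states[idx.root_index] = rng.choice(4, size=n_sites, p=freqs)
    unique_rates = np.unique(site_rates)
    for i in order:
        if i == idx.root_index:
            continue
        parent = idx.parent[i]
        t = idx.branch_lengths[i]
        for rate in unique_rates:
            mask = site_rates == rate
            p = transition_matrices(q, np.array([t]), scale * rate)[0]
            cum = np.cumsum(p, axis=1)
            u = rng.random(int(mask.sum()))
            parent_states = states[parent, mask]
            draw = (u[:, None] > cum[parent_states]).sum(axis=1)
            states[i, mask] = draw
    return states


def simulate_sites(
    tree: Chronogram,
    params: GtrGammaParams,
    n_sites: int,
    K: int = 10,
    seed: int = 0,
    gene_name: str = "rrna1",
    missing_fraction: float = 0.0,
) -> SimulatedSites:
    """Evolve columns under GTR+Gamma with uniformly drawn category labels.

    ``missing_fraction`` masks that fraction of (taxon, site) cells with '?'
    to emulate incomplete matrices; default off.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if not 0 <= missing_fraction < 1:
        raise ValueError("missing_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    idx = TreeIndex(tree)
    mix = discretize_gamma(params.alpha, K)
    cats = rng.integers(1, K + 1, size=n_sites)
    site_rates = mix.rates[cats - 1]
    states = _evolve_columns(
        idx, params.generator(), params.base_freqs, params.branch_scale,
        site_rates, rng,
    )
    rows = {
        node.label: "".join(NUCLEOTIDES[s] for s in states[i])
        for i, node in enumerate(idx.nodes)
        if node.is_tip
    }
    if missing_fraction > 0:
        for label in sorted(rows):
            mask = rng.random(n_sites) < missing_fraction
            rows[label] = "".join(
                "?" if m else b for m, b in zip(mask, rows[label])
            )
    aln = PartitionedAlignment(rows, [Gene(gene_name, "rrna", 0, n_sites)])
    return SimulatedSites(alignment=aln, true_categories=cats, params=params, seed=seed)


_STOP_FIX = {"TAA": "TAC", "TAG": "TAC", "TGA": "TGC"}


def simulate_multigene_alignment(
    tree: Chronogram,
    params: GtrGammaParams,
    n_coding: int = 6,
    n_rrna: int = 4,
    coding_len: int = 300,
    rrna_len: int = 200,
    K: int = 10,
    seed: int = 0,
) -> SimulatedSites:
    """A partitioned alignment with coding and rRNA genes for pipeline tests.

    Coding genes are simulated like any other columns and then stop codons
    are repaired by a deterministic third-position edit, so translation
    always succeeds; category labels are tracked for the rRNA genes only
    (the removal stages never touch coding columns).
    """
    if coding_len % 3:
        raise ValueError("coding_len must be a codon multiple")
    rng = np.random.default_rng(seed)
    genes: list[Gene] = []
    rows = {t: [] for t in tree.tip_labels}
    cats_rrna = []
    cursor = 0
    for g in range(n_coding):
        sub = simulate_sites(
            tree, params, coding_len, K=K,
            seed=int(rng.integers(2**31)), gene_name=f"cds{g + 1}",
        )
        for t in rows:
            seq = sub.alignment.sequences[t]
            fixed = "".join(
                _STOP_FIX.get(seq[i:i + 3], seq[i:i + 3])
                for i in range(0, len(seq), 3)
            )
            rows[t].append(fixed)
        genes.append(Gene(f"cds{g + 1}", "coding", cursor, cursor + coding_len))
        cursor += coding_len
    for g in range(n_rrna):
        sub = simulate_sites(
            tree, params, rrna_len, K=K,
            seed=int(rng.integers(2**31)), gene_name=f"rrna{g + 1}",
        )
        for t in rows:
            rows[t].append(sub.alignment.sequences[t])
        genes.append(Gene(f"rrna{g + 1}", "rrna", cursor, cursor + rrna_len))
        cursor += rrna_len
        cats_rrna.append(sub.true_categories)
    aln = PartitionedAlignment({t: "".join(parts) for t, parts in rows.items()}, genes)
    cats = np.concatenate(cats_rrna) if cats_rrna else np.array([], dtype=int)
    return SimulatedSites(alignment=aln, true_categories=cats, params=params, seed=seed)


# -------------------------------------------------------------- characters
@dataclass
class SimulatedCharacter:
    tips: CharacterMatrix
    node_states: dict[frozenset, int] = field(default_factory=dict)
    model: RateModel | None = None
    root_state: int = 0
    seed: int = 0


def simulate_discrete_character(
    tree: Chronogram,
    model: RateModel,
    root_rule: str | None = None,
    seed: int = 0,
    name: str = "trait",
) -> SimulatedCharacter:
    """Evolve one discrete character; root drawn per the (model's) root rule."""
    rng = np.random.default_rng(seed)
    idx = TreeIndex(tree)
    k = model.n_states
    if root_rule is not None:
        from dataclasses import replace

        model = replace(model, root_rule=root_rule)
    weights = model.root_weights()
    q = model.generator()
    p_edge = transition_matrices(q, idx.branch_lengths)
    states = np.empty(len(idx.nodes), dtype=np.int64)
    root_state = int(rng.choice(k, p=weights))
    states[idx.root_index] = root_state
    for i in reversed(range(len(idx.nodes))):
        if i == idx.root_index:
            continue
        parent_state = states[idx.parent[i]]
        states[i] = rng.choice(k, p=p_edge[i][parent_state])
    labels = list(model.labels)
    tips = CharacterMatrix(
        name=name,
        alphabet=labels,
        assignments={
            node.label: labels[states[i]]
            for i, node in enumerate(idx.nodes)
            if node.is_tip
        },
    )
    clades = tree.clade_tip_sets()
    node_states = {
        clades[node]: int(states[i]) for i, node in enumerate(idx.nodes)
    }
    return SimulatedCharacter(
        tips=tips, node_states=node_states, model=model,
        root_state=root_state, seed=seed,
    )
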