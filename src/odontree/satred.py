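"""Substitution-saturation reduction: the DS1->DS4 dataset series.

The series progressively strips saturated signal from a partitioned
multi-gene alignment:

DS1
    the untouched concatenated nucleotide alignment;
DS2
    protein-coding genes translated to amino acids (synonymous saturation
    removed), rRNA genes kept as nucleotides;
DS3
    DS2 with rRNA sites assigned to the fastest of K discrete gamma rate
    categories removed;
DS4
    DS2 with the two fastest categories removed.

Sites are assigned to categories by empirical Bayes under a GTR+Gamma model
fitted on a fixed tree: the posterior weight of category ``c`` at a site is
proportional to ``(1/K) * L_site(rate_c)`` and the assigned category is the
argmax (ties broken toward the slower category).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_id
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from .ctmc import TreeIndex, discretize_gamma, prune_partials, transition_matrices
from .treeio import Chronogram

__all__ = [
    "Gene",
    "PartitionedAlignment",
    "GtrGammaParams",
    "SiteRateAssignment",
    "DatasetSeries",
    "translate_cds",
    "GtrGammaSiteClassifier",
    "fit_gtr_gamma",
    "assign_site_categories",
    "remove_categories",
    "build_ds_series",
]

NUCLEOTIDES = "ACGT"

#: IUPAC nucleotide codes -> compatible-base indicator over ACGT
IUPAC = {
    "A": (1, 0, 0, 0), "C": (0, 1, 0, 0), "G": (0, 0, 1, 0), "T": (0, 0, 0, 1),
    "U": (0, 0, 0, 1),
    "R": (1, 0, 1, 0), "Y": (0, 1, 0, 1), "S": (0, 1, 1, 0), "W": (1, 0, 0, 1),
    "K": (0, 0, 1, 1), "M": (1, 1, 0, 0),
    "B": (0, 1, 1, 1), "D": (1, 0, 1, 1), "H": (1, 1, 0, 1), "V": (1, 1, 1, 0),
    "N": (1, 1, 1, 1), "-": (1, 1, 1, 1), "?": (1, 1, 1, 1), ".": (1, 1, 1, 1),
}

GENE_KINDS = ("coding", "rrna", "aa")


@dataclass(frozen=True)
class Gene:
    """One partition: a named column span with a data kind.

    ``start``/``end`` are 0-based, end-exclusive column indices into the
    concatenated alignment; ``frame`` is the reading-frame offset for coding
    partitions.
    """

    name: str
    kind: str
    start: int
    end: int
    frame: int = 0

    def __post_init__(self) -> None:
        if self.kind not in GENE_KINDS:
            raise ValueError(f"gene kind must be one of {GENE_KINDS}")
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad column span [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class PartitionedAlignment:
    """Equal-length sequence rows partitioned into genes."""

    sequences: dict[str, str]
    genes: list[Gene]

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError(f"rows have unequal lengths: {sorted(lengths)}")
        n = lengths.pop() if lengths else 0
        spans = sorted((g.start, g.end) for g in self.genes)
        cursor = 0
        for start, end in spans:
            if start != cursor:
                raise ValueError("gene spans must partition the alignment without overlap")
            cursor = end
        if self.genes and cursor != n:
            raise ValueError(
                f"gene spans cover {cursor} columns but alignment has {n}"
            )
        for g in self.genes:
            if g.kind == "coding" and (g.length - g.frame) % 3 != 0:
                raise ValueError(
                    f"coding gene {g.name!r}: length {g.length} minus frame "
                    f"{g.frame} is not divisible by 3"
                )

    @property
    def taxa(self) -> list[str]:
        return list(self.sequences)

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0

    def gene(self, name: str) -> Gene:
        for g in self.genes:
            if g.name == name:
                return g
        raise KeyError(f"no gene named {name!r}")

    def gene_rows(self, gene: Gene | str) -> dict[str, str]:
        g = gene if isinstance(gene, Gene) else self.gene(gene)
        return {t: s[g.start:g.end] for t, s in self.sequences.items()}

    def subset_genes(self, kinds: Iterable[str]) -> "PartitionedAlignment":
        kinds = set(kinds)
        keep = [g for g in self.genes if g.kind in kinds]
        rows = {t: "".join(s[g.start:g.end] for g in keep) for t, s in self.sequences.items()}
        genes, cursor = [], 0
        for g in keep:
            genes.append(replace(g, start=cursor, end=cursor + g.length))
            cursor += g.length
        return PartitionedAlignment(rows, genes)

    # -------------------------------------------------------------------- io
    def to_fasta(self, path: str) -> None:
        with open(path, "w") as fh:
            for taxon, seq in self.sequences.items():
                fh.write(f">{taxon}\n{seq}\n")

    def to_phylip(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(f" {len(self.sequences)} {self.n_columns}\n")
            for taxon, seq in self.sequences.items():
                fh.write(f"{taxon.replace(' ', '_')}  {seq}\n")

    def to_nexus(self, path: str) -> None:
        """Mixed-datatype NEXUS (MrBayes dialect) with a SETS block."""
        aa = [g for g in self.genes if g.kind == "aa"]
        nuc = [g for g in self.genes if g.kind != "aa"]
        if aa and nuc:
            # mixed blocks must be contiguous per datatype
            ranges = []
            for kind, gs in (("PROTEIN", aa), ("DNA", nuc)):
                lo = min(g.start for g in gs) + 1
                hi = max(g.end for g in gs)
                ranges.append(f"{kind}:{lo}-{hi}")
            datatype = "MIXED(" + ",".join(ranges) + ")"
        elif aa:
            datatype = "PROTEIN"
        else:
            datatype = "DNA"
        lines = [
            "#NEXUS",
            "BEGIN DATA;",
            f"  DIMENSIONS NTAX={len(self.sequences)} NCHAR={self.n_columns};",
            f"  FORMAT DATATYPE={datatype} GAP=- MISSING=?;",
            "  MATRIX",
        ]
        for taxon, seq in self.sequences.items():
            lines.append(f"    {taxon.replace(' ', '_')}  {seq}")
        lines += ["  ;", "END;", "", "BEGIN SETS;"]
        for g in self.genes:
            lines.append(f"  CHARSET {g.name} = {g.start + 1}-{g.end};")
        lines += ["END;", ""]
        with open(path, "w") as fh:
            fh.write("\n".join(lines))

    def partitions_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"gene": g.name, "kind": g.kind, "start": g.start + 1,
                 "end": g.end, "frame": g.frame}
                for g in self.genes
            ]
        )

    @classmethod
    def from_fasta(cls, path: str, genes: list[Gene]) -> "PartitionedAlignment":
        from Bio import SeqIO

        rows = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}
        if not rows:
            raise ValueError(f"no sequences parsed from {path!r}")
        return cls(rows, genes)

    @classmethod
    def from_phylip(cls, path: str, genes: list[Gene]) -> "PartitionedAlignment":
        with open(path) as fh:
            header = fh.readline().split()
            ntax, ncols = int(header[0]), int(header[1])
            rows: dict[str, str] = {}
            for line in fh:
                if not line.strip():
                    continue
                name, seq = line.split(None, 1)
                rows[name] = seq.replace(" ", "").strip().upper()
        if len(rows) != ntax:
            raise ValueError(f"expected {ntax} rows, parsed {len(rows)}")
        return cls(rows, genes)


def read_partitions(path: str) -> list[Gene]:
    """Read a TSV with columns gene, kind, start (1-based), end, frame."""
    df = pd.read_csv(path, sep="\t")
    return [
        Gene(r.gene, r.kind, int(r.start) - 1, int(r.end),
             int(getattr(r, "frame", 0) or 0))
        for r in df.itertuples()
    ]


# -------------------------------------------------------------- translation
_STANDARD = unambiguous_dna_by_id[1]


def _codon_amino_acids(codon: str, table) -> set[str]:
    """All amino acids (or '*') reachable by resolving IUPAC ambiguity."""
    options = []
    for base in codon:
        hits = IUPAC.get(base)
        if hits is None:
            raise ValueError(f"unknown nucleotide symbol {base!r}")
        options.append([NUCLEOTIDES[i] for i, h in enumerate(hits) if h])
    out: set[str] = set()
    for a in options[0]:
        for b in options[1]:
            for c in options[2]:
                cod = a + b + c
                out.add("*" if cod in table.stop_codons else table.forward_table[cod])
    return out


def translate_cds(
    rows: Mapping[str, str], code: int = 1, frame: int = 0
) -> dict[str, str]:
    """Translate aligned coding nucleotide rows to aligned amino acids.

    Codons that are entirely gaps translate to '-'; codons containing gaps or
    ambiguity codes that do not resolve to a unique amino acid translate to
    'X'.  A codon that unambiguously encodes a stop raises, naming the taxon
    and the codon index.
    """
    table = unambiguous_dna_by_id[code]
    out: dict[str, str] = {}
    for taxon, seq in rows.items():
        seq = seq.upper()[frame:]
        if len(seq) % 3 != 0:
            raise ValueError(
                f"taxon {taxon!r}: coding sequence length {len(seq)} "
                "is not divisible by 3"
            )
        aas = []
        for i in range(0, len(seq), 3):
            codon = seq[i:i + 3]
            if all(b in "-?." for b in codon):
                aas.append("-")
                continue
            if any(b in "-?." for b in codon):
                aas.append("X")
                continue
            hits = _codon_amino_acids(codon, table)
            if hits == {"*"}:
                raise ValueError(
                    f"stop codon {codon} in taxon {taxon!r} at codon index {i // 3}"
                )
            if len(hits) == 1:
                aas.append(next(iter(hits)))
            else:
                aas.append("X")
        out[taxon] = "".join(aas)
    return out


# ------------------------------------------------------------------ GTR+G
@dataclass
class GtrGammaParams:
    """GTR exchangeabilities + base frequencies + gamma shape + branch scale.

    ``exchangeabilities`` are ordered (AC, AG, AT, CG, CT, GT) with GT fixed
    to 1; ``branch_scale`` converts Myr branch lengths to expected
    substitutions per site at relative rate 1.
    """

    exchangeabilities: np.ndarray
    base_freqs: np.ndarray
    alpha: float
    branch_scale: float
    log_likelihood: float | None = None

    def __post_init__(self) -> None:
        self.exchangeabilities = np.asarray(self.exchangeabilities, dtype=float)
        self.base_freqs = np.asarray(self.base_freqs, dtype=float)
        if self.exchangeabilities.shape != (6,) or np.any(self.exchangeabilities <= 0):
            raise ValueError("need 6 positive exchangeabilities (AC,AG,AT,CG,CT,GT)")
        if self.base_freqs.shape != (4,) or np.any(self.base_freqs <= 0):
            raise ValueError("need 4 positive base frequencies")
        if not np.isclose(self.base_freqs.sum(), 1.0, atol=1e-12):
            raise ValueError("base frequencies must sum to 1")
        if self.alpha <= 0:
            raise ValueError("gamma shape alpha must be > 0")
        if self.branch_scale < 0:
            raise ValueError("branch scale must be >= 0")

    def generator(self) -> np.ndarray:
        """GTR generator normalized to one expected substitution per unit time."""
        s = np.zeros((4, 4))
        pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        for (i, j), x in zip(pairs, self.exchangeabilities):
            s[i, j] = s[j, i] = x
        q = s * self.base_freqs[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -(self.base_freqs * np.diag(q)).sum()
        return q / mu


@dataclass
class SiteRateAssignment:
    """Per-site posterior over K gamma categories plus the argmax category."""

    posterior: np.ndarray        # (n_sites, K)
    categories: np.ndarray       # (n_sites,), values 1..K (1 slowest)
    columns: np.ndarray          # global column indices into the source alignment
    genes: np.ndarray            # gene name per site
    K: int

    def __post_init__(self) -> None:
        assert self.posterior.shape == (len(self.columns), self.K)


def _column_tensor(rows: Mapping[str, str], taxa: Sequence[str]) -> np.ndarray:
    """(n_taxa, n_sites, 4) partial-likelihood leaves from IUPAC symbols."""
    n_sites = len(next(iter(rows.values())))
    out = np.empty((len(taxa), n_sites, 4))
    lut = {sym: np.array(vec, dtype=float) for sym, vec in IUPAC.items()}
    for ti, taxon in enumerate(taxa):
        seq = rows[taxon].upper()
        for si, base in enumerate(seq):
            try:
                out[ti, si] = lut[base]
            except KeyError:
                raise ValueError(
                    f"unknown nucleotide symbol {base!r} in taxon {taxon!r}"
                ) from None
    return out


class GtrGammaSiteClassifier(BaseEstimator):
    """Fit GTR+Gamma on a fixed chronogram and classify sites by rate.

    The topology and relative branch lengths come from the chronogram; a
    global substitution-rate scale (per Myr) is fitted together with the
    exchangeabilities and the gamma shape.  Base frequencies are empirical.

    After :meth:`fit`, ``params_`` holds the :class:`GtrGammaParams` and
    ``log_likelihood_`` the maximized log-likelihood; :meth:`predict_proba`
    gives per-site category posteriors and :meth:`predict` the assigned
    categories (1..K, ties toward the slower category).
    """

    def __init__(self, K: int = 10, n_starts: int = 3, seed: int = 0):
        self.K = K
        self.n_starts = n_starts
        self.seed = seed

    # ----------------------------------------------------------- internals
    def _site_logliks_per_category(
        self, idx: TreeIndex, leaves: np.ndarray, params: GtrGammaParams
    ) -> np.ndarray:
        """(n_sites, K) per-category site log-likelihoods."""
        mix = discretize_gamma(params.alpha, self.K)
        q = params.generator()
        n_sites = leaves.shape[1]
        out = np.empty((n_sites, self.K))
        tip_rows = idx.tip_rows
        for c, rate in enumerate(mix.rates):
            partials = np.ones((len(idx.nodes), n_sites, 4))
            for label, row in tip_rows.items():
                partials[row] = leaves[self._taxon_pos[label]]
            p_edge = transition_matrices(
                q, idx.branch_lengths, params.branch_scale * rate
            )
            partials, log_scale = prune_partials(idx, partials, p_edge)
            root = partials[idx.root_index] @ params.base_freqs
            out[:, c] = np.log(np.clip(root, 1e-300, None)) + log_scale
        return out

    def _loglik(self, idx, leaves, weights, params) -> float:
        per_cat = self._site_logliks_per_category(idx, leaves, params)
        m = per_cat.max(axis=1)
        mixed = m + np.log(np.exp(per_cat - m[:, None]).mean(axis=1))
        return float(mixed @ weights)

    # ----------------------------------------------------------------- fit
    def fit(
        self,
        alignment: PartitionedAlignment | Mapping[str, str],
        tree: Chronogram | TreeIndex,
    ) -> "GtrGammaSiteClassifier":
        if self.K < 2:
            raise ValueError("K must be >= 2 for site-rate classification")
        rows = (
            alignment.sequences
            if isinstance(alignment, PartitionedAlignment)
            else dict(alignment)
        )
        idx = tree if isinstance(tree, TreeIndex) else TreeIndex(tree)
        shared = [t for t in idx.tip_rows if t in rows]
        if len(shared) < 4:
            raise ValueError("need at least 4 taxa shared between tree and alignment")
        if len({rows[t] for t in shared}) < 2:
            raise ValueError("fewer than 2 distinct sequences; nothing to fit")
        rows = {t: rows[t] for t in shared}
        self._taxon_pos = {t: i for i, t in enumerate(shared)}
        leaves = _column_tensor(rows, shared)

        # drop all-gap columns (uninformative and degenerate)
        informative = ~np.all(leaves.sum(axis=2) == 4.0, axis=0)
        if not informative.all():
            warnings.warn(
                f"dropping {int((~informative).sum())} all-gap columns before fitting"
            )
        fit_leaves = leaves[:, informative, :]

        # empirical base frequencies from unambiguous symbols
        counts = np.zeros(4)
        for seq in rows.values():
            for base in seq:
                vec = IUPAC.get(base.upper(), (1, 1, 1, 1))
                if sum(vec) == 1:
                    counts[np.argmax(vec)] += 1
        freqs = (counts + 1.0) / (counts + 1.0).sum()

        # pattern compression
        codes = np.array(
            [[IUPAC_INDEX.setdefault(sym, len(IUPAC_INDEX)) for sym in rows[t].upper()]
             for t in shared]
        )
        codes = codes[:, informative]
        _, first, inverse, counts_u = np.unique(
            codes, axis=1, return_index=True, return_inverse=True, return_counts=True
        )
        patt_leaves = fit_leaves[:, first, :]
        weights = counts_u.astype(float)

        def make_params(x: np.ndarray) -> GtrGammaParams:
            ex = np.concatenate([np.exp(x[:5]), [1.0]])
            return GtrGammaParams(
                exchangeabilities=ex,
                base_freqs=freqs,
                alpha=float(np.exp(x[5])),
                branch_scale=float(np.exp(x[6])),
            )

        def neg(x: np.ndarray) -> float:
            try:
                ll = self._loglik(idx, patt_leaves, weights, make_params(x))
            except (ValueError, FloatingPointError):
                return 1e12
            return 1e12 if not np.isfinite(ll) else -ll

        rng = np.random.default_rng(self.seed)
        scale_guesses = np.array([1e-3, 1e-2, 1e-1])
        best = None
        bounds = [(-5, 5)] * 5 + [(np.log(0.02), np.log(50.0)), (np.log(1e-6), np.log(1.0))]
        for s in range(self.n_starts):
            x0 = np.zeros(7)
            x0[5] = np.log(0.5)
            x0[6] = np.log(scale_guesses[s % len(scale_guesses)])
            if s >= len(scale_guesses):
                x0[:5] = rng.normal(0, 0.3, 5)
                x0[5] += rng.normal(0, 0.5)
            res = minimize(neg, x0, method="L-BFGS-B", bounds=bounds)
            if best is None or res.fun < best.fun:
                best = res
        params = make_params(best.x)
        params.log_likelihood = -float(best.fun)
        self.params_ = params
        self.log_likelihood_ = params.log_likelihood
        self.tree_index_ = idx
        self.taxa_ = shared
        return self

    # ------------------------------------------------------------- predict
    def _posteriors(
        self, rows: Mapping[str, str], params: GtrGammaParams | None = None
    ) -> np.ndarray:
        params = params or self.params_
        rows = {t: rows[t] for t in self.taxa_}
        leaves = _column_tensor(rows, self.taxa_)
        per_cat = self._site_logliks_per_category(self.tree_index_, leaves, params)
        m = per_cat.max(axis=1, keepdims=True)
        w = np.exp(per_cat - m)          # equal 1/K prior cancels in the ratio
        return w / w.sum(axis=1, keepdims=True)

    def predict_proba(self, alignment) -> np.ndarray:
        rows = (
            alignment.sequences
            if isinstance(alignment, PartitionedAlignment)
            else dict(alignment)
        )
        return self._posteriors(rows)

    def predict(self, alignment) -> np.ndarray:
        post = self.predict_proba(alignment)
        return np.argmax(post, axis=1) + 1  # argmax takes the first (slower) on ties


IUPAC_INDEX: dict[str, int] = {}


def substitution_tree_index(newick: str) -> TreeIndex:
    """A :class:`TreeIndex` for a rooted newick whose branch lengths are in
    substitutions per site (not time).

    The site classifier normally derives branch lengths from a chronogram
    and fits a global per-Myr scale; this helper lets a caller supply
    substitution branch lengths directly instead (the fitted scale then
    plays the role of an overall multiplier near 1).
    """
    import dendropy

    from .treeio import Chronogram, _dendropy_to_nodes

    dtree = dendropy.Tree.get(data=newick, schema="newick",
                              suppress_internal_node_taxa=True,
                              rooting="force-rooted")
    root = _dendropy_to_nodes(dtree)  # node.age temporarily holds edge length
    skeleton = Chronogram(root, validate=False)
    # convert edge lengths to pseudo-ages (= minus depth) so that
    # parent.age - node.age reproduces the edge length exactly
    lengths = {id(n): n.age for n in skeleton.postorder()}
    root.age = 0.0
    for node in skeleton.preorder():
        if node.parent is not None:
            node.age = node.parent.age - lengths[id(node)]
    return TreeIndex(skeleton)


# --------------------------------------------------------------- operations
def fit_gtr_gamma(
    alignment: PartitionedAlignment | Mapping[str, str],
    tree: Chronogram,
    K: int = 10,
    seed: int = 0,
) -> GtrGammaParams:
    """ML GTR+Gamma parameters on the fixed chronogram topology."""
    clf = GtrGammaSiteClassifier(K=K, seed=seed)
    clf.fit(alignment, tree)
    return clf.params_


def assign_site_categories(
    alignment: PartitionedAlignment,
    tree: Chronogram,
    params: GtrGammaParams | None = None,
    K: int = 10,
    kinds: tuple[str, ...] = ("rrna",),
    per_gene: bool = True,
    seed: int = 0,
) -> SiteRateAssignment:
    """Empirical-Bayes gamma-category assignment for sites of the given kinds.

    With ``per_gene=True`` (default) parameters are fitted separately per
    gene; a supplied ``params`` forces joint classification under those
    parameters instead.
    """
    target_genes = [g for g in alignment.genes if g.kind in kinds]
    if not target_genes:
        raise ValueError(f"alignment has no genes of kinds {kinds}")
    posts, cats, cols, gene_names = [], [], [], []
    if params is not None or not per_gene:
        groups = [target_genes]
    else:
        groups = [[g] for g in target_genes]
    for group in groups:
        rows = {
            t: "".join(alignment.sequences[t][g.start:g.end] for g in group)
            for t in alignment.taxa
        }
        clf = GtrGammaSiteClassifier(K=K, seed=seed)
        if params is not None:
            # classification only, at the supplied parameters
            idx = tree if isinstance(tree, TreeIndex) else TreeIndex(tree)
            shared = [t for t in idx.tip_rows if t in rows]
            clf.taxa_ = shared
            clf.tree_index_ = idx
            clf._taxon_pos = {t: i for i, t in enumerate(shared)}
            clf.params_ = params
        else:
            clf.fit(rows, tree)
        post = clf._posteriors(rows)
        posts.append(post)
        cats.append(np.argmax(post, axis=1) + 1)
        for g in group:
            cols.extend(range(g.start, g.end))
            gene_names.extend([g.name] * g.length)
    return SiteRateAssignment(
        posterior=np.vstack(posts),
        categories=np.concatenate(cats),
        columns=np.array(cols),
        genes=np.array(gene_names),
        K=K,
    )


def remove_categories(
    alignment: PartitionedAlignment,
    assignment: SiteRateAssignment,
    drop: set[int],
    restrict_to: tuple[str, ...] = ("rrna",),
) -> tuple[PartitionedAlignment, float]:
    """Delete columns of the restricted partitions whose category is in ``drop``.

    Returns the reduced alignment and the removal fraction (removed /
    original column count of the restricted partitions).
    """
    bad = {c for c in drop if not 1 <= c <= assignment.K}
    if bad:
        raise ValueError(f"drop categories outside 1..{assignment.K}: {sorted(bad)}")
    col_cat = dict(zip(assignment.columns.tolist(), assignment.categories.tolist()))
    remove = {
        col for col, cat in col_cat.items() if cat in drop
    }
    restricted_cols = sum(g.length for g in alignment.genes if g.kind in restrict_to)
    keep_mask = np.ones(alignment.n_columns, dtype=bool)
    for g in alignment.genes:
        if g.kind in restrict_to:
            for col in range(g.start, g.end):
                if col in remove:
                    keep_mask[col] = False
    new_rows = {
        t: "".join(np.array(list(s))[keep_mask]) for t, s in alignment.sequences.items()
    }
    genes, cursor = [], 0
    for g in alignment.genes:
        kept = int(keep_mask[g.start:g.end].sum())
        genes.append(replace(g, start=cursor, end=cursor + kept))
        cursor += kept
    reduced = PartitionedAlignment(new_rows, genes)
    fraction = (len(remove) / restricted_cols) if restricted_cols else 0.0
    return reduced, fraction


@dataclass
class DatasetSeries:
    """The DS1..DS4 artifacts plus the bookkeeping needed to audit them."""

    ds1: PartitionedAlignment
    ds2: PartitionedAlignment
    ds3: PartitionedAlignment
    ds4: PartitionedAlignment
    assignment: SiteRateAssignment
    manifest: pd.DataFrame
    removal_fractions: dict[str, float] = field(default_factory=dict)


def _translate_alignment(alignment: PartitionedAlignment) -> PartitionedAlignment:
    """DS2 construction: coding genes -> amino acids, rRNA untouched."""
    rows = {t: [] for t in alignment.taxa}
    genes, cursor = [], 0
    for g in alignment.genes:
        sub = alignment.gene_rows(g)
        if g.kind == "coding":
            sub = translate_cds(sub, frame=g.frame)
            kind, length = "aa", (g.length - g.frame) // 3
        else:
            kind, length = g.kind, g.length
        for t in rows:
            rows[t].append(sub[t])
        genes.append(Gene(g.name, kind, cursor, cursor + length))
        cursor += length
    return PartitionedAlignment({t: "".join(parts) for t, parts in rows.items()}, genes)


def build_ds_series(
    alignment: PartitionedAlignment,
    tree: Chronogram,
    K: int = 10,
    params: GtrGammaParams | None = None,
    per_gene: bool = True,
    seed: int = 0,
) -> DatasetSeries:
    """Run the full noise-reduction series on a partitioned alignment.

    Category assignment is computed once on the rRNA partitions of the
    original nucleotide alignment; DS3/DS4 remove the fastest one / two
    categories from the rRNA columns of DS2.
    """
    assignment = assign_site_categories(
        alignment, tree, params=params, K=K, per_gene=per_gene, seed=seed
    )
    ds2 = _translate_alignment(alignment)

    # map rRNA columns of the original alignment into DS2 coordinates
    orig_to_ds2: dict[int, int] = {}
    for g_old in alignment.genes:
        if g_old.kind == "rrna":
            g_new = ds2.gene(g_old.name)
            for off in range(g_old.length):
                orig_to_ds2[g_old.start + off] = g_new.start + off

    assignment_ds2 = SiteRateAssignment(
        posterior=assignment.posterior,
        categories=assignment.categories,
        columns=np.array([orig_to_ds2[c] for c in assignment.columns]),
        genes=assignment.genes,
        K=K,
    )
    ds3, frac3 = remove_categories(ds2, assignment_ds2, {K})
    ds4, frac4 = remove_categories(ds2, assignment_ds2, {K - 1, K})

    manifest = pd.DataFrame(
        {
            "column_ds2": assignment_ds2.columns,
            "column_ds1": assignment.columns,
            "gene": assignment.genes,
            "category": assignment.categories,
            "dropped_in_ds3": assignment.categories == K,
            "dropped_in_ds4": assignment.categories >= K - 1,
        }
    ).sort_values("column_ds2").reset_index(drop=True)
    return DatasetSeries(
        ds1=alignment,
        ds2=ds2,
        ds3=ds3,
        ds4=ds4,
        assignment=assignment_ds2,
        manifest=manifest,
        removal_fractions={"ds3": frac3, "ds4": frac4},
    )
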