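"""Time-calibrated trees (chronograms): reading, writing, building, collapsing.

A chronogram is a rooted ultrametric tree whose primary node attribute is an
absolute age in Ma (million years before present).  Tips sit at age 0 and the
branch subtending a node has length ``parent.age - node.age`` in Myr.  Ages,
not branch lengths, are the stored representation; branch lengths are derived
on demand.  Polytomies are allowed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import dendropy

__all__ = [
    "ChronogramError",
    "Node",
    "Chronogram",
    "CladeAge",
    "CladeAgeTable",
    "read_newick",
    "build_chronogram",
    "collapse_to_representatives",
]

#: relative tolerance for ultrametricity checks (fraction of root age)
ULTRAMETRIC_RTOL = 1e-9


class ChronogramError(ValueError):
    """Raised for malformed, non-ultrametric or inconsistent tree input."""


class Node:
    """A tree node with an absolute age in Ma."""

    __slots__ = ("label", "age", "parent", "children")

    def __init__(self, label: str | None = None, age: float = 0.0):
        self.label = label
        self.age = float(age)
        self.parent: Node | None = None
        self.children: list[Node] = []

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_tip(self) -> bool:
        return not self.children

    @property
    def branch_length(self) -> float | None:
        """Length in Myr of the branch above this node (None at the root)."""
        if self.parent is None:
            return None
        return self.parent.age - self.age

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "tip" if self.is_tip else f"internal[{len(self.children)}]"
        return f"<Node {self.label!r} {kind} age={self.age:.4g}>"


class Chronogram:
    """Rooted ultrametric tree with node ages in Ma."""

    def __init__(self, root: Node, validate: bool = True):
        self.root = root
        if validate:
            self.validate()

    # ---------------------------------------------------------------- walks
    def postorder(self) -> Iterator[Node]:
        stack: list[tuple[Node, bool]] = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded or node.is_tip:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def tips(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_tip]

    @property
    def tip_labels(self) -> list[str]:
        return [t.label for t in self.tips()]

    @property
    def root_age(self) -> float:
        return self.root.age

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.postorder() if not n.is_tip]

    # ------------------------------------------------------------- queries
    def find_tip(self, label: str) -> Node:
        for tip in self.tips():
            if tip.label == label:
                return tip
        raise KeyError(f"no tip labelled {label!r}")

    def mrca(self, labels: Sequence[str]) -> Node:
        """Most recent common ancestor of the given tip labels."""
        labels = set(labels)
        missing = labels - set(self.tip_labels)
        if missing:
            raise KeyError(f"tips not in tree: {sorted(missing)}")
        if len(labels) == 1:
            return self.find_tip(next(iter(labels)))
        # smallest clade containing all labels
        clade_sets = self.clade_tip_sets()
        best = self.root
        for node, tipset in clade_sets.items():
            if labels <= tipset and len(tipset) < len(clade_sets[best]):
                best = node
        return best

    def clade_tip_sets(self) -> dict[Node, frozenset[str]]:
        """Map every node to the frozenset of tip labels below it."""
        out: dict[Node, frozenset[str]] = {}
        for node in self.postorder():
            if node.is_tip:
                out[node] = frozenset([node.label])
            else:
                acc: set[str] = set()
                for child in node.children:
                    acc |= out[child]
                out[node] = frozenset(acc)
        return out

    # ---------------------------------------------------------- validation
    def validate(self) -> None:
        seen: set[str] = set()
        for tip in self.tips():
            if tip.label is None:
                raise ChronogramError("unlabelled tip")
            if tip.label in seen:
                raise ChronogramError(f"duplicate tip label {tip.label!r}")
            seen.add(tip.label)
        tol = max(self.root_age, 1.0) * ULTRAMETRIC_RTOL
        for node in self.postorder():
            if node.age < -tol:
                raise ChronogramError(f"negative age at {node.label!r}")
            if node.is_tip and abs(node.age) > tol:
                raise ChronogramError(
                    f"tip {node.label!r} has nonzero age {node.age!r}: "
                    "tree is not ultrametric"
                )
            for child in node.children:
                if child.age >= node.age:
                    raise ChronogramError(
                        f"zero or negative branch above {child.label or 'internal node'!r}: "
                        f"child age {child.age} >= parent age {node.age}"
                    )

    def copy(self) -> "Chronogram":
        def clone(node: Node) -> Node:
            new = Node(node.label, node.age)
            for child in node.children:
                new.add_child(clone(child))
            return new

        return Chronogram(clone(self.root), validate=False)

    # ------------------------------------------------------------------ io
    def to_newick(self, decimals: int = 6) -> str:
        def fmt(node: Node) -> str:
            if node.is_tip:
                core = node.label or ""
            else:
                inner = ",".join(fmt(c) for c in node.children)
                core = f"({inner})" + (node.label or "")
            if node.parent is None:
                return f"{core}:0.000000"
            return f"{core}:{node.parent.age - node.age:.{decimals}f}"

        return fmt(self.root) + ";"

    def write(self, path: str, decimals: int = 6) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick(decimals=decimals) + "\n")

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Chronogram {len(self.tips())} tips, root age {self.root_age:.4g} Ma>"


# ---------------------------------------------------------------- clade ages
@dataclass(frozen=True)
class CladeAge:
    """Age of the MRCA of a set of tips.

    ``source`` records the provenance of the age value so reports can flag
    entries that do not come from the primary analysis (e.g. values taken
    from supplementary material, or placeholders).
    """

    tips: frozenset[str]
    age_ma: float
    source: str = "primary"


@dataclass
class CladeAgeTable:
    entries: list[CladeAge] = field(default_factory=list)

    def add(self, tips: Sequence[str], age_ma: float, source: str = "primary") -> None:
        self.entries.append(CladeAge(frozenset(tips), float(age_ma), source))

    def to_csv(self, path_or_buf) -> None:
        close = False
        if isinstance(path_or_buf, str):
            path_or_buf = open(path_or_buf, "w", newline="")
            close = True
        try:
            writer = csv.writer(path_or_buf)
            writer.writerow(["clade_tips", "age_ma", "source"])
            for entry in self.entries:
                writer.writerow([";".join(sorted(entry.tips)), repr(entry.age_ma), entry.source])
        finally:
            if close:
                path_or_buf.close()

    @classmethod
    def from_csv(cls, path_or_buf) -> "CladeAgeTable":
        if isinstance(path_or_buf, str):
            with open(path_or_buf, newline="") as fh:
                return cls.from_csv(fh)
        reader = csv.DictReader(path_or_buf)
        table = cls()
        for row in reader:
            table.add(
                row["clade_tips"].split(";"),
                float(row["age_ma"]),
                row.get("source", "primary") or "primary",
            )
        return table


# ------------------------------------------------------------------- readers
def _dendropy_to_nodes(dtree: dendropy.Tree) -> Node:
    def convert(dnode) -> Node:
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label:
            label = dnode.label
        node = Node(label=label)
        node.age = dnode.edge.length if dnode.edge.length is not None else 0.0
        for child in dnode.child_nodes():
            node.add_child(convert(child))
        return node

    return convert(dtree.seed_node)


def read_newick(text: str, age_mode: str = "branch-lengths") -> Chronogram:
    """Parse a rooted newick string into a :class:`Chronogram`.

    Parameters
    ----------
    text:
        Newick string (or path-like content already read into memory).
    age_mode:
        ``"branch-lengths"`` interprets the ``:x`` annotations as branch
        lengths in Myr and derives node ages; ``"node-ages"`` interprets
        them directly as absolute node ages in Ma (tips may omit theirs).
    """
    if age_mode not in ("branch-lengths", "node-ages"):
        raise ValueError(f"unknown age_mode {age_mode!r}")
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True,
            rooting="force-rooted",
        )
    except Exception as exc:  # dendropy raises several parse error types
        offset = getattr(exc, "column", None)
        loc = f" near character {offset}" if offset is not None else ""
        raise ChronogramError(f"malformed newick{loc}: {exc}") from exc

    root = _dendropy_to_nodes(dtree)
    # at this point node.age temporarily holds the raw ':x' annotation
    if age_mode == "node-ages":
        for node in Chronogram(root, validate=False).postorder():
            if node.is_tip:
                node.age = 0.0
        chron = Chronogram(root)
        return chron

    # branch lengths -> depths -> ages
    depths: dict[int, float] = {id(root): 0.0}
    order = list(Chronogram(root, validate=False).preorder())
    for node in order:
        if node.parent is not None:
            depths[id(node)] = depths[id(node.parent)] + node.age
    tip_depths = {n.label: depths[id(n)] for n in order if n.is_tip}
    root_age = max(tip_depths.values())
    tol = max(root_age, 1.0) * ULTRAMETRIC_RTOL * 10
    for label, depth in tip_depths.items():
        if abs(depth - root_age) > max(tol, 1e-12):
            raise ChronogramError(
                f"non-ultrametric input: tip {label!r} at depth {depth} "
                f"but root-to-tip span is {root_age}"
            )
    for node in order:
        node.age = root_age - depths[id(node)]
        if node.is_tip:
            node.age = 0.0
    return Chronogram(root)


def write_newick(tree: Chronogram, decimals: int = 6) -> str:
    return tree.to_newick(decimals=decimals)


# ------------------------------------------------------------------ builders
def build_chronogram(topology: str, ages: CladeAgeTable) -> Chronogram:
    """Combine a (possibly branch-length-free) newick topology with MRCA ages.

    Every internal node of the topology must be covered by exactly one age
    entry; tips are implicitly at age 0.
    """
    try:
        dtree = dendropy.Tree.get(
            data=topology, schema="newick", suppress_internal_node_taxa=True,
            rooting="force-rooted",
        )
    except Exception as exc:
        raise ChronogramError(f"malformed newick topology: {exc}") from exc
    root = _dendropy_to_nodes(dtree)
    for node in Chronogram(root, validate=False).postorder():
        node.age = 0.0
    skeleton = Chronogram(root, validate=False)

    clades = skeleton.clade_tip_sets()
    by_node: dict[int, float] = {}
    for entry in ages.entries:
        target = skeleton.mrca(sorted(entry.tips))
        if target.is_tip:
            raise ChronogramError(
                f"age entry {sorted(entry.tips)} resolves to a tip, not an MRCA"
            )
        if id(target) in by_node:
            raise ChronogramError(
                f"multiple age entries resolve to the clade {sorted(clades[target])}"
            )
        by_node[id(target)] = entry.age_ma

    for node in skeleton.internal_nodes():
        if id(node) not in by_node:
            raise ChronogramError(
                "missing age for internal node with tips "
                f"{sorted(clades[node])}"
            )
        node.age = by_node[id(node)]

    for node in skeleton.internal_nodes():
        for child in node.children:
            if child.age >= node.age:
                raise ChronogramError(
                    f"clade {sorted(clades[child])} has age {child.age} >= "
                    f"parent age {node.age}"
                )
    return Chronogram(root)


def extract_clade_ages(tree: Chronogram) -> CladeAgeTable:
    """Inverse of :func:`build_chronogram`: one entry per internal node."""
    table = CladeAgeTable()
    clades = tree.clade_tip_sets()
    for node in tree.internal_nodes():
        table.add(sorted(clades[node]), node.age)
    return table


def collapse_to_representatives(
    tree: Chronogram, mapping: Mapping[str, str]
) -> Chronogram:
    """Collapse monophyletic tip groups to single representative tips.

    Each group of tips mapping to the same label must form a monophyletic
    clade; the group's subtree is replaced by a single tip (age 0) attached
    to the group's stem.  Ages of all surviving internal nodes are unchanged.
    """
    missing = set(tree.tip_labels) - set(mapping)
    if missing:
        raise ChronogramError(f"mapping does not cover tips: {sorted(missing)}")

    tree = tree.copy()
    groups: dict[str, set[str]] = {}
    for tip, group in mapping.items():
        groups.setdefault(group, set()).add(tip)

    clades = tree.clade_tip_sets()
    for group, members in sorted(groups.items()):
        mrca = tree.mrca(sorted(members))
        if not mrca.is_tip:
            extra = clades[mrca] - members
            if extra:
                raise ChronogramError(
                    f"group {group!r} is not monophyletic: clade of its tips "
                    f"also contains {sorted(extra)[0]!r}"
                )
        # replace subtree by a fresh tip on the same stem
        replacement = Node(label=group, age=0.0)
        parent = mrca.parent
        if parent is None:
            raise ChronogramError(
                f"group {group!r} spans the whole tree; nothing to attach to"
            )
        parent.children[parent.children.index(mrca)] = replacement
        replacement.parent = parent
    return Chronogram(tree.root)
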