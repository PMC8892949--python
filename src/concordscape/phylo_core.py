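"""Trees, alignments, bipartition algebra, and topology enumeration.

The structures here are deliberately lightweight: a :class:`PhyloTree` is a
parent/child-linked node tree with optional branch lengths, which is all the
concordance, likelihood, and trait machinery needs.  Standard-format I/O is
delegated to dendropy (newick) and Biopython (FASTA, relaxed PHYLIP); the
bipartition algebra, Robinson--Foulds distance, and exhaustive enumeration of
rooted topologies are implemented directly because they are the substrate of
the landscape scan.
"""

from __future__ import annotations

import io
import itertools
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import dendropy
import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.Align import MultipleSeqAlignment


class PhyloError(ValueError):
    """Base class for tree/alignment validation failures."""


class NewickParseError(PhyloError):
    pass


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

class Node:
    """One vertex of a tree; a leaf iff it has no children."""

    __slots__ = ("children", "parent", "label", "length")

    def __init__(self, label=None, length=None):
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.label: str | None = label
        self.length: float | None = length

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Node({self.label!r}, n_children={len(self.children)})"


class PhyloTree:
    """Leaf-labeled tree with optional nonnegative branch lengths.

    ``rooted`` distinguishes a rooted tree (root with two children; internal
    branches correspond to clades) from an unrooted representation (root may
    have three or more children; internal branches correspond to splits).
    """

    def __init__(self, root: Node, rooted: bool | None = None):
        self.root = root
        if rooted is None:
            rooted = len(root.children) == 2
        self.rooted = rooted
        self._validate()

    # -- construction -------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        return read_tree(text)

    # -- validation ---------------------------------------------------------

    def _validate(self):
        labels = [n.label for n in self.leaves()]
        seen = set()
        for lab in labels:
            if lab is None or lab == "":
                raise PhyloError("every leaf must carry a label")
            if lab in seen:
                raise PhyloError(f"duplicate leaf label: {lab!r}")
            seen.add(lab)
        for node in self.preorder():
            if node.length is not None and node.length < 0:
                raise PhyloError(
                    f"negative branch length {node.length} above {node.label!r}"
                )

    # -- traversal ----------------------------------------------------------

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def leaves(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def taxon_set(self) -> frozenset:
        return frozenset(self.leaf_labels())

    def n_leaves(self) -> int:
        return len(self.leaves())

    # -- copying / editing --------------------------------------------------

    def copy(self) -> "PhyloTree":
        def rec(node: Node) -> Node:
            new = Node(node.label, node.length)
            for c in node.children:
                new.add_child(rec(c))
            return new

        return PhyloTree(rec(self.root), rooted=self.rooted)

    def is_binary(self) -> bool:
        for node in self.preorder():
            if node.is_leaf:
                continue
            k = len(node.children)
            if node is self.root:
                if k not in (2, 3):
                    return False
            elif k != 2:
                return False
        return True

    # -- serialization ------------------------------------------------------

    def to_newick(self, lengths: bool = True) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                s = node.label
            else:
                s = "(" + ",".join(fmt(c) for c in node.children) + ")"
                if node.label:
                    s += node.label
            if lengths and node.length is not None:
                s += ":" + format(node.length, ".12g")
            return s

        return fmt(self.root) + ";"

    def __repr__(self):  # pragma: no cover
        return f"PhyloTree({self.to_newick()})"


# ---------------------------------------------------------------------------
# Newick I/O (parsing via dendropy)
# ---------------------------------------------------------------------------

def _from_dendropy(dtree: dendropy.Tree) -> PhyloTree:
    def rec(dnode) -> Node:
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon is not None else dnode.label
            node = Node(label=label)
        else:
            node = Node(label=dnode.label)
        node.length = dnode.edge.length
        for child in dnode.child_nodes():
            node.add_child(rec(child))
        return node

    return PhyloTree(rec(dtree.seed_node))


def read_tree(text: str) -> PhyloTree:
    """Parse a single newick string into a :class:`PhyloTree`."""
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several tokenizer error types
        offset = getattr(exc, "col_num", None)
        loc = f" near character offset {offset}" if offset is not None else ""
        raise NewickParseError(f"malformed newick{loc}: {exc}") from exc
    return _from_dendropy(dtree)


def read_trees(path) -> list[PhyloTree]:
    """Read a file of newick trees, one per line, preserving order."""
    with open(path) as fh:
        text = fh.read()
    return read_trees_string(text)


def read_trees_string(text: str) -> list[PhyloTree]:
    trees = []
    for line in text.strip().splitlines():
        line = line.strip()
        if line:
            trees.append(read_tree(line))
    return trees


def write_trees(trees: Iterable[PhyloTree], path, lengths: bool = True) -> None:
    with open(path, "w") as fh:
        for t in trees:
            fh.write(t.to_newick(lengths=lengths) + "\n")


def unroot(tree: PhyloTree) -> PhyloTree:
    """Return an unrooted copy (trifurcating root) of a rooted binary tree.

    The two branches meeting at a two-child root are merged into one; if the
    tree is already unrooted a plain copy is returned.
    """
    t = tree.copy()
    root = t.root
    if len(root.children) != 2:
        t.rooted = False
        return t
    a, b = root.children
    # collapse into whichever child is internal
    keep, other = (a, b) if not a.is_leaf else (b, a)
    if keep.is_leaf:
        t.rooted = False
        return t  # two-leaf tree: nothing to collapse
    total = None
    if a.length is not None or b.length is not None:
        total = (a.length or 0.0) + (b.length or 0.0)
    new_root = Node(label=root.label)
    for c in keep.children:
        new_root.add_child(c)
    other.length = total
    new_root.add_child(other)
    return PhyloTree(new_root, rooted=False)


def restrict_tree(tree: PhyloTree, taxa: Iterable[str]) -> PhyloTree:
    """Prune the tree to ``taxa``, suppressing unifurcations (lengths summed)."""
    keep = set(taxa)

    def rec(node: Node) -> Node | None:
        if node.is_leaf:
            if node.label in keep:
                return Node(node.label, node.length)
            return None
        kids = [k for k in (rec(c) for c in node.children) if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            child = kids[0]
            if node.length is not None and child.length is not None:
                child.length = child.length + node.length
            elif node.length is not None:
                child.length = node.length
            return child
        new = Node(node.label, node.length)
        for k in kids:
            new.add_child(k)
        return new

    new_root = rec(tree.root)
    if new_root is None:
        raise PhyloError("restriction removed every leaf")
    new_root.length = None
    return PhyloTree(new_root, rooted=tree.rooted)


# ---------------------------------------------------------------------------
# Bipartitions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Bipartition:
    """Unordered pair of disjoint taxon sets covering the full taxon set."""

    side_a: frozenset
    side_b: frozenset

    def __post_init__(self):
        if self.side_a & self.side_b:
            raise PhyloError("bipartition sides must be disjoint")

    def __eq__(self, other):
        if not isinstance(other, Bipartition):
            return NotImplemented
        return {self.side_a, self.side_b} == {other.side_a, other.side_b}

    def __hash__(self):
        return hash(frozenset((self.side_a, self.side_b)))

    @property
    def taxa(self) -> frozenset:
        return self.side_a | self.side_b

    def is_nontrivial(self) -> bool:
        return len(self.side_a) >= 2 and len(self.side_b) >= 2

    def restrict(self, taxa: frozenset) -> "Bipartition":
        return Bipartition(self.side_a & taxa, self.side_b & taxa)

    def normalized_side(self) -> frozenset:
        """The side containing the lexicographically smallest taxon."""
        anchor = min(self.taxa)
        return self.side_a if anchor in self.side_a else self.side_b

    def __repr__(self):
        fmt = lambda s: "{" + ",".join(sorted(s)) + "}"
        a, b = sorted((self.side_a, self.side_b), key=lambda s: sorted(s))
        return f"{fmt(a)}|{fmt(b)}"


def _clade_sets(tree: PhyloTree) -> dict:
    """Map each non-root node to the frozenset of leaf labels below it."""
    clades = {}
    for node in tree.postorder():
        if node.is_leaf:
            clades[node] = frozenset([node.label])
        else:
            clades[node] = frozenset().union(*(clades[c] for c in node.children))
    return clades


def bipartition_set(tree: PhyloTree) -> set[Bipartition]:
    """Nontrivial bipartitions of ``tree``, one per internal branch.

    On an unrooted tree these are the standard splits (both sides >= 2 taxa;
    n-3 of them for a binary tree).  On a rooted tree every clade of size
    2..n-1 defines a branch, including the size-(n-1) clade adjacent to the
    root, because the root position is itself informative.
    """
    taxa = tree.taxon_set()
    n = len(taxa)
    if n < 4 and not tree.rooted:
        return set()
    clades = _clade_sets(tree)
    out: set[Bipartition] = set()
    for node, clade in clades.items():
        if node is tree.root:
            continue
        other = taxa - clade
        if tree.rooted:
            if 2 <= len(clade) <= n - 1 and other:
                out.add(Bipartition(clade, other))
        else:
            if len(clade) >= 2 and len(other) >= 2:
                out.add(Bipartition(clade, other))
    return out


def rooted_clades(tree: PhyloTree) -> set[frozenset]:
    """Nontrivial rooted clades (leaf sets of size 2..n-1 below internal nodes).

    Unlike :func:`bipartition_set`, complementary clades are kept distinct:
    {A,B} and {C,D,E} are different clades of a 5-taxon rooted tree even
    though they induce the same unordered bipartition.  A rooted binary
    topology is uniquely determined by this set, which is what rooted
    Robinson--Foulds comparison needs.
    """
    taxa = tree.taxon_set()
    n = len(taxa)
    clades = _clade_sets(tree)
    return {
        clade for node, clade in clades.items()
        if node is not tree.root and 2 <= len(clade) <= n - 1
    }


def unrooted_splits(tree: PhyloTree) -> set[frozenset]:
    """Unrooted nontrivial splits as normalized frozensets.

    Each split is represented by the side containing the smallest taxon
    label, which makes membership tests against induced bipartitions cheap.
    Works for rooted or unrooted input (the root edge is ignored).
    """
    taxa = tree.taxon_set()
    anchor = min(taxa) if taxa else None
    out: set[frozenset] = set()
    clades = _clade_sets(tree)
    for node, clade in clades.items():
        if node is tree.root:
            continue
        other = taxa - clade
        if len(clade) >= 2 and len(other) >= 2:
            side = clade if anchor in clade else other
            out.add(side)
    return out


def robinson_foulds(t1: PhyloTree, t2: PhyloTree) -> int:
    """Symmetric-difference (Robinson--Foulds) distance between two trees.

    Unrooted trees are compared on their nontrivial splits; rooted trees on
    their rooted clade sets (so trees differing only in root placement are at
    positive distance, and the distance is a proper metric on rooted
    topologies).
    """
    s1, s2 = t1.taxon_set(), t2.taxon_set()
    if s1 != s2:
        missing = sorted(s1 ^ s2)
        raise PhyloError(f"leaf sets differ; offending taxa: {missing}")
    if t1.rooted != t2.rooted:
        raise PhyloError("cannot compare a rooted with an unrooted tree")
    if t1.rooted:
        return len(rooted_clades(t1) ^ rooted_clades(t2))
    return len(bipartition_set(t1) ^ bipartition_set(t2))


# ---------------------------------------------------------------------------
# Topology enumeration and canonical forms
# ---------------------------------------------------------------------------

def canonical_form(tree: PhyloTree) -> str:
    """Canonical topology string: equal iff two trees share a rooted topology.

    Children are ordered by their smallest descendant label (ties broken by
    the canonical substring), and branch lengths are ignored.
    """

    def rec(node: Node) -> tuple[str, str]:
        if node.is_leaf:
            return node.label, node.label
        parts = sorted(rec(c) for c in node.children)
        min_label = min(p[0] for p in parts)
        return min_label, "(" + ",".join(p[1] for p in parts) + ")"

    return rec(tree.root)[1] + ";"


def _tuple_to_tree(t) -> PhyloTree:
    def rec(x) -> Node:
        if isinstance(x, tuple):
            node = Node()
            for part in x:
                node.add_child(rec(part))
            return node
        return Node(label=x)

    root = rec(t)
    return PhyloTree(root, rooted=len(root.children) == 2)


def enumerate_rooted_topologies(labels: Sequence[str]) -> list[PhyloTree]:
    """All distinct rooted binary leaf-labeled topologies on ``labels``.

    Built by recursive leaf insertion on every branch (including above the
    root), which yields the (2k-3)!! rooted topologies; the result is sorted
    by canonical form for a reproducible order.
    """
    labels = list(labels)
    if len(set(labels)) != len(labels):
        raise PhyloError("labels must be distinct")
    if not labels:
        raise PhyloError("need at least one label")
    shapes = [labels[0]]
    for leaf in labels[1:]:
        nxt = []
        for shape in shapes:
            nxt.extend(_insertions(shape, leaf))
        shapes = nxt
    trees = [_tuple_to_tree(s) for s in shapes]
    by_canon = {canonical_form(t): t for t in trees}
    if len(by_canon) != len(trees):  # pragma: no cover - enumeration is exact
        raise AssertionError("duplicate topologies produced by insertion")
    return [by_canon[k] for k in sorted(by_canon)]


def _insertions(shape, leaf):
    """Yield every tree obtained by inserting ``leaf`` on a branch of ``shape``."""
    yield (shape, leaf)
    if isinstance(shape, tuple):
        a, b = shape
        for na in _insertions(a, leaf):
            yield (na, b)
        for nb in _insertions(b, leaf):
            yield (a, nb)


def n_rooted_topologies(k: int) -> int:
    """(2k-3)!! -- the number of rooted binary leaf-labeled topologies."""
    if k < 1:
        raise PhyloError("k must be >= 1")
    out = 1
    for m in range(3, 2 * k - 2, 2):
        out *= m
    return out


# ---------------------------------------------------------------------------
# Clade maps
# ---------------------------------------------------------------------------

@dataclass
class CladeMap:
    """Assignment of taxa to named clades, with one clade as the outgroup."""

    assignments: dict  # taxon -> clade label
    outgroup: str

    def __post_init__(self):
        clades = set(self.assignments.values())
        if self.outgroup not in clades:
            raise PhyloError(f"outgroup clade {self.outgroup!r} has no taxa")
        if len(clades) - 1 < 2:
            raise PhyloError("need at least two ingroup clades")

    @property
    def ingroup_clades(self) -> list[str]:
        return sorted(set(self.assignments.values()) - {self.outgroup})

    @property
    def clades(self) -> list[str]:
        return sorted(set(self.assignments.values()))

    def taxa_in(self, clade: str) -> frozenset:
        return frozenset(t for t, c in self.assignments.items() if c == clade)

    def taxa(self) -> frozenset:
        return frozenset(self.assignments)

    @classmethod
    def from_tsv(cls, path) -> "CladeMap":
        import pandas as pd

        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"taxon", "clade", "outgroup"}
        if not required.issubset(df.columns):
            raise PhyloError(f"clade map needs columns {sorted(required)}")
        if df["taxon"].duplicated().any():
            dupes = df.loc[df["taxon"].duplicated(), "taxon"].tolist()
            raise PhyloError(f"taxa assigned more than once: {dupes}")
        out_clades = set(df.loc[df["outgroup"].astype(int) == 1, "clade"])
        if len(out_clades) != 1:
            raise PhyloError("exactly one clade must be flagged as outgroup")
        return cls(dict(zip(df["taxon"], df["clade"])), out_clades.pop())

    def to_tsv(self, path) -> None:
        import pandas as pd

        rows = [
            {"taxon": t, "clade": c, "outgroup": int(c == self.outgroup)}
            for t, c in sorted(self.assignments.items())
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

_CODES = {"A": 0, "C": 1, "G": 2, "T": 3, "-": 4, "N": 4}
MISSING = 4
_BASES = np.array(list("ACGTN"))


class MultipleAlignment:
    """Nucleotide alignment: taxa x sites, characters in {A,C,G,T,-,N}.

    Ambiguity codes beyond N are collapsed to N on construction (with a
    warning), mirroring a pipeline that converts non-nucleotide characters to
    missing data.  ``codes`` is an integer matrix with A,C,G,T -> 0..3 and
    anything else -> 4 (missing).
    """

    def __init__(self, taxa: Sequence[str], rows: Sequence[str]):
        self.taxa = list(taxa)
        if len(set(self.taxa)) != len(self.taxa):
            raise PhyloError("alignment taxa must be unique")
        lengths = {len(r) for r in rows}
        if len(lengths) > 1:
            raise PhyloError(f"ragged alignment rows (lengths {sorted(lengths)})")
        self.n_sites = lengths.pop() if lengths else 0
        chars = np.array([list(r.upper()) for r in rows], dtype="<U1")
        if chars.size:
            known = np.isin(chars, list("ACGT-N"))
            if not known.all():
                bad = sorted(set(chars[~known].tolist()))
                warnings.warn(
                    f"collapsing ambiguity codes {bad} to N", stacklevel=2
                )
                chars[~known] = "N"
        self.chars = chars
        codes = np.full(chars.shape, MISSING, dtype=np.uint8)
        for base, code in (("A", 0), ("C", 1), ("G", 2), ("T", 3)):
            codes[chars == base] = code
        self.codes = codes
        self._index = {t: i for i, t in enumerate(self.taxa)}

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_taxa, self.n_sites)

    def row_index(self, taxon: str) -> int:
        try:
            return self._index[taxon]
        except KeyError:
            raise PhyloError(f"taxon {taxon!r} not in alignment") from None

    def row(self, taxon: str) -> str:
        return "".join(self.chars[self.row_index(taxon)])

    def subset_columns(self, start: int, end: int) -> "MultipleAlignment":
        rows = ["".join(r) for r in self.chars[:, start:end]]
        return MultipleAlignment(self.taxa, rows)

    def subset_taxa(self, taxa: Sequence[str]) -> "MultipleAlignment":
        idx = [self.row_index(t) for t in taxa]
        rows = ["".join(r) for r in self.chars[idx]]
        return MultipleAlignment(list(taxa), rows)

    # -- I/O ----------------------------------------------------------------

    @classmethod
    def from_fasta(cls, path) -> "MultipleAlignment":
        records = list(SeqIO.parse(path, "fasta"))
        if not records:
            raise PhyloError(f"no sequences in {path}")
        return cls([r.id for r in records], [str(r.seq) for r in records])

    def to_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(self.row(t)), id=t, description="") for t in self.taxa
        ]
        SeqIO.write(records, path, "fasta-2line")

    @classmethod
    def from_phylip(cls, path) -> "MultipleAlignment":
        aln = AlignIO.read(path, "phylip-relaxed")
        return cls([r.id for r in aln], [str(r.seq) for r in aln])

    def to_phylip(self, path) -> None:
        aln = MultipleSeqAlignment(
            SeqRecord(Seq(self.row(t)), id=t, description="") for t in self.taxa
        )
        AlignIO.write(aln, path, "phylip-relaxed")

    @classmethod
    def concatenate(cls, alignments: Sequence["MultipleAlignment"],
                    all_taxa: Sequence[str] | None = None) -> "MultipleAlignment":
        """Concatenate gene alignments; taxa absent from a gene are filled with N."""
        if all_taxa is None:
            seen = []
            for a in alignments:
                for t in a.taxa:
                    if t not in seen:
                        seen.append(t)
            all_taxa = seen
        rows = []
        for t in all_taxa:
            parts = []
            for a in alignments:
                parts.append(a.row(t) if t in a._index else "N" * a.n_sites)
            rows.append("".join(parts))
        return cls(list(all_taxa), rows)


# ---------------------------------------------------------------------------
# Partition files (RAxML dialect)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenePartition:
    """A gene's column interval, stored 0-based half-open."""

    name: str
    start: int
    end: int

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise PhyloError(f"empty or inverted interval for {self.name}")

    @property
    def width(self) -> int:
        return self.end - self.start


_PARTITION_RE = re.compile(
    r"^\s*DNA\s*,\s*(?P<name>\S+)\s*=\s*(?P<a>\d+)\s*-\s*(?P<b>\d+)\s*$"
)


def read_partitions(path, n_sites: int | None = None) -> list[GenePartition]:
    """Parse 'DNA, name = a-b' lines (1-based inclusive) to half-open intervals."""
    parts: list[GenePartition] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            m = _PARTITION_RE.match(line)
            if not m:
                raise PhyloError(f"unparseable partition line {lineno}: {line!r}")
            a, b = int(m["a"]), int(m["b"])
            parts.append(GenePartition(m["name"], a - 1, b))
    validate_partitions(parts, n_sites)
    return parts


def validate_partitions(parts: Sequence[GenePartition],
                        n_sites: int | None = None) -> None:
    ordered = sorted(parts, key=lambda p: p.start)
    for prev, cur in zip(ordered, ordered[1:]):
        if cur.start < prev.end:
            raise PhyloError(f"partitions {prev.name} and {cur.name} overlap")
    if n_sites is not None:
        for p in parts:
            if p.end > n_sites:
                raise PhyloError(
                    f"partition {p.name} ends at {p.end} > {n_sites} sites"
                )


def write_partitions(parts: Sequence[GenePartition], path) -> None:
    with open(path, "w") as fh:
        for p in parts:
            fh.write(f"DNA, {p.name} = {p.start + 1}-{p.end}\n")
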