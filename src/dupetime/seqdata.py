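"""Core domain types: alignments, coding-sequence sets, and rooted trees.

The tree class is deliberately small: the duplication-timing analysis needs
parent pointers, stable branch identifiers (a branch is named after its child
node), ancestor queries, and graft/prune surgery — nothing more. Newick text
is parsed through dendropy and converted, so all dialect handling (quoted
labels, comments) is delegated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import dendropy
from Bio import AlignIO, SeqIO

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY") | {"-", "X"}
NUCLEOTIDE_ALPHABET = set("ACGTN")

#: identifier of the branch above the root (attachment slot for a new outgroup)
ROOT_BRANCH = "__root__"


class AlignmentShapeError(ValueError):
    """Rows of an alignment differ in length."""


class AlphabetError(ValueError):
    """A sequence contains characters outside its declared alphabet."""


class FrameError(ValueError):
    """A coding sequence length is not a multiple of three."""


# ---------------------------------------------------------------------------
# sequence containers
# ---------------------------------------------------------------------------

@dataclass
class ProteinAlignment:
    """Aligned amino-acid sequences (20 residues plus gap '-' and unknown 'X')."""

    names: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.rows):
            raise ValueError("names and rows differ in length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate sequence identifiers")
        if self.rows:
            length = len(self.rows[0])
            for name, row in zip(self.names, self.rows):
                if len(row) != length:
                    raise AlignmentShapeError(
                        f"row {name!r} has length {len(row)}, expected {length}"
                    )
                bad = set(row.upper()) - PROTEIN_ALPHABET
                if bad:
                    raise AlphabetError(f"illegal characters in {name!r}: {sorted(bad)}")
        self.rows = [r.upper() for r in self.rows]

    @property
    def length(self) -> int:
        """Number of aligned sites (columns)."""
        return len(self.rows[0]) if self.rows else 0

    @property
    def n_sequences(self) -> int:
        return len(self.names)

    def row(self, name: str) -> str:
        return self.rows[self.names.index(name)]

    def subset(self, names: Sequence[str]) -> "ProteinAlignment":
        return ProteinAlignment(list(names), [self.row(n) for n in names])


@dataclass
class CodingSequenceSet:
    """In-frame protein-coding nucleotide sequences (frame 1, standard code).

    Internal stop codons are tolerated with a warning; downstream codon
    counting skips them. Lengths must be multiples of three.
    """

    names: list[str]
    sequences: list[str]
    genetic_code: int = 1

    def __post_init__(self) -> None:
        if len(self.names) != len(self.sequences):
            raise ValueError("names and sequences differ in length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate sequence identifiers")
        cleaned = []
        for name, seq in zip(self.names, self.sequences):
            seq = seq.upper()
            bad = set(seq) - NUCLEOTIDE_ALPHABET
            if bad:
                raise AlphabetError(f"illegal characters in {name!r}: {sorted(bad)}")
            if len(seq) % 3 != 0:
                raise FrameError(f"{name!r}: length {len(seq)} is not a multiple of 3")
            cleaned.append(seq)
        self.sequences = cleaned
        n_stops = sum(self._internal_stops(s) for s in self.sequences)
        if n_stops:
            warnings.warn(
                f"{n_stops} internal stop codon(s) present; they are excluded "
                "from codon counts",
                stacklevel=2,
            )

    @staticmethod
    def _internal_stops(seq: str) -> int:
        stops = {"TAA", "TAG", "TGA"}
        codons = [seq[i : i + 3] for i in range(0, len(seq) - 3, 3)]
        return sum(c in stops for c in codons)

    def codons(self, name: str) -> list[str]:
        seq = self.sequences[self.names.index(name)]
        return [seq[i : i + 3] for i in range(0, len(seq), 3)]

    def filter_min_length(self, min_aa: int) -> "CodingSequenceSet":
        """Drop sequences encoding fewer than ``min_aa`` amino acids."""
        keep = [i for i, s in enumerate(self.sequences) if len(s) // 3 >= min_aa]
        return CodingSequenceSet(
            [self.names[i] for i in keep],
            [self.sequences[i] for i in keep],
            self.genetic_code,
        )


# ---------------------------------------------------------------------------
# rooted trees
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    name: str | None = None
    length: float | None = None
    parent: "TreeNode | None" = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "TreeNode") -> None:
        child.parent = self
        self.children.append(child)

    def ancestors(self) -> Iterator["TreeNode"]:
        """Strict ancestors, nearest first."""
        node = self.parent
        while node is not None:
            yield node
            node = node.parent

    def is_ancestor_of(self, other: "TreeNode") -> bool:
        """True if self is a strict ancestor of other."""
        return any(a is self for a in other.ancestors())

    def __repr__(self) -> str:  # pragma: no cover
        return f"TreeNode({self.name!r})"


class RootedTree:
    """Rooted (binary, for backbones) tree with stable branch identifiers.

    A branch is identified by the name of its child node; internal nodes
    without explicit Newick labels receive deterministic post-order names
    ``N1, N2, ...``. The slot above the root is addressable as
    :data:`ROOT_BRANCH` so a query can be attached as a new outgroup.
    """

    def __init__(self, root: TreeNode):
        self.root = root
        self._assign_names()
        labels = self.leaf_names()
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate leaf labels")

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "RootedTree":
        try:
            dtree = dendropy.Tree.get(
                data=text, schema="newick", suppress_internal_node_taxa=True
            )
        except Exception as exc:  # dendropy raises parser-specific subclasses
            raise ValueError(f"invalid Newick: {exc}") from exc
        root = cls._convert(dtree.seed_node)
        return cls(root)

    @staticmethod
    def _convert(dnode) -> TreeNode:
        name = None
        if dnode.taxon is not None:
            name = dnode.taxon.label
        elif dnode.label:
            name = dnode.label
        node = TreeNode(name=name, length=dnode.edge.length)
        for child in dnode.child_nodes():
            node.add_child(RootedTree._convert(child))
        return node

    def _assign_names(self) -> None:
        counter = 0
        seen = set()
        for node in self.postorder():
            if node.name is None:
                counter += 1
                node.name = f"N{counter}"
            if node.name in seen:
                raise ValueError(f"duplicate node name {node.name!r}")
            seen.add(node.name)

    # -- traversal ---------------------------------------------------------

    def postorder(self) -> Iterator[TreeNode]:
        def walk(node: TreeNode) -> Iterator[TreeNode]:
            for child in node.children:
                yield from walk(child)
            yield node

        yield from walk(self.root)

    def preorder(self) -> Iterator[TreeNode]:
        def walk(node: TreeNode) -> Iterator[TreeNode]:
            yield node
            for child in node.children:
                yield from walk(child)

        yield from walk(self.root)

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def internal_nodes(self) -> list[TreeNode]:
        return [n for n in self.postorder() if not n.is_leaf]

    def node(self, name: str) -> TreeNode:
        for n in self.postorder():
            if n.name == name:
                return n
        raise KeyError(name)

    def branch_ids(self, include_root: bool = True) -> list[str]:
        """All branch identifiers (child-node names), root branch last.

        An n-leaf rooted binary tree has 2n-2 real branches plus the root
        slot, i.e. 2n-1 attachable positions.
        """
        ids = [n.name for n in self.postorder() if n is not self.root]
        if include_root:
            ids.append(ROOT_BRANCH)
        return ids

    def check_binary(self) -> None:
        for node in self.internal_nodes():
            if len(node.children) != 2:
                raise ValueError(
                    f"node {node.name!r} has {len(node.children)} children; "
                    "backbone trees must be strictly binary (a basal "
                    "trifurcation indicates an unrooted tree)"
                )

    # -- copying and output ------------------------------------------------

    def copy(self) -> "RootedTree":
        def dup(node: TreeNode) -> TreeNode:
            new = TreeNode(name=node.name, length=node.length)
            for child in node.children:
                new.add_child(dup(child))
            return new

        return RootedTree(dup(self.root))

    def newick(self, lengths: bool = True, internal_labels: bool = False) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                s = node.name
            else:
                s = "(" + ",".join(fmt(c) for c in node.children) + ")"
                if internal_labels:
                    s += node.name
            if lengths and node.length is not None and node is not self.root:
                s += f":{node.length:.10g}"
            return s

        return fmt(self.root) + ";"

    def canonical_newick(self) -> str:
        """Topology-only Newick with children sorted by smallest leaf label.

        Two rooted trees have equal canonical strings iff they share the
        same labelled topology; used for deduplication.
        """

        def key(node: TreeNode) -> str:
            return node.name if node.is_leaf else min(key(c) for c in node.children)

        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return node.name
            parts = sorted((fmt(c) for c in sorted(node.children, key=key)))
            return "(" + ",".join(parts) + ")"

        return fmt(self.root) + ";"


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _looks_like_nucleotide(seqs: Sequence[str]) -> bool:
    chars = set("".join(seqs).upper()) - {"-"}
    return bool(chars) and chars <= NUCLEOTIDE_ALPHABET


def read_fasta(path, kind: str = "auto") -> ProteinAlignment | CodingSequenceSet:
    """Read FASTA into a :class:`ProteinAlignment` or :class:`CodingSequenceSet`.

    ``kind`` is ``"protein"``, ``"cds"`` or ``"auto"`` (sequences over
    {A,C,G,T,N} are taken as CDS). Record order is preserved; duplicate
    identifiers are rejected.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    names = [r.id for r in records]
    seqs = [str(r.seq) for r in records]
    if len(set(names)) != len(names):
        raise ValueError("duplicate FASTA identifiers")
    if kind == "auto":
        kind = "cds" if _looks_like_nucleotide(seqs) else "protein"
    if kind == "cds":
        return CodingSequenceSet(names, seqs)
    return ProteinAlignment(names, seqs)


def write_fasta(obj: ProteinAlignment | CodingSequenceSet, path) -> None:
    seqs = obj.rows if isinstance(obj, ProteinAlignment) else obj.sequences
    with open(path, "w") as fh:
        for name, seq in zip(obj.names, seqs):
            fh.write(f">{name}\n{seq}\n")


def read_phylip(path) -> ProteinAlignment:
    """Read a relaxed sequential/interleaved PHYLIP protein alignment."""
    try:
        aln = AlignIO.read(str(path), "phylip-relaxed")
    except ValueError:
        aln = AlignIO.read(str(path), "phylip")
    return ProteinAlignment([r.id for r in aln], [str(r.seq) for r in aln])


def read_newick(path_or_text) -> RootedTree:
    """Read a rooted tree from a Newick file or literal string."""
    text = str(path_or_text)
    if not text.strip().startswith("("):
        with open(text) as fh:
            text = fh.read()
    tree = RootedTree.from_newick(text)
    return tree


def write_newick(tree: RootedTree, path, lengths: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(tree.newick(lengths=lengths) + "\n")
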