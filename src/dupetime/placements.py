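"""Enumeration of candidate attachments of one query gene on a backbone.

A backbone specification holds one or more alternative binary arrangements
of the same leaf set (resolutions of a constrained polytomy treated as
equally likely a priori). The query is grafted onto every branch of every
arrangement, including the slot above the root, giving
(arrangements) x (2n-1) candidate rooted topologies for an n-leaf backbone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .seqdata import ROOT_BRANCH, RootedTree, TreeNode

DEFAULT_PENDANT = 0.1


@dataclass
class BackboneSpec:
    """Alternative binary arrangements of a constrained backbone."""

    arrangements: dict[str, RootedTree]

    def __post_init__(self) -> None:
        leaf_sets = {frozenset(t.leaf_names()) for t in self.arrangements.values()}
        if len(leaf_sets) > 1:
            raise ValueError("arrangements must share one leaf set")
        for tree in self.arrangements.values():
            tree.check_binary()

    @property
    def leaf_names(self) -> list[str]:
        return sorted(next(iter(self.arrangements.values())).leaf_names())

    @classmethod
    def from_yaml(cls, path) -> "BackboneSpec":
        """Load ``{arrangements: [{id: ..., newick: ...}, ...]}`` (or a single
        ``newick`` key) from YAML."""
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        if "newick" in cfg:
            return cls({"arr1": RootedTree.from_newick(cfg["newick"])})
        arrangements = {
            entry["id"]: RootedTree.from_newick(entry["newick"])
            for entry in cfg["arrangements"]
        }
        return cls(arrangements)


@dataclass
class Placement:
    """One candidate topology: the query grafted on one backbone branch."""

    placement_id: str
    arrangement_id: str
    branch_id: str
    tree: RootedTree
    graft_node: str  # name of the internal node created by the graft
    query: str = ""
    extra: dict = field(default_factory=dict)


def graft(
    tree: RootedTree,
    branch_id: str,
    query: str,
    pendant: float = DEFAULT_PENDANT,
    graft_name: str = "GRAFT",
) -> RootedTree:
    """Attach ``query`` on the named branch of a copy of ``tree``.

    The new internal node bisects the branch (halving its length, or using
    ``pendant/2`` halves when the branch carries no length); grafting on
    :data:`ROOT_BRANCH` creates a new root with the old root and the query
    as children.
    """
    if query in tree.leaf_names():
        raise ValueError(f"query name {query!r} collides with a backbone leaf")
    work = tree.copy()
    new = TreeNode(name=graft_name)
    leaf = TreeNode(name=query, length=pendant)
    if branch_id == ROOT_BRANCH:
        old_root = work.root
        old_root.length = pendant / 2.0
        new.add_child(old_root)
        new.add_child(leaf)
        return RootedTree(new)
    node = work.node(branch_id)
    if node is work.root:
        raise KeyError(f"{branch_id!r} is the root node, not a branch")
    parent = node.parent
    half = (node.length / 2.0) if node.length is not None else pendant / 2.0
    new.length = half
    node.length = half
    parent.children[parent.children.index(node)] = new
    new.parent = parent
    new.add_child(node)
    new.add_child(leaf)
    return RootedTree(work.root)


def degraft(tree: RootedTree, query: str) -> RootedTree:
    """Remove ``query`` and splice out its parent, merging branch lengths."""
    work = tree.copy()
    leaf = work.node(query)
    if not leaf.is_leaf:
        raise ValueError(f"{query!r} is not a leaf")
    parent = leaf.parent
    if parent is None:
        raise ValueError("cannot remove the root")
    (other,) = [c for c in parent.children if c is not leaf]
    if parent is work.root:
        other.parent = None
        other.length = None
        return RootedTree(other)
    grand = parent.parent
    if other.length is not None and parent.length is not None:
        other.length += parent.length
    grand.children[grand.children.index(parent)] = other
    other.parent = grand
    return RootedTree(work.root)


def enumerate_placements(
    spec: BackboneSpec, query: str, pendant: float = DEFAULT_PENDANT
) -> list[Placement]:
    """All distinct placements of ``query`` across arrangements and branches.

    Every arrangement contributes 2n-1 attachment positions (2n-2 branches
    plus the root slot); duplicates across arrangements are rejected via
    canonical topology strings.
    """
    placements: list[Placement] = []
    seen: dict[str, str] = {}
    for arr_id, tree in spec.arrangements.items():
        for branch_id in tree.branch_ids(include_root=True):
            grafted = graft(tree, branch_id, query, pendant=pendant)
            canon = grafted.canonical_newick()
            pid = f"{arr_id}:{branch_id}"
            if canon in seen:
                raise ValueError(
                    f"duplicate topology: {pid} repeats {seen[canon]}"
                )
            seen[canon] = pid
            placements.append(
                Placement(
                    placement_id=pid,
                    arrangement_id=arr_id,
                    branch_id=branch_id,
                    tree=grafted,
                    graft_node="GRAFT",
                    query=query,
                )
            )
    return placements
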