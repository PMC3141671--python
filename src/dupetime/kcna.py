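"""The shaker-related potassium-channel (KCNA) backbone shipped as default.

Gnathostomes carry eight KCNA genes, six of them in two syntenic tri-gene
clusters (KCNA6-1-5 and KCNA3-2-10) produced by two tandem duplications
followed by one cluster-wide (chromosomal/whole-genome) duplication. On the
gene tree that cluster duplication appears simultaneously as the three
paralog-pair nodes (KCNA1,2), (KCNA3,6) and (KCNA5,10), which therefore map
to a single duplication event — the focal event whose timing relative to
the cyclostome–gnathostome split is under test. Relationships among KCNA4,
KCNA7 and the six cluster genes are fixed; the three pairings among the
paralog-pair cherries are treated as equally likely, giving three backbone
arrangements.
"""

from __future__ import annotations

from .placements import BackboneSpec
from .seqdata import RootedTree
from .timing import EventModel

#: the three paralog-pair cherries created by the cluster duplication
PAIRS = {
    "12": "(KCNA1:{t},KCNA2:{t})anc12:{i}",
    "36": "(KCNA3:{t},KCNA6:{t})anc36:{i}",
    "510": "(KCNA5:{t},KCNA10:{t})anc510:{i}",
}

#: default branch lengths (substitutions/site) used by fixtures and simulation
TERMINAL_LENGTH = 0.3
INTERNAL_LENGTH = 0.15


def kcna_arrangement_newick(
    pairing: tuple[str, str],
    terminal: float = TERMINAL_LENGTH,
    internal: float = INTERNAL_LENGTH,
) -> str:
    """Newick for one basal arrangement: the two named cherries are sisters."""
    a, b = pairing
    (c,) = [p for p in PAIRS if p not in pairing]
    fmt = dict(t=f"{terminal:g}", i=f"{internal:g}")
    pa, pb, pc = (PAIRS[x].format(**fmt) for x in (a, b, c))
    return (
        f"(((({pa},{pb})ancPair:{internal:g},{pc})ancCluster:{internal:g},"
        f"KCNA4:{terminal:g})anc4:{internal:g},KCNA7:{terminal:g})root;"
    )


def kcna_backbone_spec(
    terminal: float = TERMINAL_LENGTH, internal: float = INTERNAL_LENGTH
) -> BackboneSpec:
    """The 8-gene backbone with its three equally likely basal arrangements."""
    pairings = [("12", "36"), ("12", "510"), ("36", "510")]
    return BackboneSpec(
        {
            f"arr_{a}_{b}": RootedTree.from_newick(
                kcna_arrangement_newick((a, b), terminal, internal)
            )
            for a, b in pairings
        }
    )


def kcna_event_model() -> EventModel:
    """Duplication events behind the seven internal nodes of the backbone.

    The three paralog-pair nodes share the focal cluster duplication; the
    two in-cluster tandem duplications, the KCNA4 split and the KCNA7 split
    are one event each.
    """
    return EventModel(
        node_to_event={
            "anc12": "cluster_dup",
            "anc36": "cluster_dup",
            "anc510": "cluster_dup",
            "ancPair": "tandem_dup_2",
            "ancCluster": "tandem_dup_1",
            "anc4": "kcna4_split",
            "root": "kcna7_split",
        },
        focal_event="cluster_dup",
    )
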