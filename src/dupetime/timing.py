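"""Timing duplication events against the speciation node of a grafted query.

The node created by grafting the query (a cyclostome gene) is interpreted
as the cyclostome–gnathostome speciation, S. A duplication event — a set
of pairwise non-ancestral backbone nodes that arose in one duplication —
is timed:

* ``before`` the split if any of its nodes is a strict ancestor of S;
* ``after``  the split if (otherwise) any of its nodes descends from S;
* ``undetermined`` when all its nodes sit in "uncle" subtrees branching
  off below S's ancestors, which the topology cannot order against S.

Duplications are counted per backbone *node* but timed per *event*: the
one focal cluster duplication spans three paralog-pair nodes, so timing it
"before" moves three node-counts at once. The focal event's timing defines
the competing scenarios (II = cluster duplication before the split, I =
after); probability-weighted averaging over candidate placements yields a
scenario probability and expected duplication counts N_bef / N_aft.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .placements import Placement
from .seqdata import RootedTree
from .weights import TopologyWeights

BEFORE, AFTER, UNDETERMINED = "before", "after", "undetermined"
SCENARIO_I, SCENARIO_II, AMBIGUOUS = "I", "II", "ambiguous"


@dataclass
class EventModel:
    """Many-to-one map from backbone internal nodes to duplication events."""

    node_to_event: dict[str, str]
    focal_event: str

    def __post_init__(self) -> None:
        if self.focal_event not in self.node_to_event.values():
            raise ValueError(f"focal event {self.focal_event!r} maps to no node")

    @property
    def events(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for node, event in self.node_to_event.items():
            out.setdefault(event, []).append(node)
        return out

    def validate(self, backbone: RootedTree) -> None:
        """Check full coverage of internal nodes and non-ancestrality within events."""
        internal = {n.name for n in backbone.internal_nodes()}
        mapped = set(self.node_to_event)
        if internal != mapped:
            raise ValueError(
                f"event map does not cover internal nodes: missing {sorted(internal - mapped)}, "
                f"extra {sorted(mapped - internal)}"
            )
        for event, names in self.events.items():
            nodes = [backbone.node(n) for n in names]
            for i, a in enumerate(nodes):
                for b in nodes[i + 1 :]:
                    if a.is_ancestor_of(b) or b.is_ancestor_of(a):
                        raise ValueError(
                            f"event {event!r} contains ancestral pair ({a.name}, {b.name})"
                        )

    @classmethod
    def from_tsv(cls, path) -> "EventModel":
        """Read a (node_label, event_id, is_focal) table."""
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"node_label", "event_id", "is_focal"}
        if not required <= set(df.columns):
            raise ValueError(f"event map needs columns {sorted(required)}")
        focal = df.loc[df["is_focal"].str.lower().isin({"1", "true", "yes"}), "event_id"]
        if focal.nunique() != 1:
            raise ValueError("exactly one focal event must be designated")
        return cls(
            node_to_event=dict(zip(df["node_label"], df["event_id"])),
            focal_event=focal.iloc[0],
        )

    def to_tsv(self, path) -> None:
        rows = [
            {"node_label": n, "event_id": e, "is_focal": str(e == self.focal_event).lower()}
            for n, e in self.node_to_event.items()
        ]
        pd.DataFrame(rows).to_csv(Path(path), sep="\t", index=False)


@dataclass
class TimingResult:
    """Per-placement event timings and node-level duplication counts."""

    placement_id: str
    event_timing: dict[str, str]
    n_bef: int
    n_aft: int
    n_und: int
    scenario: str


@dataclass
class ScenarioSummary:
    """Probability-weighted scenario support and duplication counts."""

    p_scenario_i: float
    p_scenario_ii: float
    n_bef: float
    n_aft: float
    query: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "query": self.query,
                    "P_I": self.p_scenario_i,
                    "P_II": self.p_scenario_ii,
                    "N_bef": self.n_bef,
                    "N_aft": self.n_aft,
                }
            ]
        )


def classify_placement(placement: Placement, events: EventModel) -> TimingResult:
    """Time every event of ``events`` against the placement's graft node."""
    tree = placement.tree
    s = tree.node(placement.graft_node)
    ancestors = set(id(a) for a in s.ancestors())
    timing: dict[str, str] = {}
    counts = Counter()
    for event, names in events.events.items():
        nodes = [tree.node(n) for n in names]
        if any(id(n) in ancestors for n in nodes):
            verdict = BEFORE
        elif any(s.is_ancestor_of(n) for n in nodes):
            verdict = AFTER
        else:
            verdict = UNDETERMINED
        timing[event] = verdict
        counts[verdict] += len(nodes)
    focal = timing[events.focal_event]
    scenario = {BEFORE: SCENARIO_II, AFTER: SCENARIO_I, UNDETERMINED: AMBIGUOUS}[focal]
    return TimingResult(
        placement_id=placement.placement_id,
        event_timing=timing,
        n_bef=counts[BEFORE],
        n_aft=counts[AFTER],
        n_und=counts[UNDETERMINED],
        scenario=scenario,
    )


def scenario_counts(
    placements: list[Placement], events: EventModel
) -> dict[str, int]:
    """Histogram of scenarios over a full placement enumeration."""
    hist = Counter(classify_placement(p, events).scenario for p in placements)
    return {SCENARIO_I: hist[SCENARIO_I], SCENARIO_II: hist[SCENARIO_II], AMBIGUOUS: hist[AMBIGUOUS]}


def summarize(
    weights: TopologyWeights,
    timings: list[TimingResult],
    ambiguous_prior: float = 0.5,
    query: str = "",
) -> ScenarioSummary:
    """Probability-weighted scenario summary over all candidate placements.

    Ambiguous placements split their mass ``ambiguous_prior`` to scenario II
    (default one-half, i.e. the two scenarios treated as equally possible),
    and their undetermined node counts likewise.
    """
    if len(weights.weights) != len(timings):
        raise ValueError("weights and timings differ in length")
    w = np.asarray(weights.weights, dtype=float)
    p_ii = n_bef = n_aft = 0.0
    for wt, t in zip(w, timings):
        if t.scenario == SCENARIO_II:
            p_ii += wt
        elif t.scenario == AMBIGUOUS:
            p_ii += ambiguous_prior * wt
        n_bef += wt * (t.n_bef + ambiguous_prior * t.n_und)
        n_aft += wt * (t.n_aft + (1.0 - ambiguous_prior) * t.n_und)
    return ScenarioSummary(
        p_scenario_i=1.0 - p_ii,
        p_scenario_ii=p_ii,
        n_bef=n_bef,
        n_aft=n_aft,
        query=query,
    )


def timings_frame(timings: list[TimingResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "placement_id": t.placement_id,
                "scenario": t.scenario,
                "n_bef": t.n_bef,
                "n_aft": t.n_aft,
                "n_und": t.n_und,
            }
            for t in timings
        ]
    )
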