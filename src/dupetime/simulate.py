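"""Synthetic data emulating the statistical structure of the real analyses.

Two generator families:

* protein alignments evolved along a known (possibly query-grafted) tree
  under the same empirical substitution models the likelihood engine uses,
  giving ground-truth placements for recovery tests of the full
  place-and-time pipeline;
* in-frame coding-sequence sets whose third-position G+C content is tilted
  toward a target GC3 at the synonymous level only (the protein is
  untouched), emulating a genome whose coding GC3 runs far above its
  average GC — with an optional extra within-family codon preference to
  dial codon-usage bias from none (ENc near 61) to maximal (ENc near 20).

All generators are pure functions of their parameters and a seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .codonstats import SYNONYMOUS_FAMILIES
from .kcna import kcna_backbone_spec, kcna_event_model
from .likelihood import AA_ORDER, SubstitutionModel, load_empirical_matrix
from .placements import BackboneSpec, graft
from .seqdata import ROOT_BRANCH, CodingSequenceSet, ProteinAlignment, RootedTree
from .timing import EventModel


# ---------------------------------------------------------------------------
# alignment simulation
# ---------------------------------------------------------------------------

def simulate_alignment(
    tree: RootedTree,
    model: SubstitutionModel,
    n_sites: int,
    seed: int | np.random.Generator,
) -> ProteinAlignment:
    """Evolve an amino-acid alignment along ``tree`` under ``model``.

    Root states are drawn from the stationary frequencies; each site draws
    one rate category (gamma and/or invariant) once and keeps it on every
    branch; states then evolve by the model's transition matrices.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if n_sites < 0:
        raise ValueError("n_sites must be non-negative")
    pi = model.pi
    rates, p_inv = model.category_rates()
    k = len(rates)
    cat = rng.integers(0, k, size=n_sites)
    if p_inv > 0:
        invariant = rng.random(n_sites) < p_inv
    else:
        invariant = np.zeros(n_sites, dtype=bool)
    site_rate = np.where(invariant, 0.0, rates[cat])
    states: dict[str, np.ndarray] = {
        tree.root.name: rng.choice(20, size=n_sites, p=pi)
    }
    left, lam, right = model.spectral()
    for node in tree.preorder():
        if node is tree.root:
            continue
        t = float(node.length) if node.length is not None else 0.0
        parent_states = states[node.parent.name]
        child = parent_states.copy()
        for r in np.unique(site_rate):
            mask = site_rate == r
            if r == 0.0 or t == 0.0:
                continue
            P = np.clip((left * np.exp(lam * r * t)[None, :]) @ right, 0.0, None)
            P = P / P.sum(axis=1, keepdims=True)
            sub = parent_states[mask]
            draw = np.empty(sub.shape, dtype=np.int64)
            for s in np.unique(sub):
                sel = sub == s
                draw[sel] = rng.choice(20, size=int(sel.sum()), p=P[s])
            child[mask] = draw
        states[node.name] = child
    names = tree.leaf_names()
    rows = ["".join(AA_ORDER[i] for i in states[n]) for n in names]
    return ProteinAlignment(names, rows)


# ---------------------------------------------------------------------------
# family simulation with a known placement
# ---------------------------------------------------------------------------

#: default attachment branch for each simulated duplication-timing scenario:
#: II = query orthologous to one cluster gene (cluster duplication predates
#: the split), I = query basal to the whole family (postdates), and the
#: topologically uninformative KCNA4 neighbourhood.
SCENARIO_BRANCHES = {
    "II": "KCNA1",
    "I": ROOT_BRANCH,
    "basal-ambiguous": "KCNA4",
}


@dataclass
class SimulationSpec:
    """Recipe for one simulated gene family with a known true placement."""

    seed: int
    scenario: str = "II"
    n_sites: int = 1000
    query: str = "QUERY"
    arrangement_id: str = "arr_12_36"
    branch_id: str | None = None  # overrides the scenario default
    pendant: float = 0.5
    model: SubstitutionModel = field(default_factory=lambda: SubstitutionModel("JTT", alpha=1.0))
    backbone: BackboneSpec = field(default_factory=kcna_backbone_spec)
    events: EventModel = field(default_factory=kcna_event_model)

    def true_branch(self) -> str:
        if self.branch_id is not None:
            return self.branch_id
        if self.scenario not in SCENARIO_BRANCHES:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        return SCENARIO_BRANCHES[self.scenario]


def simulate_family(spec: SimulationSpec) -> tuple[ProteinAlignment, dict]:
    """Alignment evolved on the query-grafted true tree, plus the truth label."""
    arrangement = spec.backbone.arrangements[spec.arrangement_id]
    branch = spec.true_branch()
    true_tree = graft(arrangement, branch, spec.query, pendant=spec.pendant)
    aln = simulate_alignment(true_tree, spec.model, spec.n_sites, spec.seed)
    truth = {
        "scenario": spec.scenario,
        "arrangement_id": spec.arrangement_id,
        "branch_id": branch,
        "placement_id": f"{spec.arrangement_id}:{branch}",
        "query": spec.query,
    }
    return aln, truth


# ---------------------------------------------------------------------------
# coding-sequence generation with a GC3 target
# ---------------------------------------------------------------------------

def _default_aa_freqs() -> dict[str, float]:
    """JTT stationary frequencies as the canonical amino-acid composition."""
    _, pi = load_empirical_matrix("JTT")
    return dict(zip(AA_ORDER, pi))

def _gc_ending(codon: str) -> bool:
    return codon[2] in "GC"


def _family_probs(w: float, strength: float) -> dict[str, np.ndarray]:
    """Within-family codon probabilities under GC tilt w and preference."""
    probs = {}
    for aa, codons in SYNONYMOUS_FAMILIES.items():
        preferred = next((c for c in codons if _gc_ending(c)), codons[0])
        weight = np.array(
            [
                (w if _gc_ending(c) else 1.0) * (np.exp(strength) if c == preferred else 1.0)
                for c in codons
            ]
        )
        probs[aa] = weight / weight.sum()
    return probs


def _expected_gc3(w: float, aa_freqs: dict[str, float], strength: float) -> float:
    probs = _family_probs(w, strength)
    total = sum(aa_freqs.values())
    e = 0.0
    for aa, codons in SYNONYMOUS_FAMILIES.items():
        p = probs[aa]
        gc_share = sum(pi for pi, c in zip(p, codons) if _gc_ending(c))
        e += (aa_freqs[aa] / total) * gc_share
    return e


def solve_gc3_tilt(
    gc3_target: float, aa_freqs: dict[str, float], strength: float = 0.0
) -> float:
    """GC-ending codon weight w whose expected GC3 equals the target.

    The expectation is monotone in w; targets outside the attainable range
    (bounded below by the Met+Trp share, whose codons end in G) are clamped
    with a warning.
    """
    if not 0.0 < gc3_target < 1.0:
        raise ValueError("gc3_target must lie in (0, 1)")
    lo, hi = np.exp(-25.0), np.exp(25.0)
    f_lo = _expected_gc3(lo, aa_freqs, strength)
    f_hi = _expected_gc3(hi, aa_freqs, strength)
    if gc3_target <= f_lo:
        warnings.warn(f"gc3_target {gc3_target} below attainable {f_lo:.3f}; clamped")
        return lo
    if gc3_target >= f_hi:
        warnings.warn(f"gc3_target {gc3_target} above attainable {f_hi:.3f}; clamped")
        return hi
    log_w = brentq(
        lambda lw: _expected_gc3(np.exp(lw), aa_freqs, strength) - gc3_target,
        -25.0,
        25.0,
    )
    return float(np.exp(log_w))


def neutral_gc3(aa_freqs: dict[str, float] | None = None) -> float:
    """Expected GC3 when every synonymous codon is used uniformly (w=1)."""
    return _expected_gc3(1.0, aa_freqs or _default_aa_freqs(), 0.0)


def generate_coding_set(
    n_genes: int,
    length: int,
    gc3_target: float | list[float],
    preference_strength: float = 0.0,
    seed: int | np.random.Generator = 0,
    aa_freqs: dict[str, float] | None = None,
    name_prefix: str = "gene",
) -> CodingSequenceSet:
    """In-frame CDS set with synonymous choices tilted toward a GC3 target.

    Amino acids are drawn i.i.d. from ``aa_freqs`` (default: the JTT
    stationary composition); within each synonymous family codons are drawn
    with a deterministic G/C-third-position tilt solved so the expected GC3
    matches the target. ``preference_strength`` adds extra weight on one
    preferred codon per family (0 = none; large values drive ENc toward 20).
    ``gc3_target`` may be a scalar or one value per gene.
    """
    if length % 3 != 0:
        raise ValueError("length must be a multiple of three")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    aa_freqs = aa_freqs or _default_aa_freqs()
    targets = np.broadcast_to(np.asarray(gc3_target, dtype=float), (n_genes,))
    aas = list(aa_freqs)
    aa_p = np.array([aa_freqs[a] for a in aas])
    aa_p = aa_p / aa_p.sum()
    n_codons = length // 3
    names, seqs = [], []
    tilt_cache: dict[float, dict[str, np.ndarray]] = {}
    for g in range(n_genes):
        t = float(targets[g])
        if t not in tilt_cache:
            w = solve_gc3_tilt(t, aa_freqs, preference_strength)
            tilt_cache[t] = _family_probs(w, preference_strength)
        probs = tilt_cache[t]
        aa_seq = rng.choice(len(aas), size=n_codons, p=aa_p)
        codons = np.empty(n_codons, dtype=object)
        for i in np.unique(aa_seq):
            aa = aas[i]
            family = SYNONYMOUS_FAMILIES[aa]
            mask = aa_seq == i
            picks = rng.choice(len(family), size=int(mask.sum()), p=probs[aa])
            codons[mask] = np.array(family, dtype=object)[picks]
        names.append(f"{name_prefix}{g + 1}")
        seqs.append("".join(codons))
    return CodingSequenceSet(names, seqs)
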