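"""End-to-end orchestration of the two analysis tracks.

``place_and_time`` runs the duplication-timing track: enumerate candidate
attachments of one query gene on the constrained backbone, score every
topology by maximum likelihood, convert log-likelihoods to topology
probabilities, and fold them through the event-timing rule into a scenario
summary (P(I), P(II), N_bef, N_aft).

``composition`` runs the sequence-property track: per-gene GC/GC3/ENc,
the RSCU table, and a CA or within-group CA ordination with its
first-axis-vs-GC3 correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .codonstats import codon_counts, enc_table, expected_enc, gc3, rscu
from .likelihood import (
    SubstitutionModel,
    TreeLikelihood,
    estimate_alpha,
    optimize_branch_lengths,
)
from .ordination import CAResult, axis_gc_correlation, ca, ca_rscu, wca
from .placements import BackboneSpec, Placement, enumerate_placements
from .seqdata import CodingSequenceSet, ProteinAlignment
from .timing import (
    EventModel,
    ScenarioSummary,
    TimingResult,
    classify_placement,
    summarize,
    timings_frame,
)
from .weights import TopologyWeights, attach_kh, likelihood_weights, rell_weights


@dataclass
class PlacementAnalysis:
    """Everything the duplication-timing track computes for one query gene."""

    query: str
    placements: list[Placement]
    site_lnl: np.ndarray  # (sites, placements)
    weights: TopologyWeights
    timings: list[TimingResult]
    summary: ScenarioSummary
    model: SubstitutionModel

    def placement_table(self) -> pd.DataFrame:
        df = self.weights.to_frame().merge(
            timings_frame(self.timings), on="placement_id"
        )
        df.insert(1, "arrangement_id", [p.arrangement_id for p in self.placements])
        df.insert(2, "branch_id", [p.branch_id for p in self.placements])
        return df


def place_and_time(
    aln: ProteinAlignment,
    backbone: BackboneSpec,
    events: EventModel,
    model: SubstitutionModel | None = None,
    weight_method: str = "lw",
    rell_replicates: int = 10_000,
    seed: int | None = None,
    optimize: str = "full",
    pendant: float = 0.1,
    fit_alpha: bool = False,
    max_rounds: int = 20,
    xtol: float = 1e-4,
    out_dir: str | Path | None = None,
) -> PlacementAnalysis:
    """Run the full placement-enumeration / likelihood / timing pipeline.

    The alignment must contain every backbone taxon plus exactly one extra
    sequence, taken as the query. ``optimize`` is ``"full"`` (every branch
    of every candidate topology, the default) or ``"attachment"`` (backbone
    branch lengths fitted once per arrangement on the query-less alignment,
    then only the three branches created by each graft re-optimized —
    evolutionary-placement style, much faster and nearly as accurate when
    the backbone is well resolved). ``fit_alpha`` estimates the gamma shape
    once on the first arrangement's backbone and holds it fixed across all
    candidate placements.
    """
    model = model or SubstitutionModel("JTT", alpha=1.0)
    backbone_leaves = set(backbone.leaf_names)
    extra = [n for n in aln.names if n not in backbone_leaves]
    missing = backbone_leaves - set(aln.names)
    if missing:
        raise ValueError(f"backbone taxa missing from alignment: {sorted(missing)}")
    if len(extra) != 1:
        raise ValueError(
            f"alignment must contain exactly one query; found {len(extra)}: {extra}"
        )
    query = extra[0]
    for arrangement in backbone.arrangements.values():
        events.validate(arrangement)

    backbone_aln = aln.subset(sorted(backbone_leaves))
    if fit_alpha:
        first = next(iter(backbone.arrangements.values()))
        model = replace(model, alpha=estimate_alpha(backbone_aln, first, model))

    if optimize == "attachment":
        fitted = {
            arr_id: optimize_branch_lengths(
                backbone_aln, tree, model, max_rounds=max_rounds, xtol=xtol
            )[0]
            for arr_id, tree in backbone.arrangements.items()
        }
        working = BackboneSpec(fitted)
    elif optimize == "full":
        working = backbone
    else:
        raise ValueError("optimize must be 'full' or 'attachment'")

    placements = enumerate_placements(working, query, pendant=pendant)
    site_cols = []
    for placement in placements:
        engine = TreeLikelihood(placement.tree, aln, model)
        if optimize == "attachment":
            # the three branches the graft creates or splits: the pendant,
            # the bisected halves (graft node's branch + its non-query child)
            graft_node = placement.tree.node(placement.graft_node)
            touched = {c.name for c in graft_node.children}
            if graft_node.parent is not None:
                touched.add(graft_node.name)
            engine.optimize_branch_lengths(
                max_rounds=max_rounds, xtol=xtol, branches=touched
            )
        else:
            engine.optimize_branch_lengths(max_rounds=max_rounds, xtol=xtol)
        site_cols.append(engine.site_log_likelihoods().per_site)
    site_lnl = np.column_stack(site_cols)

    ids = [p.placement_id for p in placements]
    if weight_method == "lw":
        w = likelihood_weights(site_lnl.sum(axis=0), placement_ids=ids)
    elif weight_method == "rell":
        w = rell_weights(site_lnl, replicates=rell_replicates, seed=seed, placement_ids=ids)
    else:
        raise ValueError("weight_method must be 'lw' or 'rell'")
    attach_kh(w, site_lnl)

    timings = [classify_placement(p, events) for p in placements]
    summary = summarize(w, timings, query=query)
    analysis = PlacementAnalysis(
        query=query,
        placements=placements,
        site_lnl=site_lnl,
        weights=w,
        timings=timings,
        summary=summary,
        model=model,
    )
    if out_dir is not None:
        _write_placement_outputs(analysis, Path(out_dir), weight_method, seed)
    return analysis


def _write_placement_outputs(
    analysis: PlacementAnalysis, out_dir: Path, weight_method: str, seed
) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    analysis.placement_table().to_csv(out_dir / "placements.tsv", sep="\t", index=False)
    analysis.summary.to_frame().to_csv(out_dir / "summary.tsv", sep="\t", index=False)
    with open(out_dir / "placements.nwk", "w") as fh:
        for p in analysis.placements:
            fh.write(p.tree.newick() + "\n")
    pd.DataFrame(
        {
            "placement_id": [p.placement_id for p in analysis.placements],
            "arrangement_id": [p.arrangement_id for p in analysis.placements],
            "branch_id": [p.branch_id for p in analysis.placements],
        }
    ).to_csv(out_dir / "placements_index.tsv", sep="\t", index=False)
    np.savetxt(
        out_dir / "site_loglik.tsv",
        analysis.site_lnl,
        delimiter="\t",
        header="\t".join(p.placement_id for p in analysis.placements),
        comments="",
    )
    config = {
        "query": analysis.query,
        "model": {
            "matrix": analysis.model.matrix_name,
            "alpha": analysis.model.alpha,
            "n_categories": analysis.model.n_categories,
            "p_inv": analysis.model.p_inv,
        },
        "weight_method": weight_method,
        "seed": seed,
    }
    with open(out_dir / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh)


@dataclass
class CompositionAnalysis:
    """Per-row statistics and ordination of one coding-sequence dataset."""

    stats: pd.DataFrame       # rows x (n_codons, GC, GC3, ENc, ENc_expected)
    rscu_table: pd.DataFrame  # rows x 59
    ordination: CAResult | None
    axis1_gc3_r: float | None
    axis1_gc3_r2: float | None
    mode: str


def species_codon_counts(species: dict[str, CodingSequenceSet]) -> pd.DataFrame:
    """Species x 59 codon counts, each species on its concatenated CDS."""
    rows = {
        name: codon_counts(cds, by="dataset").iloc[0] for name, cds in species.items()
    }
    return pd.DataFrame(rows).T


def composition(
    data: CodingSequenceSet | dict[str, CodingSequenceSet],
    mode: str = "wca",
    min_aa: int | None = None,
    out_dir: str | Path | None = None,
) -> CompositionAnalysis:
    """Composition statistics plus ordination for genes or species.

    ``data`` is either one coding-sequence set (rows = genes) or a mapping
    species -> set (rows = species, each concatenated). ``mode`` selects
    the ordination: ``"wca"`` (within-group CA of codon counts, default),
    ``"ca"`` (plain CA of codon counts) or ``"ca-rscu"``. Ordination is
    skipped, with a warning, when fewer than two rows or no variation
    remain.
    """
    if isinstance(data, CodingSequenceSet):
        if min_aa is not None:
            data = data.filter_min_length(min_aa)
        counts = codon_counts(data, by="gene")
        stats = enc_table(data, aggregate="gene")
        gc3_values = gc3(data)
    else:
        if min_aa is not None:
            data = {k: v.filter_min_length(min_aa) for k, v in data.items()}
        counts = species_codon_counts(data)
        pooled = {
            name: CodingSequenceSet([name], ["".join(cds.sequences)])
            for name, cds in data.items()
        }
        stats = pd.concat(
            [enc_table(cds, aggregate="gene") for cds in pooled.values()]
        )
        gc3_values = pd.Series(
            {name: gc3(cds).iloc[0] for name, cds in pooled.items()}, name="GC3"
        )
    stats = stats.assign(ENc_expected=expected_enc(stats["GC3"].to_numpy()))

    result = None
    r = r2 = None
    if len(counts) < 2:
        warnings.warn("fewer than two rows; ordination skipped")
    else:
        run = {"wca": wca, "ca": ca, "ca-rscu": ca_rscu}.get(mode)
        if run is None:
            raise ValueError("mode must be 'wca', 'ca' or 'ca-rscu'")
        result = run(counts)
        if result.total_inertia <= 1e-12 or result.n_axes == 0:
            warnings.warn("no variation across rows; ordination has zero inertia")
            result = None
        else:
            r, r2 = axis_gc_correlation(result, gc3_values)

    analysis = CompositionAnalysis(
        stats=stats,
        rscu_table=rscu(counts),
        ordination=result,
        axis1_gc3_r=r,
        axis1_gc3_r2=r2,
        mode=mode,
    )
    if out_dir is not None:
        _write_composition_outputs(analysis, Path(out_dir))
    return analysis


def _write_composition_outputs(analysis: CompositionAnalysis, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    analysis.stats.rename_axis("row").to_csv(out_dir / "stats.tsv", sep="\t")
    analysis.rscu_table.rename_axis("row").to_csv(out_dir / "rscu.tsv", sep="\t")
    if analysis.ordination is not None:
        o = analysis.ordination
        o.row_coords.rename_axis("row").to_csv(out_dir / "row_coords.tsv", sep="\t")
        o.col_coords.rename_axis("column").to_csv(out_dir / "col_coords.tsv", sep="\t")
        pd.DataFrame(
            {
                "axis": np.arange(1, o.n_axes + 1),
                "inertia": o.eigenvalues,
                "fraction": o.inertia_fractions,
            }
        ).to_csv(out_dir / "eigenvalues.tsv", sep="\t", index=False)
        pd.DataFrame(
            [{"axis": 1, "pearson_r": analysis.axis1_gc3_r, "r2": analysis.axis1_gc3_r2}]
        ).to_csv(out_dir / "axis_gc3_correlation.tsv", sep="\t", index=False)
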