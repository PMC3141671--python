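"""Coding-sequence composition statistics: GC, GC3, codon counts, RSCU,
Wright's effective number of codons (ENc) and amino-acid composition.

ENc measures how far a gene departs from uniform synonymous codon usage:
20 means one codon per amino acid (maximal bias), 61 means all sense
codons used evenly. Wright's null expectation under mutation pressure
alone, ENc = 2 + s + 29/(s^2 + (1-s)^2) with s the third-position G+C
fraction, is the reference curve for GC-driven bias.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .seqdata import CodingSequenceSet, ProteinAlignment

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = set(_STANDARD.stop_codons)

#: amino acid -> synonymous codons (sense codons, standard code)
SYNONYMOUS_FAMILIES: dict[str, list[str]] = {}
for codon, aa in sorted(_STANDARD.forward_table.items()):
    SYNONYMOUS_FAMILIES.setdefault(aa, []).append(codon)

#: the 59 synonymous codons: 61 sense codons minus Met (ATG) and Trp (TGG)
CODONS_59: list[str] = sorted(
    c for aa, codons in SYNONYMOUS_FAMILIES.items() if len(codons) > 1 for c in codons
)
CODON_TO_AA = {c: aa for aa, cs in SYNONYMOUS_FAMILIES.items() for c in cs}

#: degeneracy classes of Wright's estimator: {class size: number of amino acids}
DEGENERACY_CLASSES = {2: 9, 3: 1, 4: 5, 6: 3}


# ---------------------------------------------------------------------------
# codon counting
# ---------------------------------------------------------------------------

def codon_counts(cds: CodingSequenceSet, by: str = "gene") -> pd.DataFrame:
    """Counts of the 59 synonymous codons per gene (or one pooled row).

    Stop codons, codons containing N, and the non-degenerate ATG/TGG are
    excluded. ``by="dataset"`` concatenates all genes into a single row
    named ``"dataset"`` (species-level usage is conventionally computed on
    the concatenated coding sequence).
    """
    col = {c: i for i, c in enumerate(CODONS_59)}
    rows = []
    for name in cds.names:
        v = np.zeros(len(CODONS_59))
        for codon in cds.codons(name):
            i = col.get(codon)
            if i is not None:
                v[i] += 1
        rows.append(v)
    df = pd.DataFrame(rows, index=cds.names, columns=CODONS_59)
    if by == "dataset":
        df = df.sum(axis=0).to_frame(name="dataset").T
    elif by != "gene":
        raise ValueError("by must be 'gene' or 'dataset'")
    return df


def _third_positions(seq: str):
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        if "N" not in codon:
            yield codon[2]


def gc3(cds: CodingSequenceSet) -> pd.Series:
    """Per-gene fraction of G+C at third codon positions (codons with N skipped)."""
    out = {}
    for name, seq in zip(cds.names, cds.sequences):
        thirds = list(_third_positions(seq))
        out[name] = (
            sum(ch in "GC" for ch in thirds) / len(thirds) if thirds else np.nan
        )
    return pd.Series(out, name="GC3")


def gc(cds: CodingSequenceSet) -> pd.Series:
    """Per-gene overall G+C fraction (N excluded from the denominator)."""
    out = {}
    for name, seq in zip(cds.names, cds.sequences):
        counted = [ch for ch in seq if ch != "N"]
        out[name] = (
            sum(ch in "GC" for ch in counted) / len(counted) if counted else np.nan
        )
    return pd.Series(out, name="GC")


# ---------------------------------------------------------------------------
# effective number of codons
# ---------------------------------------------------------------------------

def _family_homozygosity(counts: np.ndarray) -> float | None:
    """F-hat of one synonymous family; None when fewer than two codons observed."""
    n = counts.sum()
    if n < 2:
        return None
    p = counts / n
    return (n * float(p @ p) - 1.0) / (n - 1.0)


def enc(counts) -> float:
    """Wright's effective number of codons for one row of codon counts.

    Average homozygosities are formed per degeneracy class (2-, 3-, 4- and
    6-fold; Ile kept 3-fold, Leu/Ser/Arg kept 6-fold). A missing 3-fold
    class is imputed as (F2+F4)/2; any other missing class contributes its
    amino acids scaled by the mean codons-per-amino-acid of the observed
    classes. Fewer than two observed classes yields NaN. The result is
    clamped to [20, 61].
    """
    row = pd.Series(counts, index=CODONS_59) if not isinstance(counts, pd.Series) else counts
    f_by_class: dict[int, list[float]] = {k: [] for k in DEGENERACY_CLASSES}
    for aa, codons in SYNONYMOUS_FAMILIES.items():
        if len(codons) < 2:
            continue
        f = _family_homozygosity(row[codons].to_numpy(dtype=float))
        if f is not None and f > 0:  # F=0 families carry no usable signal
            f_by_class[len(codons)].append(f)
    f_bar = {k: float(np.mean(v)) for k, v in f_by_class.items() if v}
    if len(f_bar) < 2:
        return float("nan")
    # rescale base uses only genuinely observed classes
    observed = [(k, f_bar[k]) for k in DEGENERACY_CLASSES if k in f_bar]
    per_aa = sum(DEGENERACY_CLASSES[k] / f for k, f in observed) / sum(
        DEGENERACY_CLASSES[k] for k, _ in observed
    )
    if 3 not in f_bar and 2 in f_bar and 4 in f_bar:
        f_bar[3] = (f_bar[2] + f_bar[4]) / 2.0
    total = 2.0  # Met and Trp always contribute one codon each
    for k, n_aa in DEGENERACY_CLASSES.items():
        if k in f_bar:
            if f_bar[k] <= 0:
                return float("nan")
            total += n_aa / f_bar[k]
        else:
            total += n_aa * per_aa
    return float(np.clip(total, 20.0, 61.0))


def enc_table(cds: CodingSequenceSet, aggregate: str = "gene") -> pd.DataFrame:
    """Per-gene (or pooled) ENc with GC3 and GC.

    ``aggregate="concat"`` reports a single row computed on the
    concatenation of all genes; ``"mean"`` averages per-gene values.
    """
    per_gene = pd.DataFrame(
        {
            "n_codons": codon_counts(cds).sum(axis=1),
            "GC": gc(cds),
            "GC3": gc3(cds),
            "ENc": codon_counts(cds).apply(enc, axis=1),
        }
    )
    if aggregate == "gene":
        return per_gene
    if aggregate == "mean":
        return per_gene.mean(axis=0).to_frame(name="mean").T
    if aggregate == "concat":
        pooled = CodingSequenceSet(["dataset"], ["".join(cds.sequences)])
        return enc_table(pooled, aggregate="gene")
    raise ValueError("aggregate must be 'gene', 'mean' or 'concat'")


def expected_enc(s) -> np.ndarray | float:
    """Wright's null ENc-GC3 curve: 2 + s + 29/(s^2 + (1-s)^2)."""
    s = np.asarray(s, dtype=float)
    out = 2.0 + s + 29.0 / (s**2 + (1.0 - s) ** 2)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# RSCU and amino-acid composition
# ---------------------------------------------------------------------------

def rscu(counts) -> pd.DataFrame | pd.Series:
    """Relative synonymous codon usage: count over within-family mean.

    Accepts a (rows x 59) count table or a single row. Families entirely
    absent from a row get NaN for their codons; an observed k-fold family's
    RSCU values sum to k.
    """
    if isinstance(counts, pd.Series):
        return rscu(counts.to_frame().T).iloc[0]
    df = counts.astype(float).copy()
    out = pd.DataFrame(np.nan, index=df.index, columns=df.columns)
    for aa, codons in SYNONYMOUS_FAMILIES.items():
        cols = [c for c in codons if c in df.columns]
        if len(cols) < 2:
            continue
        family = df[cols]
        mean = family.mean(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[cols] = family.div(mean, axis=0)
        out.loc[mean == 0, cols] = np.nan
    return out


def aa_composition(seqs: ProteinAlignment | list[str]) -> pd.Series:
    """Frequencies of the 20 amino acids over a protein set (X and gaps ignored).

    Sequences are pooled (concatenated) before counting, so the result is
    order-invariant; frequencies sum to one.
    """
    rows = seqs.rows if isinstance(seqs, ProteinAlignment) else list(seqs)
    if not rows:
        raise ValueError("empty protein set")
    aas = sorted(SYNONYMOUS_FAMILIES)
    counts = dict.fromkeys(aas, 0)
    for row in rows:
        for ch in row.upper():
            if ch in counts:
                counts[ch] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no canonical residues present")
    return pd.Series({aa: counts[aa] / total for aa in aas}, name="frequency")


def composition_table(sets: dict[str, list[str]]) -> pd.DataFrame:
    """Species/gene x 20 amino-acid frequency table for correspondence analysis."""
    return pd.DataFrame({name: aa_composition(rows) for name, rows in sets.items()}).T
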