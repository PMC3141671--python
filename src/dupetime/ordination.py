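"""Correspondence analysis (CA) and within-group CA (WCA) of count tables.

CA decomposes the chi-square structure of a non-negative table: with
P = X/n, row masses r and column masses c, the standardized residual
matrix S = D_r^{-1/2} (P - r c^T) D_c^{-1/2} is factored by SVD; squared
singular values are the principal inertias and sum to chi^2/n.

WCA removes between-amino-acid structure from a codon-count table before
ordination: each cell is replaced by its deviation from the expectation
given the row's family total and the table-wide within-family codon
profile, keeping the original row and column masses. Only synonymous-
choice variation then remains — rows with identical within-family codon
proportions have zero within-group inertia regardless of their amino-acid
composition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .codonstats import CODON_TO_AA, rscu

_TOL = 1e-12


@dataclass
class CAResult:
    """Factor coordinates and inertia decomposition of one analysis."""

    row_coords: pd.DataFrame
    col_coords: pd.DataFrame
    eigenvalues: np.ndarray
    inertia_fractions: np.ndarray
    total_inertia: float

    @property
    def n_axes(self) -> int:
        return len(self.eigenvalues)


def _clean(table: pd.DataFrame) -> pd.DataFrame:
    df = pd.DataFrame(table).astype(float)
    if (df.to_numpy() < 0).any():
        raise ValueError("correspondence analysis needs a non-negative table")
    zero_rows = df.index[df.sum(axis=1) == 0]
    zero_cols = df.columns[df.sum(axis=0) == 0]
    if len(zero_rows) or len(zero_cols):
        warnings.warn(
            f"dropping {len(zero_rows)} all-zero row(s) and "
            f"{len(zero_cols)} all-zero column(s)"
        )
        df = df.drop(index=zero_rows, columns=zero_cols)
    if df.empty:
        raise ValueError("table is empty after dropping zero margins")
    return df


def _decompose(
    residual: np.ndarray, r: np.ndarray, c: np.ndarray, index, columns
) -> CAResult:
    """SVD of a standardized residual matrix into principal coordinates."""
    U, s, Vt = np.linalg.svd(residual, full_matrices=False)
    max_axes = min(residual.shape) - 1 if min(residual.shape) > 1 else 1
    keep = np.where(s > np.sqrt(_TOL))[0][: max(max_axes, 0)]
    s = s[keep]
    U = U[:, keep]
    V = Vt[keep].T
    # sign convention: first nonzero column loading positive
    for a in range(len(s)):
        col = V[:, a]
        nz = np.nonzero(np.abs(col) > _TOL)[0]
        if nz.size and col[nz[0]] < 0:
            V[:, a] *= -1
            U[:, a] *= -1
    row = (U * s[None, :]) / np.sqrt(r)[:, None]
    col = (V * s[None, :]) / np.sqrt(c)[:, None]
    eig = s**2
    total = float(eig.sum())
    axes = [f"axis{i + 1}" for i in range(len(s))]
    return CAResult(
        row_coords=pd.DataFrame(row, index=index, columns=axes),
        col_coords=pd.DataFrame(col, index=columns, columns=axes),
        eigenvalues=eig,
        inertia_fractions=eig / total if total > 0 else eig,
        total_inertia=total,
    )


def ca(table: pd.DataFrame) -> CAResult:
    """Correspondence analysis of a non-negative table.

    A rank-deficient table (all row profiles equal) yields zero axes and
    total inertia 0.
    """
    df = _clean(table)
    X = df.to_numpy()
    n = X.sum()
    P = X / n
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    return _decompose(S, r, c, df.index, df.columns)


def wca(table: pd.DataFrame, groups: dict[str, str] | None = None) -> CAResult:
    """Within-group CA of a codon-count table.

    ``groups`` maps each column (codon) to its group (amino acid); the
    default is the standard-code synonymous-family partition. Each cell
    x_gc is centred to x_gc - T_ga * m_{c|a} where T_ga is the row's family
    total and m_{c|a} the global within-family profile; row/column masses
    of the original table are retained. Families absent from every row are
    dropped.
    """
    df = _clean(table)
    groups = groups or {c: CODON_TO_AA[c] for c in df.columns}
    missing = [c for c in df.columns if c not in groups]
    if missing:
        raise ValueError(f"columns without a group: {missing}")
    X = df.to_numpy()
    n = X.sum()
    P = X / n
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    Y = np.empty_like(X, dtype=float)
    cols = list(df.columns)
    for group in sorted(set(groups[c_] for c_ in cols)):
        j = [i for i, c_ in enumerate(cols) if groups[c_] == group]
        sub = X[:, j]
        profile = sub.sum(axis=0) / sub.sum()
        Y[:, j] = sub - np.outer(sub.sum(axis=1), profile)
    S = (Y / n) / np.sqrt(np.outer(r, c))
    return _decompose(S, r, c, df.index, df.columns)


def ca_rscu(counts: pd.DataFrame) -> CAResult:
    """CA of the relative-synonymous-codon-usage matrix (NaN families -> 0)."""
    table = rscu(counts).fillna(0.0)
    return ca(table)


def axis_gc_correlation(result: CAResult, gc_values: pd.Series, axis: int = 1):
    """Pearson correlation of one row-coordinate axis with per-row GC values.

    Axis sign is arbitrary, so |r| is the stable quantity; r and r^2 are
    returned. A constant input is flagged with a warning and yields NaN.
    """
    coords = result.row_coords[f"axis{axis}"]
    g = pd.Series(gc_values).reindex(coords.index)
    if g.isna().any():
        raise ValueError("GC values missing for some rows")
    if np.ptp(g.to_numpy()) < _TOL or np.ptp(coords.to_numpy()) < _TOL:
        warnings.warn("correlation undefined for a constant vector")
        return float("nan"), float("nan")
    r, _ = stats.pearsonr(coords.to_numpy(), g.to_numpy())
    return float(r), float(r**2)
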