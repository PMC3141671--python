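import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency, spearmanr

import dupetime as dt
from dupetime.codonstats import CODONS_59, SYNONYMOUS_FAMILIES


def random_count_table(rng, rows=6, cols=8):
    return pd.DataFrame(
        rng.integers(1, 60, size=(rows, cols)).astype(float),
        index=[f"r{i}" for i in range(rows)],
        columns=[f"c{j}" for j in range(cols)],
    )


class TestCA:
    def test_identical_row_profiles_zero_inertia(self):
        table = pd.DataFrame([[2.0, 4.0, 6.0], [1.0, 2.0, 3.0]])
        res = dt.ca(table)
        assert res.total_inertia == pytest.approx(0.0, abs=1e-12)
        assert res.n_axes == 0

    def test_two_by_two_hand_computation(self):
        # chi2 = 2, n = 8 -> total inertia 0.25, single axis carries all of it
        res = dt.ca(pd.DataFrame([[3.0, 1.0], [1.0, 3.0]]))
        assert res.total_inertia == pytest.approx(0.25)
        assert res.n_axes == 1
        assert res.inertia_fractions[0] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_total_inertia_equals_chi2_over_n(self, seed):
        rng = np.random.default_rng(seed)
        table = random_count_table(rng)
        res = dt.ca(table)
        chi2 = chi2_contingency(table.to_numpy(), correction=False)[0]
        assert res.total_inertia == pytest.approx(chi2 / table.to_numpy().sum())

    def test_symmetric_table_symmetric_coordinates(self):
        table = pd.DataFrame([[5.0, 1.0], [1.0, 5.0]])
        res = dt.ca(table)
        assert np.allclose(
            np.abs(res.row_coords.to_numpy()), np.abs(res.col_coords.to_numpy())
        )

    def test_eigenvalues_non_increasing_fractions_sum_to_one(self):
        rng = np.random.default_rng(3)
        res = dt.ca(random_count_table(rng, rows=5, cols=7))
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)
        assert res.inertia_fractions.sum() == pytest.approx(1.0)
        assert res.n_axes <= min(5, 7) - 1

    def test_zero_margins_dropped_with_warning(self):
        table = pd.DataFrame([[2.0, 0.0, 3.0], [4.0, 0.0, 1.0], [0.0, 0.0, 0.0]])
        with pytest.warns(UserWarning, match="dropping"):
            res = dt.ca(table)
        assert res.row_coords.shape[0] == 2

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            dt.ca(pd.DataFrame([[1.0, -1.0]]))


def codon_table_from_profiles(aa_totals: pd.DataFrame, profiles) -> pd.DataFrame:
    """Rows x 59 counts with per-row amino-acid totals and codon profiles."""
    out = pd.DataFrame(0.0, index=aa_totals.index, columns=CODONS_59)
    for aa, codons in SYNONYMOUS_FAMILIES.items():
        if len(codons) < 2 or aa not in aa_totals.columns:
            continue
        for row in aa_totals.index:
            p = profiles(row, aa, codons)
            out.loc[row, codons] = aa_totals.loc[row, aa] * np.asarray(p)
    return out


class TestWCA:
    def test_row_invariant_codon_profiles_zero_within_inertia(self):
        # different amino-acid compositions, identical within-family usage
        rng = np.random.default_rng(10)
        aas = [a for a, c in SYNONYMOUS_FAMILIES.items() if len(c) > 1]
        totals = pd.DataFrame(
            rng.integers(10, 200, size=(4, len(aas))).astype(float),
            index=list("wxyz"),
            columns=aas,
        )
        shared = {
            aa: rng.dirichlet(np.ones(len(SYNONYMOUS_FAMILIES[aa])))
            for aa in aas
        }
        table = codon_table_from_profiles(totals, lambda r, aa, c: shared[aa])
        res = dt.wca(table)
        assert res.total_inertia == pytest.approx(0.0, abs=1e-12)
        # while plain CA still sees the amino-acid differences
        assert dt.ca(table).total_inertia > 1e-4

    def test_single_family_reduces_to_ca(self):
        rng = np.random.default_rng(11)
        leu = SYNONYMOUS_FAMILIES["L"]
        table = pd.DataFrame(
            rng.integers(1, 40, size=(5, 6)).astype(float),
            index=[f"g{i}" for i in range(5)],
            columns=leu,
        )
        w = dt.wca(table, groups={c: "L" for c in leu})
        c = dt.ca(table)
        assert w.total_inertia == pytest.approx(c.total_inertia)
        assert np.allclose(np.abs(w.row_coords), np.abs(c.row_coords))

    def test_two_row_gc_preference_single_axis(self):
        def profile(row, aa, codons):
            gc = np.array([c[2] in "GC" for c in codons], dtype=float)
            pref = gc if row == "gc_lover" else 1 - gc
            if pref.sum() == 0:
                pref = np.ones(len(codons))
            return pref / pref.sum()

        totals = pd.DataFrame(
            50.0,
            index=["gc_lover", "at_lover"],
            columns=[a for a, c in SYNONYMOUS_FAMILIES.items() if len(c) > 1],
        )
        table = codon_table_from_profiles(totals, profile)
        res = dt.wca(table)
        assert res.n_axes == 1
        assert res.inertia_fractions[0] == pytest.approx(1.0)
        signs = np.sign(res.row_coords["axis1"].to_numpy())
        assert signs[0] * signs[1] == -1

    @pytest.mark.parametrize("seed", [0, 1])
    def test_within_inertia_bounded_by_total(self, seed):
        rng = np.random.default_rng(seed)
        table = pd.DataFrame(
            rng.integers(0, 50, size=(6, 59)).astype(float),
            index=[f"g{i}" for i in range(6)],
            columns=CODONS_59,
        )
        assert dt.wca(table).total_inertia <= dt.ca(table).total_inertia + 1e-12

    def test_ca_rscu_runs_and_orders_like_wca(self):
        rng = np.random.default_rng(12)
        gc3_targets = np.linspace(0.35, 0.85, 6)
        counts = {}
        for i, t in enumerate(gc3_targets):
            cds = dt.generate_coding_set(8, 300, t, seed=rng)
            counts[f"sp{i}"] = dt.codon_counts(cds, by="dataset").iloc[0]
        table = pd.DataFrame(counts).T
        res = dt.ca_rscu(table)
        rho = spearmanr(res.row_coords["axis1"], gc3_targets)[0]
        assert abs(rho) >= 0.9


class TestAxisGCCorrelation:
    def test_proportional_coordinates_r2_one(self):
        rng = np.random.default_rng(13)
        gc3_targets = np.linspace(0.3, 0.9, 8)
        rows = {}
        for i, t in enumerate(gc3_targets):
            cds = dt.generate_coding_set(5, 300, t, seed=int(100 + i))
            rows[f"s{i}"] = dt.codon_counts(cds, by="dataset").iloc[0]
        res = dt.wca(pd.DataFrame(rows).T)
        fake_gc = pd.Series(
            res.row_coords["axis1"] * 2.0 + 0.5, index=res.row_coords.index
        )
        r, r2 = dt.axis_gc_correlation(res, fake_gc)
        assert r2 == pytest.approx(1.0)

    def test_independent_vectors_rarely_correlate(self):
        rng = np.random.default_rng(14)
        hits = 0
        reps = 40
        for _ in range(reps):
            x = rng.normal(size=100)
            y = rng.normal(size=100)
            r = np.corrcoef(x, y)[0, 1]
            hits += abs(r) < 0.3
        assert hits / reps >= 0.95

    def test_constant_vector_flagged(self):
        table = pd.DataFrame([[3.0, 1.0], [1.0, 3.0]], index=["a", "b"])
        res = dt.ca(table)
        with pytest.warns(UserWarning, match="constant"):
            r, r2 = dt.axis_gc_correlation(res, pd.Series([0.5, 0.5], index=["a", "b"]))
        assert np.isnan(r)
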