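"""Panel loading, imputation, scoring and quantile stratification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from afgrs import (
    AF9_KEEP,
    GenotypeMatrix,
    GrsVector,
    PanelError,
    assign_quantiles,
    compute_grs,
    impute_missing,
    load_panel,
    subset_one_per_gene,
)
from afgrs.panel import PANEL_COLUMNS


def gm(dosage, rsids, ids=None):
    dosage = np.asarray(dosage, dtype=float)
    ids = ids or [f"p{i}" for i in range(dosage.shape[0])]
    return GenotypeMatrix(ids, rsids, dosage)


class TestLoadPanel:
    def test_builtin_af12_matches_published_weights(self, panel12):
        assert len(panel12) == 12
        assert panel12.weight("rs2200733") == 0.54
        assert panel12.weight("rs17570669") == -0.31
        assert sum(w < 0 for w in panel12.weights) == 4
        lo, hi = panel12.score_bounds()
        assert lo == pytest.approx(-1.42)
        assert hi == pytest.approx(3.46)

    def test_builtin_af9_is_one_per_gene_with_rs2200733(self, panel9, panel12):
        assert len(panel9) == 9
        assert len(set(panel9.genes)) == 9
        pitx2 = [r for r, g in zip(panel9.rsids, panel9.genes) if g == "PITX2"]
        assert pitx2 == ["rs2200733"]
        # weights carried over unchanged
        for rsid in panel9.rsids:
            assert panel9.weight(rsid) == panel12.weight(rsid)

    def test_file_round_trip(self, panel12, tmp_path):
        path = tmp_path / "panel.csv"
        panel12.table.to_csv(path, index=False)
        again = load_panel(str(path))
        pd.testing.assert_frame_equal(again.table[PANEL_COLUMNS], panel12.table)

    @pytest.mark.parametrize(
        "mutate, match",
        [
            (lambda t: t.assign(freq=[1.2] + [0.2] * 11), "frequency"),
            (lambda t: t.assign(rsid=["rs2200733"] * 2 + t["rsid"].tolist()[2:]), "duplicate"),
            (lambda t: t.assign(modeled_allele=["X"] + t["modeled_allele"].tolist()[1:]), "nucleotide"),
        ],
    )
    def test_invalid_panels_rejected(self, panel12, tmp_path, mutate, match):
        bad = mutate(panel12.table.copy())
        path = tmp_path / "bad.csv"
        bad.to_csv(path, index=False)
        with pytest.raises(PanelError, match=match):
            load_panel(str(path))


class TestImputation:
    def test_missing_becomes_observed_column_mean(self):
        g = gm([[0], [1], [2], [np.nan]], ["rs1"])
        out = impute_missing(g)
        assert out.dosage[3, 0] == pytest.approx(1.0)
        assert out.n_missing == 0

    def test_no_missing_is_identity(self):
        g = gm([[0, 1], [2, 1]], ["rs1", "rs2"])
        assert impute_missing(g) is g

    def test_study_missing_rate_bookkeeping(self, rng):
        # 15 missing cells in a 904 x 12 matrix is a 0.14% missing rate
        d = rng.integers(0, 3, size=(904, 12)).astype(float)
        flat = rng.choice(d.size, size=15, replace=False)
        d.ravel()[flat] = np.nan
        g = gm(d, [f"rs{j}" for j in range(12)])
        assert g.n_missing == 15
        assert g.missing_rate == pytest.approx(15 / (904 * 12))
        assert impute_missing(g).n_missing == 0

    def test_fully_missing_column_needs_panel_fallback(self, panel12):
        d = np.full((3, 12), 1.0)
        d[:, panel12.rsids.index("rs2200733")] = np.nan
        g = gm(d, panel12.rsids)
        with pytest.raises(ValueError, match="no observed genotypes"):
            impute_missing(g)
        out = impute_missing(g, panel12)
        # Hardy-Weinberg fallback 2 * freq
        assert np.all(out.dosage[:, panel12.rsids.index("rs2200733")] == pytest.approx(2 * 0.13))

    @given(
        data=st.lists(
            st.lists(st.sampled_from([0.0, 1.0, 2.0, np.nan]), min_size=3, max_size=3),
            min_size=2,
            max_size=8,
        )
    )
    @settings(derandomize=True, max_examples=50)
    def test_imputation_preserves_observed_column_means(self, data):
        d = np.array(data)
        g = gm(d, ["rs1", "rs2", "rs3"])
        if any(np.all(np.isnan(d[:, j])) for j in range(3)):
            return  # fully missing columns are the fallback path, tested above
        out = impute_missing(g)
        for j in range(3):
            col = d[:, j]
            np.testing.assert_allclose(out.dosage[:, j].mean(), col[~np.isnan(col)].mean())


class TestComputeGrs:
    def test_all_zero_dosage_scores_zero(self, panel12):
        g = gm(np.zeros((3, 12)), panel12.rsids)
        assert np.all(compute_grs(g, panel12).score == 0.0)

    def test_homozygous_top_snp_scores_twice_its_weight(self, panel12):
        d = np.zeros((1, 12))
        d[0, panel12.rsids.index("rs2200733")] = 2
        assert compute_grs(gm(d, panel12.rsids), panel12).score[0] == pytest.approx(1.08)

    def test_heterozygous_everywhere_scores_weight_sum(self, panel12):
        # the 12 published weights sum to 1.02
        score = compute_grs(gm(np.ones((1, 12)), panel12.rsids), panel12).score[0]
        assert score == pytest.approx(1.02)

    def test_rsid_mismatch_lists_offenders(self, panel12):
        g = gm(np.zeros((1, 2)), ["rs2200733", "rs9999999"])
        with pytest.raises(PanelError, match="rs9999999"):
            compute_grs(g, panel12)

    def test_missing_dosages_rejected(self, panel12):
        d = np.zeros((2, 12))
        d[0, 0] = np.nan
        with pytest.raises(ValueError, match="impute"):
            compute_grs(gm(d, panel12.rsids), panel12)

    @given(
        dosage=st.lists(
            st.lists(st.sampled_from([0.0, 1.0, 2.0]), min_size=3, max_size=3),
            min_size=1,
            max_size=5,
        )
    )
    @settings(derandomize=True, max_examples=50)
    def test_matches_brute_force_cell_loop(self, panel12, dosage):
        sub = panel12.table.iloc[:3]
        from afgrs import SnpPanel

        panel3 = SnpPanel(sub.reset_index(drop=True))
        d = np.array(dosage)
        scores = compute_grs(gm(d, panel3.rsids), panel3).score
        for j in range(d.shape[0]):
            expected = 0.0
            for i in range(3):
                expected += panel3.weights[i] * d[j, i]
            assert scores[j] == pytest.approx(expected, abs=1e-12)

    @given(scale=st.floats(min_value=0.0, max_value=1.0))
    @settings(derandomize=True, max_examples=25)
    def test_linearity_in_dosage(self, panel12, scale):
        d = np.random.default_rng(11).integers(0, 3, size=(6, 12)).astype(float)
        base = compute_grs(gm(d, panel12.rsids), panel12).score
        scaled = compute_grs(gm(d * scale, panel12.rsids), panel12).score
        np.testing.assert_allclose(scaled, scale * base, atol=1e-12)

    def test_scores_respect_theoretical_bounds(self, panel12, rng):
        d = rng.integers(0, 3, size=(200, 12)).astype(float)
        s = compute_grs(gm(d, panel12.rsids), panel12).score
        lo, hi = panel12.score_bounds()
        assert np.all(s >= lo - 1e-12) and np.all(s <= hi + 1e-12)


class TestAssignQuantiles:
    def test_five_distinct_scores_one_per_group(self):
        v = GrsVector([f"p{i}" for i in range(5)], np.array([1.0, 2, 3, 4, 5]))
        out = assign_quantiles(v, 5)
        assert list(out.quintile) == [1, 2, 3, 4, 5]
        assert len(out.quintile_bounds) == 4

    def test_closed_upper_bound_convention(self):
        # a score exactly on a cut point belongs to the lower group
        scores = np.array([1.0, 2, 3, 4, 5, 6])
        v = assign_quantiles(GrsVector([f"p{i}" for i in range(6)], scores), 3)
        for s, lab in zip(scores, v.tertile):
            assert (s <= v.tertile_bounds[0]) == (lab == 1)

    def test_ties_make_unequal_groups(self):
        scores = np.array([0.0] * 4 + [1, 2, 3, 4, 5, 6])
        v = assign_quantiles(GrsVector([f"p{i}" for i in range(10)], scores), 5)
        sizes = np.bincount(v.quintile)[1:]
        assert sizes.sum() == 10
        assert sizes[0] == 4  # the tied block stays together

    def test_identical_scores_error(self):
        v = GrsVector(["a", "b", "c"], np.array([1.0, 1.0, 1.0]))
        with pytest.raises(ValueError, match="distinct"):
            assign_quantiles(v, 3)

    @given(seed=st.integers(0, 100))
    @settings(derandomize=True, max_examples=25)
    def test_invariant_to_monotone_transform(self, seed):
        r = np.random.default_rng(seed)
        scores = r.normal(size=50)
        ids = [f"p{i}" for i in range(50)]
        a = assign_quantiles(GrsVector(ids, scores), 5)
        b = assign_quantiles(GrsVector(ids, np.exp(scores)), 5)
        np.testing.assert_array_equal(a.quintile, b.quintile)


class TestSubsetOnePerGene:
    def test_af12_reduces_to_af9(self, panel12, panel9):
        out = subset_one_per_gene(panel12, AF9_KEEP)
        pd.testing.assert_frame_equal(out.table, panel9.table)

    def test_already_reduced_panel_unchanged(self, panel9):
        out = subset_one_per_gene(panel9, AF9_KEEP)
        pd.testing.assert_frame_equal(out.table, panel9.table)

    def test_unknown_rsid_rejected(self, panel12):
        with pytest.raises(PanelError, match="rs9999999"):
            subset_one_per_gene(panel12, {"PITX2": "rs9999999"})

    def test_uncovered_multi_snp_gene_rejected(self, panel12):
        with pytest.raises(PanelError, match="PITX2"):
            subset_one_per_gene(panel12, {})
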