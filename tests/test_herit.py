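"""Stratified LDSC machinery: annotation windows, LD-score oracle,
exact regression recovery, jackknife behaviour, FDR, and the variance
comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from scherit import (AnnotationMatrix, PartitionedLDScores, GenotypePanel,
                     build_annotation, compute_ld_scores, stratified_ldsc,
                     celltype_test, fdr_adjust, compare_matched_variance,
                     make_block_annotation, LdSimConfig, simulate_ld_reference)
from conftest import brute_force_ld_scores, brute_force_bh


def _variants(positions, chrom="1"):
    return pd.DataFrame({
        "SNP": [f"rs{i}" for i in range(len(positions))],
        "CHR": chrom, "POS": positions, "A1": "A", "A2": "G"})


class TestBuildAnnotation:
    def test_window_boundaries_are_inclusive(self):
        coords = pd.DataFrame({"gene": ["g"], "chrom": "1",
                               "start": [200_000], "end": [210_000]})
        variants = _variants([99_999, 100_000, 310_000, 310_001])
        annot = build_annotation({"set": ["g"]}, coords, variants,
                                 window_bp=100_000)
        col = annot.matrix[:, annot.categories.index("set")]
        assert col.tolist() == [0, 1, 1, 0]

    def test_other_chromosome_not_annotated(self):
        coords = pd.DataFrame({"gene": ["g"], "chrom": "1",
                               "start": [100], "end": [200]})
        variants = _variants([150], chrom="2")
        variants = pd.concat([variants, _variants([150], chrom="1")]).reset_index(drop=True)
        variants["SNP"] = ["a", "b"]
        annot = build_annotation({"set": ["g"]}, coords, variants, window_bp=10)
        assert annot.matrix[:, 1].tolist() == [0, 1]

    def test_overlapping_genes_stay_binary(self):
        coords = pd.DataFrame({"gene": ["g1", "g2"], "chrom": "1",
                               "start": [100, 150], "end": [300, 400]})
        variants = _variants([200])
        annot = build_annotation({"set": ["g1", "g2"]}, coords, variants,
                                 window_bp=0)
        assert annot.matrix[0, 1] == 1

    def test_missing_gene_dropped_with_warning_and_empty_set_kept(self):
        coords = pd.DataFrame({"gene": ["g1"], "chrom": "1",
                               "start": [1000], "end": [2000]})
        variants = _variants([5_000_000])
        with pytest.warns(UserWarning):
            annot = build_annotation({"set": ["g1", "ghost"]}, coords,
                                     variants, window_bp=10)
        assert annot.m_c["set"] == 0
        assert "set" in annot.categories


class TestLdScores:
    def test_exactly_uncorrelated_pair_gives_unit_base_score(self):
        dosages = np.array([[0, 0], [0, 2], [2, 0], [2, 2]], dtype=np.int8)
        panel = GenotypePanel(dosages=dosages, variants=_variants([1000, 2000]))
        annot = AnnotationMatrix(_variants([1000, 2000])[["SNP", "CHR", "POS"]]
                                 .rename(columns={"POS": "BP"}),
                                 np.ones((2, 1), np.int8), ["base"])
        ell = compute_ld_scores(panel, annot, adjusted=False)
        assert np.allclose(ell.values(), 1.0)

    def test_half_correlated_pair_sums_to_one_and_a_quarter(self):
        # sample r = 0.5 by construction
        dosages = np.array([[2, 2], [1, 1], [1, 0], [0, 1]], dtype=np.int8)
        panel = GenotypePanel(dosages=dosages, variants=_variants([1000, 2000]))
        annot = AnnotationMatrix(_variants([1000, 2000])[["SNP", "CHR", "POS"]]
                                 .rename(columns={"POS": "BP"}),
                                 np.ones((2, 1), np.int8), ["base"])
        ell = compute_ld_scores(panel, annot, adjusted=False)
        assert ell.values()[0, 0] == pytest.approx(1.25, abs=1e-12)

    @pytest.mark.parametrize("adjusted", [False, True])
    @pytest.mark.parametrize("window", [None, 15_000])
    def test_matches_brute_force_oracle(self, panel_small, adjusted, window):
        annot = make_block_annotation(panel_small, 0.3, seed=2)
        ell = compute_ld_scores(panel_small, annot, ld_window_bp=window,
                                adjusted=adjusted)
        oracle = brute_force_ld_scores(
            panel_small.dosages, annot.matrix,
            annot.snps["CHR"].to_numpy(), annot.snps["BP"].to_numpy(),
            ld_window_bp=window, adjusted=adjusted)
        assert np.max(np.abs(ell.values() - oracle)) < 1e-12

    def test_base_dominates_binary_categories_unadjusted(self, panel_small):
        annot = make_block_annotation(panel_small, 0.4, seed=3)
        ell = compute_ld_scores(panel_small, annot, adjusted=False).values()
        base = ell[:, 0]
        assert (ell[:, 1] <= base + 1e-12).all()
        assert (base >= 1.0 - 1e-12).all()   # includes the self-pair


def _noise_free_sumstats(panel, ldscores, tau, n=10_000, intercept=1.0):
    ell = ldscores.values()
    chi2 = intercept + n * ell @ np.asarray(tau)
    return pd.DataFrame({"SNP": ldscores.table["SNP"], "A1": "A", "A2": "G",
                         "N": n, "Z": np.sqrt(chi2)})


@pytest.fixture(scope="module")
def setup(panel_small):
    annot = make_block_annotation(panel_small, 0.3, seed=2)
    ldsc = compute_ld_scores(panel_small, annot, adjusted=False)
    return panel_small, annot, ldsc


class TestStratifiedLdsc:

    def test_flat_chi2_gives_zero_tau_and_unit_intercept(self, setup):
        panel, annot, ldsc = setup
        ss = pd.DataFrame({"SNP": ldsc.table["SNP"], "A1": "A", "A2": "G",
                           "N": 1000, "Z": 1.0})
        res = stratified_ldsc(ss, ldsc, annot, n_blocks=6)
        assert np.allclose(res.table["tau"], 0.0, atol=1e-12)
        assert res.intercept == pytest.approx(1.0, abs=1e-10)
        assert res.table.loc["base", "enrichment"] == pytest.approx(1.0)

    def test_exact_recovery_of_known_tau(self, setup):
        panel, annot, ldsc = setup
        tau = np.array([1e-4, 3e-4])
        ss = _noise_free_sumstats(panel, ldsc, tau)
        res = stratified_ldsc(ss, ldsc, annot, n_blocks=10)
        assert np.allclose(res.table["tau"], tau, rtol=1e-9)
        assert (res.table["tau_se"] < 1e-8).all()
        assert res.table.loc["base", "enrichment"] == pytest.approx(1.0, abs=1e-9)
        assert res.table.loc["base", "enrichment_se"] < 1e-9

    def test_single_base_category_tau_recovered(self, panel_small):
        annot = make_block_annotation(panel_small, 0.3, seed=2) \
            .subset_categories(["base"])
        ldsc = compute_ld_scores(panel_small, annot, adjusted=False)
        ss = _noise_free_sumstats(panel_small, ldsc, [1e-4])
        res = stratified_ldsc(ss, ldsc, annot, n_blocks=5)
        assert res.table.loc["base", "tau"] == pytest.approx(1e-4, rel=1e-10)

    def test_enrichment_reflects_planted_excess(self, setup):
        panel, annot, ldsc = setup
        # category tau above base: enrichment of the category exceeds 1
        ss = _noise_free_sumstats(panel, ldsc, [1e-4, 4e-4])
        res = stratified_ldsc(ss, ldsc, annot, n_blocks=6)
        assert res.table.loc["CT", "enrichment"] > 1.5

    def test_duplicate_category_raises(self, setup):
        panel, annot, ldsc = setup
        dup = AnnotationMatrix(annot.snps,
                               np.column_stack([annot.matrix, annot.matrix[:, 1]]),
                               ["base", "CT", "CT2"])
        tbl = ldsc.table.copy()
        tbl["CT2"] = tbl["CT"]
        dldsc = PartitionedLDScores(tbl, ["base", "CT", "CT2"], ldsc.adjusted)
        ss = _noise_free_sumstats(panel, ldsc, [1e-4, 1e-4])
        with pytest.raises(ValueError, match="collinear|rank"):
            stratified_ldsc(ss, dldsc, dup, n_blocks=6)

    def test_row_order_of_inputs_is_irrelevant(self, setup):
        panel, annot, ldsc = setup
        ss = _noise_free_sumstats(panel, ldsc, [1e-4, 3e-4])
        rng = np.random.default_rng(0)
        res1 = stratified_ldsc(ss, ldsc, annot, n_blocks=6)
        shuffled = ss.sample(frac=1, random_state=5).reset_index(drop=True)
        tbl = ldsc.table.sample(frac=1, random_state=9).reset_index(drop=True)
        res2 = stratified_ldsc(shuffled,
                               PartitionedLDScores(tbl, ldsc.categories, ldsc.adjusted),
                               annot, n_blocks=6)
        assert np.allclose(res1.table["tau"], res2.table["tau"])
        assert np.allclose(res1.table["enrichment"], res2.table["enrichment"],
                           equal_nan=True)

    def test_disjoint_snp_sets_error(self, setup):
        panel, annot, ldsc = setup
        ss = pd.DataFrame({"SNP": ["zz1", "zz2"], "A1": "A", "A2": "G",
                           "N": 100, "Z": 1.0})
        with pytest.raises(ValueError, match="no SNP shared"):
            stratified_ldsc(ss, ldsc, annot, n_blocks=2)


class TestCelltypeTest:
    def test_empty_category_is_flagged_not_tested(self, panel_small):
        annot = make_block_annotation(panel_small, 0.3, seed=2)
        zero = AnnotationMatrix(
            annot.snps,
            np.column_stack([annot.matrix, np.zeros(annot.n_snps, np.int8)]),
            ["base", "CT", "empty"])
        ldsc = compute_ld_scores(panel_small, zero, adjusted=False)
        ss = _noise_free_sumstats(panel_small, ldsc, [1e-4, 2e-4, 0.0])
        res = celltype_test(ss, zero, panel_small, n_blocks=6, ldscores=ldsc)
        row = res.set_index("cell_type").loc["empty"]
        assert not row["tested"] and np.isnan(row["p"])
        assert res.set_index("cell_type").loc["CT", "tested"]

    def test_q_values_are_bh_of_p(self, panel_small):
        annot = make_block_annotation(panel_small, 0.3, seed=2)
        ldsc = compute_ld_scores(panel_small, annot, adjusted=True)
        rng = np.random.default_rng(3)
        ss = pd.DataFrame({"SNP": ldsc.table["SNP"], "A1": "A", "A2": "G",
                           "N": 1000,
                           "Z": rng.normal(1, 0.5, annot.n_snps)})
        res = celltype_test(ss, annot, panel_small, n_blocks=6, ldscores=ldsc)
        tested = res[res["tested"]]
        assert np.allclose(tested["q"], fdr_adjust(tested["p"].to_numpy()))


class TestFdr:
    def test_worked_case(self):
        q = fdr_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, 0.04)

    def test_single_p_is_unchanged(self):
        assert fdr_adjust([0.37])[0] == pytest.approx(0.37)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    @settings(max_examples=100, deadline=None)
    def test_matches_step_up_oracle(self, pvals):
        assert np.allclose(fdr_adjust(pvals), brute_force_bh(pvals), atol=1e-12)

    def test_monotone_in_p(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=25)
        q = fdr_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_out_of_range_p_errors(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.2])


class TestVarianceComparison:
    def test_identical_samples_give_f_one_p_half(self):
        x = np.array([0.1, 0.5, -0.2, 0.9, 0.3, -0.6])
        res = compare_matched_variance(x, x.copy())
        assert res.f_stat == pytest.approx(1.0)
        assert res.f_p == pytest.approx(0.5)

    def test_levene_statistic_invariant_to_location_shift(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0, 1, 30)
        b = rng.normal(0, 2, 30)
        r1 = compare_matched_variance(a, b)
        r2 = compare_matched_variance(a + 5.0, b - 3.0)
        assert r1.levene_stat == pytest.approx(r2.levene_stat, rel=1e-12)

    def test_p_agrees_with_permutation_oracle(self):
        # normal samples with variance ratio 4: the F-test p should match
        # the permutation distribution of the variance ratio
        rng = np.random.default_rng(15)
        a = rng.normal(1, 1, 30)
        b = rng.normal(1, 2, 30)
        res = compare_matched_variance(a, b)
        pooled = np.concatenate([a, b])
        n_perm = 100_000
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            f = perm[30:].var(ddof=1) / perm[:30].var(ddof=1)
            count += f >= res.f_stat
        p_perm = count / n_perm
        mc_err = 3 * np.sqrt(max(p_perm, 1 / n_perm) / n_perm)
        assert res.f_p == pytest.approx(p_perm, abs=max(0.005, mc_err))

    def test_degenerate_zero_variance(self):
        res = compare_matched_variance([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])
        assert res.degenerate and res.f_p == 1.0

    def test_small_sample_errors(self):
        with pytest.raises(ValueError):
            compare_matched_variance([1.0, 2.0], [1.0, 2.0, 3.0])
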