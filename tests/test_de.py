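"""Differential-expression core: size factors, dispersions, NB test, BH."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from eggimmune.de import (
    CountMatrix,
    DesignError,
    bh_adjust,
    estimate_dispersions,
    estimate_size_factors,
    nb_exact_pvalue,
    nb_test,
    select_de_genes,
)

from conftest import make_count_matrix


class TestSizeFactors:
    def test_identical_samples_get_unit_factors(self):
        cm = make_count_matrix(np.array([[10, 10], [3, 3], [7, 7]]))
        sf = estimate_size_factors(cm)
        assert np.allclose(sf, [1.0, 1.0])

    def test_doubled_sample_splits_geometrically(self):
        # B = 2*A elementwise: geometric mean sits at sqrt(2)*A, so the
        # median ratios are 1/sqrt(2) and sqrt(2)
        a = np.array([10, 3, 7, 50])
        cm = make_count_matrix(np.column_stack([a, 2 * a]))
        sf = estimate_size_factors(cm)
        assert np.allclose(sf, [1 / np.sqrt(2), np.sqrt(2)])

    def test_matches_brute_force_median_of_ratios(self, rng):
        counts = rng.integers(1, 200, size=(5, 4))
        cm = make_count_matrix(counts)
        sf = estimate_size_factors(cm)
        # independent brute force over genes with positive geometric mean
        geo = np.exp(np.mean(np.log(counts), axis=1))
        expected = [np.median(counts[:, j] / geo) for j in range(4)]
        assert np.allclose(sf, expected)

    def test_zero_inflated_genes_are_excluded_from_the_median(self):
        counts = np.array([[0, 100], [10, 10], [4, 4], [9, 9]])
        sf = estimate_size_factors(make_count_matrix(counts))
        assert np.allclose(sf, [1.0, 1.0])

    def test_all_zero_matrix_is_an_error(self):
        with pytest.raises(DesignError):
            estimate_size_factors(make_count_matrix(np.zeros((3, 2), dtype=int)))

    def test_scaling_one_sample_scales_its_relative_factor(self, rng):
        # factors are defined up to normalization: tripling one sample's
        # counts triples its factor relative to every other sample
        counts = rng.integers(5, 500, size=(50, 4))
        scaled = counts.copy()
        scaled[:, 0] *= 3
        sf = estimate_size_factors(make_count_matrix(counts))
        sf2 = estimate_size_factors(make_count_matrix(scaled))
        rel = (sf2.iloc[0] / sf2.iloc[1]) / (sf.iloc[0] / sf.iloc[1])
        assert rel == pytest.approx(3.0, rel=0.05)


class TestDispersions:
    def test_recovers_planted_dispersion(self, rng):
        n, alpha = 200, 0.2
        mu = 10 ** rng.uniform(1.5, 3, n)
        lam = rng.gamma(1 / alpha, alpha * mu[:, None], size=(n, 6))
        cm = make_count_matrix(rng.poisson(lam))
        sf = estimate_size_factors(cm)
        disp = estimate_dispersions(cm, sf)
        assert 0.1 <= disp["dispersion_gene"].median() <= 0.4

    def test_constant_counts_give_zero_genewise_dispersion(self):
        counts = np.tile(np.array([[20], [50]]), (1, 6))
        cm = make_count_matrix(counts)
        sf = estimate_size_factors(cm)
        disp = estimate_dispersions(cm, sf)
        assert (disp["dispersion_gene"] == 0).all()

    def test_poisson_counts_give_near_zero_dispersion(self, rng):
        mu = 10 ** rng.uniform(2, 3, 300)
        cm = make_count_matrix(rng.poisson(mu[:, None], size=(300, 6)))
        sf = estimate_size_factors(cm)
        disp = estimate_dispersions(cm, sf)
        assert disp["dispersion_gene"].median() < 0.05

    def test_final_dispersion_takes_the_max_with_the_trend(self, nb_counts_3v3):
        cm, _, _ = nb_counts_3v3
        sf = estimate_size_factors(cm)
        disp = estimate_dispersions(cm, sf)
        assert (disp["dispersion"] >= disp["dispersion_gene"] - 1e-12).all()
        assert (disp["dispersion"] >= disp["dispersion_trend"] - 1e-12).all()

    def test_single_replicate_everywhere_is_an_error(self):
        cm = make_count_matrix(
            np.array([[5, 9], [3, 2]]), treatments=["naive", "septic"]
        )
        sf = pd.Series([1.0, 1.0], index=cm.sample_ids)
        with pytest.raises(DesignError, match="pool"):
            estimate_dispersions(cm, sf)


def _brute_force_nb_exact_p(counts_a, counts_b, alpha, cap=4000):
    """Independent conditioned-test oracle via exact pmf convolution."""
    q0 = np.concatenate([counts_a, counts_b]).mean()
    grid = np.arange(cap)

    def sum_pmf(n_samples):
        r = 1.0 / alpha
        p = r / (r + q0)
        pmf = stats.nbinom.pmf(grid, r, p)
        out = pmf
        for _ in range(n_samples - 1):
            out = np.convolve(out, pmf)[:cap]
        return out

    pa, pb = sum_pmf(len(counts_a)), sum_pmf(len(counts_b))
    ka, kb = int(sum(counts_a)), int(sum(counts_b))
    ks = ka + kb
    probs = pa[: ks + 1] * pb[: ks + 1][::-1]
    obs = pa[ka] * pb[kb]
    return probs[probs <= obs * (1 + 1e-10)].sum() / probs.sum()


class TestNbTest:
    def test_small_count_p_matches_enumeration_oracle(self, rng):
        alpha = 0.1
        for _ in range(10):
            a = rng.poisson(15, 2)
            b = rng.poisson(25, 2)
            cm = make_count_matrix(
                np.array([np.concatenate([a, b])]),
                treatments=["naive", "naive", "septic", "septic"],
            )
            sf = pd.Series(1.0, index=cm.sample_ids)
            disp = pd.Series([alpha], index=cm.gene_ids)
            res = nb_test(cm, sf, disp, ["s0", "s1"], ["s2", "s3"])
            oracle = _brute_force_nb_exact_p(a, b, alpha)
            assert res["pval"].iloc[0] == pytest.approx(oracle, rel=0.10)

    def test_zero_baseline_gives_infinite_fold_change_finite_p(self):
        cm = make_count_matrix(np.array([[0, 0, 0, 30, 40, 35], [9, 9, 9, 9, 9, 9]]))
        sf = pd.Series(1.0, index=cm.sample_ids)
        disp = pd.Series(0.05, index=cm.gene_ids)
        res = nb_test(cm, sf, disp, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        assert np.isposinf(res["fold_change"].iloc[0])
        assert 0 <= res["pval"].iloc[0] <= 1

    def test_all_zero_gene_gets_nan_fold_and_p_one(self):
        cm = make_count_matrix(np.array([[0] * 6, [5] * 6]))
        sf = pd.Series(1.0, index=cm.sample_ids)
        disp = pd.Series(0.05, index=cm.gene_ids)
        res = nb_test(cm, sf, disp, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        assert np.isnan(res["fold_change"].iloc[0])
        assert res["pval"].iloc[0] == 1.0

    def test_null_pvalues_roughly_uniform(self, nb_counts_3v3):
        cm, _, alpha = nb_counts_3v3
        sf = estimate_size_factors(cm)
        disp = pd.Series(alpha, index=cm.gene_ids)
        res = nb_test(cm, sf, disp, list(cm.sample_ids[:3]), list(cm.sample_ids[3:]))
        frac = (res["pval"] < 0.05).mean()
        assert 0.03 <= frac <= 0.07

    def test_unknown_sample_is_an_error(self, nb_counts_3v3):
        cm, _, alpha = nb_counts_3v3
        sf = estimate_size_factors(cm)
        with pytest.raises(DesignError, match="unknown"):
            nb_test(cm, sf, pd.Series(alpha, index=cm.gene_ids),
                    ["nope"], list(cm.sample_ids[3:]))

    def test_window_truncation_matches_full_enumeration(self):
        # moderately large total: the +-12 sigma window must not change p
        p_win = nb_exact_pvalue(500, 700, 600.0, 600.0, 900.0, 900.0)
        p_full = nb_exact_pvalue(500, 700, 600.0, 600.0, 900.0, 900.0,
                                 window_sd=1e9)
        assert p_win == pytest.approx(p_full, rel=1e-9)


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.04])[0] == pytest.approx(0.04)

    def test_stepup_hand_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_matches_statsmodels_on_random_vectors(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(50):
            p = rng.random(rng.integers(1, 200))
            ours = bh_adjust(p)
            theirs = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(ours, theirs)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_never_decreases_and_is_permutation_equivariant(self, ps):
        p = np.array(ps)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()
        perm = np.random.default_rng(0).permutation(len(p))
        assert np.allclose(bh_adjust(p[perm]), adj[perm])

    def test_out_of_range_p_is_an_error(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestSelection:
    def _frame(self, fc, padj):
        return pd.DataFrame({"fold_change": fc, "padj": padj,
                             "pval": padj, "base_mean_a": 1.0,
                             "base_mean_b": 1.0})

    def test_subthreshold_fold_is_excluded_despite_tiny_p(self):
        out = select_de_genes(self._frame([1.9], [1e-6]))
        assert not out["significant"].iloc[0]

    def test_infinite_fold_counts_as_induced(self):
        out = select_de_genes(self._frame([np.inf], [0.001]))
        assert out["significant"].iloc[0]
        assert out["direction"].iloc[0] == "induced"

    def test_repression_direction_and_nan_exclusion(self):
        out = select_de_genes(self._frame([0.4, np.nan], [0.001, 0.001]))
        assert out["direction"].tolist() == ["repressed", ""]

    def test_thresholds_must_be_positive(self):
        with pytest.raises(ValueError):
            select_de_genes(self._frame([2.0], [0.001]), fc_threshold=0)
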