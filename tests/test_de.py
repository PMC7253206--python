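"""Normalization, NB2 likelihood, GLM-LRT machinery, and BH adjustment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from cistrans.de import (
    CountMatrix,
    bh_adjust,
    estimate_dispersion,
    filter_low_expression,
    nb_glm_lrt,
    nb_loglik,
    parental_de,
    size_factors_median_ratios,
)


from _oracles import grid_max_loglik_intercept, grid_max_loglik_two_group


class TestSizeFactors:
    def test_doubled_sample_hand_value(self):
        counts = pd.DataFrame({"s1": [10, 20, 40], "s2": [20, 40, 80]})
        sf = size_factors_median_ratios(counts)
        assert np.allclose(sf.to_numpy(), [1 / np.sqrt(2), np.sqrt(2)])

    def test_identical_samples_unity(self):
        counts = pd.DataFrame({"a": [5, 9, 3], "b": [5, 9, 3], "c": [5, 9, 3]})
        assert np.allclose(size_factors_median_ratios(counts), 1.0)

    def test_single_sample_unity(self):
        counts = pd.DataFrame({"only": [4, 7, 100]})
        assert np.allclose(size_factors_median_ratios(counts), 1.0)

    def test_no_all_positive_gene_errors(self):
        counts = pd.DataFrame({"a": [0, 3], "b": [3, 0]})
        with pytest.raises(ValueError, match="relax"):
            size_factors_median_ratios(counts)


def _cm(per_genotype_counts):
    """CountMatrix with 3 replicates per genotype at the given constant."""
    cols, data = [], {}
    meta = {}
    for geno, val in per_genotype_counts.items():
        for r in range(1, 4):
            name = f"{geno}_rep{r}"
            data[name] = [val]
            meta[name] = {"genotype": geno, "replicate": f"rep{r}"}
    return CountMatrix(
        pd.DataFrame(data, index=["g1"]), pd.DataFrame.from_dict(meta, orient="index")
    )


class TestLowExpressionFilter:
    @pytest.mark.parametrize(
        "medians,rule,kept",
        [
            ({"W": 4, "C": 4, "CxW": 4}, "any", False),   # below threshold everywhere
            ({"W": 0, "C": 12, "CxW": 6}, "any", True),   # silenced in one parent kept
            ({"W": 0, "C": 12, "CxW": 6}, "all", False),  # strict variant drops it
            ({"W": 5, "C": 5, "CxW": 5}, "any", True),    # 5 is not "smaller than five"
            ({"W": 5, "C": 5, "CxW": 5}, "all", True),
        ],
    )
    def test_threshold_rules(self, medians, rule, kept):
        out = filter_low_expression(_cm(medians), threshold=5, rule=rule)
        assert (len(out.counts) == 1) is kept

    def test_unknown_rule(self):
        with pytest.raises(ValueError):
            filter_low_expression(_cm({"W": 9}), rule="some")


class TestNbLoglik:
    def test_poisson_closed_form(self):
        # log pmf(3; 3) = 3 ln 3 - 3 - ln 6
        expected = 3 * np.log(3) - 3 - np.log(6)
        assert np.isclose(nb_loglik([3], [3], 0.0), expected)

    def test_matches_scipy_nbinom(self, rng):
        y = rng.poisson(50, size=8)
        mu = rng.uniform(20, 80, size=8)
        phi = 0.07
        r = 1 / phi
        expected = stats.nbinom.logpmf(y, r, r / (r + mu)).sum()
        assert np.isclose(nb_loglik(y, mu, phi), expected, atol=1e-10)

    def test_zero_count_vanishing_mean_contributes_nothing(self):
        base = nb_loglik([4, 6], [5.0, 5.0], 0.1)
        extended = nb_loglik([4, 6, 0], [5.0, 5.0, 1e-12], 0.1)
        assert abs(extended - base) < 1e-9

    def test_maximized_at_sample_mean(self):
        y = np.array([7, 11, 9, 13], dtype=float)
        phi = 0.2
        grid = np.linspace(1.0, 30.0, 20_000)
        lls = [nb_loglik(y, np.full(4, m), phi) for m in grid]
        assert abs(grid[np.argmax(lls)] - y.mean()) < 0.01

    def test_negative_phi_rejected(self):
        with pytest.raises(ValueError):
            nb_loglik([1], [1.0], -0.5)


class TestNbGlmLrt:
    X_FULL = np.column_stack([np.ones(6), np.r_[np.ones(3), np.zeros(3)]])
    X_RED = np.ones((6, 1))
    SF = np.ones(6)
    GROUP = np.array(["W"] * 3 + ["C"] * 3)

    def test_null_data_identity(self):
        y = np.array([50, 52, 48, 50, 52, 48], dtype=float)
        res = nb_glm_lrt(y, self.X_FULL, self.X_RED, self.SF, phi=0.05, group=self.GROUP)
        assert res.lrt_stat < 1e-6
        assert res.pvalue > 0.99

    def test_strong_effect_matches_grid_oracle(self):
        # W (100,110,90) vs C (10,9,11), phi fixed at 0.1
        y = np.array([100, 110, 90, 10, 9, 11], dtype=float)
        res = nb_glm_lrt(
            y, self.X_FULL, self.X_RED, self.SF, phi=0.1,
            group=self.GROUP, p_method="chisq",
        )
        oracle_full = grid_max_loglik_two_group(y, self.X_FULL[:, 1], self.SF, 0.1)
        oracle_red = grid_max_loglik_intercept(y, self.SF, 0.1)
        assert abs(res.ll_full - oracle_full) < 1e-3
        assert abs(res.ll_reduced - oracle_red) < 1e-3
        assert res.pvalue < 1e-6

    def test_log2fc_invariant_to_joint_rescale(self):
        y = np.array([40, 44, 36, 10, 9, 11], dtype=float)
        a = nb_glm_lrt(y, self.X_FULL, self.X_RED, self.SF, phi=0.05, group=self.GROUP)
        b = nb_glm_lrt(
            2 * y, self.X_FULL, self.X_RED, 2 * self.SF, phi=0.05, group=self.GROUP
        )
        assert np.isclose(a.log2fc, b.log2fc)

    def test_lrt_invariant_to_size_factor_scaling_and_reordering(self):
        y = np.array([40, 44, 36, 10, 9, 11], dtype=float)
        a = nb_glm_lrt(y, self.X_FULL, self.X_RED, self.SF, phi=0.05)
        b = nb_glm_lrt(y, self.X_FULL, self.X_RED, 3.0 * self.SF, phi=0.05)
        assert np.isclose(a.lrt_stat, b.lrt_stat, atol=1e-6)
        perm = np.array([5, 3, 4, 0, 2, 1])
        c = nb_glm_lrt(y[perm], self.X_FULL[perm], self.X_RED[perm], self.SF, phi=0.05)
        assert np.isclose(a.lrt_stat, c.lrt_stat, atol=1e-6)

    def test_non_nested_design_rejected(self):
        X_other = np.arange(6, dtype=float).reshape(-1, 1)
        with pytest.raises(ValueError, match="nested"):
            nb_glm_lrt(np.ones(6), self.X_FULL[:, 1:], X_other, self.SF, phi=0.1)

    def test_all_zero_gene_degenerate(self):
        res = nb_glm_lrt(np.zeros(6), self.X_FULL, self.X_RED, self.SF, phi=0.1)
        assert res.degenerate
        assert res.pvalue == 1.0

    def test_p_floor(self):
        y = np.array([100000, 100001, 99999, 1, 2, 1], dtype=float)
        res = nb_glm_lrt(
            y, self.X_FULL, self.X_RED, self.SF, phi=1e-6, p_method="chisq"
        )
        assert res.pvalue >= 1e-300


class TestDispersionEstimation:
    def test_recovers_order_of_magnitude(self, rng):
        # many replicates, single group: phi-hat should approach the truth
        phi_true = 0.1
        r = 1 / phi_true
        mu = 200.0
        y = stats.nbinom.rvs(r, r / (r + mu), size=200, random_state=17)
        X = np.ones((y.size, 1))
        phi_hat = estimate_dispersion(y, X, np.zeros(y.size))
        assert 0.05 < phi_hat < 0.2

    def test_all_zero_returns_zero(self):
        assert estimate_dispersion(np.zeros(6), np.ones((6, 1))) == 0.0


class TestBhAdjust:
    def test_hand_stepup(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_all_ones_capped(self):
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_nan_propagates_and_is_excluded(self):
        q = bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(q[1])
        # ranking over the two valid entries only
        assert np.allclose(q[[0, 2]], [0.02, 0.04])

    @settings(derandomize=True, max_examples=40)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    def test_order_invariance_and_monotonicity(self, pvals):
        p = np.array(pvals)
        q = bh_adjust(p)
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(q[order]) >= -1e-12).all()
        perm = np.random.default_rng(0).permutation(p.size)
        assert np.allclose(bh_adjust(p[perm]), q[perm])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestParentalDe:
    def test_structure_and_replicate_requirement(self, uniform_sim):
        from cistrans.pipeline import total_count_matrix

        profile, truth = uniform_sim
        totals = total_count_matrix(profile)
        table = parental_de(totals)
        assert set(table.columns) >= {"log2fc", "pvalue", "qvalue", "significant"}
        assert ((table["pvalue"] >= 0) & (table["pvalue"] <= 1)).all()
        # strong parental divergence (|c+t| >= 2) should mostly be detected
        strong = truth.index[truth["expected_parental_log2fc"].abs() >= 2]
        assert table.loc[strong, "significant"].mean() > 0.8

    def test_too_few_replicates_rejected(self):
        counts = pd.DataFrame({"W_rep1": [5], "C_rep1": [5]}, index=["g"])
        meta = pd.DataFrame(
            {"genotype": ["W", "C"], "replicate": ["rep1", "rep1"]},
            index=["W_rep1", "C_rep1"],
        )
        with pytest.raises(ValueError):
            parental_de(CountMatrix(counts, meta))
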