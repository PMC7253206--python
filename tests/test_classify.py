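"""Cis/trans tests, category decision table, and study-level statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cistrans import simulate
from cistrans.ase import AlleleCountProfile
from cistrans.classify import (
    binomial_symmetry_test,
    cis_percentage_bins,
    cis_test,
    classify_all,
    classify_regulation,
    category_counts,
    effect_size_comparison,
    proportion_test,
    trans_test,
)


def make_profile(f0w, f0c, f1w, f1c):
    """Single-gene profile from per-replicate count lists."""
    cols, vals = [], []
    for rep, (w, c) in enumerate(zip(f0w, f0c), 1):
        cols += [("F0", f"rep{rep}", "W"), ("F0", f"rep{rep}", "C")]
        vals += [w, c]
    for rep, (w, c) in enumerate(zip(f1w, f1c), 1):
        cols += [("F1", f"rep{rep}", "W"), ("F1", f"rep{rep}", "C")]
        vals += [w, c]
    counts = pd.DataFrame(
        [vals], index=["g1"], columns=pd.MultiIndex.from_tuples(cols)
    ).sort_index(axis=1)
    return AlleleCountProfile(counts)


UNIT_SF = None  # use profile-derived factors unless a test pins them


def unit_sf(profile):
    return pd.Series(1.0, index=profile.counts.columns)


class TestCisTest:
    def test_symmetric_null(self):
        prof = make_profile([100] * 3, [100] * 3, [50, 55, 45], [50, 45, 55])
        res = cis_test(prof, "g1", unit_sf(prof))
        assert res.pvalue > 0.5

    def test_allele_swap_flips_log2fc_sign(self):
        prof = make_profile([100] * 3, [100] * 3, [80, 85, 75], [20, 22, 18])
        res = cis_test(prof, "g1", unit_sf(prof))
        swapped = make_profile([100] * 3, [100] * 3, [20, 22, 18], [80, 85, 75])
        res_sw = cis_test(swapped, "g1", unit_sf(swapped))
        assert np.isclose(res.log2fc, -res_sw.log2fc)
        assert res.log2fc > 0

    def test_strong_imbalance_detected(self):
        prof = make_profile([100] * 3, [100] * 3, [400, 410, 390], [100, 95, 105])
        res = cis_test(prof, "g1", unit_sf(prof))
        assert res.pvalue < 0.01


class TestTransTest:
    def test_equal_ratio_across_generations_null(self):
        # F0 ratio 4:1 and F1 ratio 4:1 with large counts -> no interaction
        prof = make_profile(
            [4000, 4100, 3900], [1000, 1020, 980],
            [2000, 2050, 1950], [500, 510, 490],
        )
        res = trans_test(prof, "g1", unit_sf(prof))
        assert res.pvalue > 0.5

    def test_ratio_shift_detected(self):
        # parents equal, hybrid strongly imbalanced -> interaction
        prof = make_profile(
            [1000, 1020, 980], [1000, 990, 1010],
            [1600, 1620, 1580], [400, 390, 410],
        )
        res = trans_test(prof, "g1", unit_sf(prof))
        assert res.pvalue < 0.01

    def test_missing_generation_errors(self):
        counts = pd.DataFrame(
            [[10, 12]],
            index=["g1"],
            columns=pd.MultiIndex.from_tuples(
                [("F1", "rep1", "W"), ("F1", "rep1", "C")]
            ),
        )
        prof = AlleleCountProfile(counts)
        with pytest.raises(ValueError, match="F0"):
            trans_test(prof, "g1", unit_sf(prof))


class TestDecisionTable:
    SIG, NS = 0.01, 0.5

    @pytest.mark.parametrize(
        "qp,qh,qt,cis,trans,expected",
        [
            (NS, NS, NS, 0.1, 0.1, "conserved"),
            (SIG, SIG, NS, 1.0, 0.1, "cis_only"),
            (SIG, NS, SIG, 0.1, 1.0, "trans_only"),
            (SIG, SIG, SIG, 1.0, 0.8, "cis_plus_trans"),
            (SIG, SIG, SIG, 1.0, -0.4, "cis_by_trans"),
            (NS, SIG, SIG, 1.0, -1.0, "compensatory"),
            (SIG, NS, NS, 0.5, 0.5, "ambiguous"),
            (NS, SIG, NS, 0.5, 0.0, "ambiguous"),
            (NS, NS, SIG, 0.0, 0.5, "ambiguous"),
            (SIG, SIG, SIG, 0.0, 0.5, "ambiguous"),  # sign tie-break
        ],
    )
    def test_categories(self, qp, qh, qt, cis, trans, expected):
        assert classify_regulation(qp, qh, qt, cis, trans, alpha=0.05) == expected


class TestClassifyAll:
    def test_partition_and_component_identity(self, uniform_calls):
        calls, truth = uniform_calls
        counts = category_counts(calls)
        assert sum(counts.values()) == len(calls)
        assert np.allclose(
            calls["cis_component"] + calls["trans_component"],
            calls["parental_log2fc"],
        )

    def test_recovery_on_uniform_mix(self, uniform_calls):
        calls, truth = uniform_calls
        joined = calls.join(truth)
        for cat in simulate.CATEGORIES:
            sel = joined["true_category"] == cat
            assert (joined.loc[sel, "category"] == cat).mean() > 0.7, cat

    def test_label_swap_symmetry(self, uniform_sim):
        """Swapping W and C everywhere flips all effect signs."""
        profile, _ = uniform_sim
        sub = AlleleCountProfile(profile.counts.iloc[:20])
        swapped_counts = sub.counts.copy()
        swapped_counts.columns = pd.MultiIndex.from_tuples(
            [(g, r, {"W": "C", "C": "W"}[a]) for g, r, a in sub.counts.columns]
        )
        swapped = AlleleCountProfile(swapped_counts.sort_index(axis=1))
        a = classify_all(sub)
        b = classify_all(swapped)
        assert np.allclose(a["parental_log2fc"], -b["parental_log2fc"], atol=1e-9)
        assert np.allclose(a["cis_component"], -b["cis_component"], atol=1e-9)
        assert (a["category"] == b["category"]).all()


class TestCisPercentage:
    @pytest.mark.parametrize(
        "parental,hybrid,expected",
        [(2.0, 2.0, 100.0), (2.0, 0.0, 0.0), (2.0, 1.0, 50.0)],
    )
    def test_share(self, parental, hybrid, expected):
        calls = pd.DataFrame(
            {
                "parental_log2fc": [parental],
                "cis_component": [hybrid],
                "trans_component": [parental - hybrid],
                "cis_percentage": [
                    100 * abs(hybrid) / (abs(hybrid) + abs(parental - hybrid))
                ],
            }
        )
        out = cis_percentage_bins(calls, [0, 1, 2, 3])
        means = out["mean_cis_percentage"].dropna()
        assert np.isclose(means.iloc[0], expected)

    def test_empty_bin_is_missing_not_zero(self):
        calls = pd.DataFrame(
            {"parental_log2fc": [0.5], "cis_percentage": [40.0]}
        )
        out = cis_percentage_bins(calls, [0, 1, 2])
        assert np.isnan(out["mean_cis_percentage"].iloc[1])
        assert out["n_genes"].iloc[1] == 0

    def test_empty_calls_rejected(self):
        with pytest.raises(ValueError):
            cis_percentage_bins(pd.DataFrame(), [0, 1])


class TestProportionTest:
    def test_study_counts_reproduce_printed_z(self):
        # 960 trans-significant of 1,062 against an even split
        z, p = proportion_test(960, 1062, 0.5)
        assert abs(z - 26.3) < 0.05
        assert p < 0.001

    def test_exact_null_small_z(self):
        z, _ = proportion_test(531, 1062, 0.5)
        assert abs(z) < 0.031

    def test_hand_computation(self):
        z, _ = proportion_test(9, 12, 0.5)
        assert np.isclose(z, (9 - 6 - 0.5) / np.sqrt(3), atol=1e-12)

    def test_invalid_p0(self):
        with pytest.raises(ValueError):
            proportion_test(5, 10, 0.0)


class TestBinomialSymmetry:
    def test_study_counts(self):
        # 4,123 up vs 4,398 down in the cultivated parent
        p = binomial_symmetry_test(4123, 4398)
        assert np.isclose(p, 0.003, atol=5e-4)

    def test_perfect_symmetry(self):
        assert binomial_symmetry_test(10, 10) == 1.0

    def test_extreme_tail_closed_form(self):
        assert np.isclose(binomial_symmetry_test(0, 20), 2 * 0.5**20, rtol=1e-9)

    def test_empty_counts(self):
        assert binomial_symmetry_test(0, 0) == 1.0


class TestEffectSizeComparison:
    def test_identical_groups_p_one(self):
        med_t, med_a, p = effect_size_comparison([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_exact_enumeration_small_groups(self):
        # all 3 ranks below: two-sided exact p = 2/C(6,3) * 1 = 0.1
        _, _, p = effect_size_comparison([1, 2, 3], [4, 5, 6])
        assert np.isclose(p, 0.1)

    def test_shifted_distributions_detected(self, rng):
        cis = np.abs(rng.normal(1.5, 0.5, size=500))
        trans = np.abs(rng.normal(2.0, 0.5, size=500))
        med_t, med_a, p = effect_size_comparison(trans, cis)
        assert med_t > med_a
        assert p < 0.001

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            effect_size_comparison([], [1.0])
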