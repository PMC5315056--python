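"""Permutation inference tests: sign flips, FWE, NPC, ANOVA, fingerprints."""

import numpy as np
import pandas as pd
import pytest

import cordconn.inference as inf


class TestSignFlip:
    def test_all_zero_values_give_p_one(self):
        res = inf.signflip_one_sample(np.zeros(20), n_flips=100, seed=0)
        assert res.stat == 0.0
        assert res.p_uncorrected == 1.0

    def test_exhaustive_all_positive_n5(self):
        # all 32 sign patterns: only +/-(1,1,1,1,1) reach |t|; p = 2/32
        res = inf.signflip_one_sample(np.ones(5), n_flips=10000, seed=0)
        assert res.exhaustive
        assert res.p_uncorrected == pytest.approx(2 / 32)

    def test_type_one_error_calibrated(self):
        """Rejection rate at alpha=0.05 over 1000 null cohorts of n=20."""
        rng = np.random.default_rng(11)
        rejections = 0
        n_cohorts = 1000
        for _ in range(n_cohorts):
            values = rng.standard_normal(20)
            res = inf.signflip_one_sample(values, n_flips=500, seed=rng)
            rejections += res.p_uncorrected <= 0.05
        rate = rejections / n_cohorts
        assert 0.03 <= rate <= 0.07

    def test_exhaustive_and_sampled_agree(self):
        rng = np.random.default_rng(3)
        values = rng.standard_normal(10) + 0.5
        exact = inf.signflip_one_sample(values, n_flips=2 ** 10, seed=0)
        assert exact.exhaustive
        sampled_flips = rng.integers(0, 2, (4000, 10)) * 2.0 - 1.0
        sampled = inf.fwe_family(values[:, None], flips=sampled_flips)[0]
        p = exact.p_uncorrected
        tol = 2 * np.sqrt(p * (1 - p) / 4000) + 1 / 4000
        assert abs(sampled.p_uncorrected - p) <= tol


class TestFweFamily:
    def test_single_test_corrected_equals_uncorrected(self, rng):
        values = rng.standard_normal((15, 1))
        res = inf.fwe_family(values, n_flips=1000, seed=4)[0]
        assert res.p_fwe == pytest.approx(res.p_uncorrected)

    def test_corrected_never_below_uncorrected(self, rng):
        values = rng.standard_normal((12, 4)) + 0.3
        for res in inf.fwe_family(values, n_flips=500, seed=5):
            assert res.p_fwe >= res.p_uncorrected

    def test_perfectly_dependent_family_no_penalty(self, rng):
        col = rng.standard_normal(8) + 1.0
        values = np.tile(col[:, None], (1, 4))
        for res in inf.fwe_family(values, n_flips=10000, seed=6):
            assert res.exhaustive
            assert res.p_fwe == pytest.approx(res.p_uncorrected)

    def test_familywise_error_controlled_k4(self):
        """Familywise type-I error over 4 independent null tests ~ alpha."""
        rng = np.random.default_rng(21)
        fw_rej, unc_power = 0, 0
        n_cohorts = 600
        for _ in range(n_cohorts):
            values = rng.standard_normal((20, 4))
            results = inf.fwe_family(values, n_flips=300, seed=rng)
            fw_rej += any(r.p_fwe <= 0.05 for r in results)
        rate = fw_rej / n_cohorts
        assert 0.02 <= rate <= 0.08

    def test_corrected_power_not_above_uncorrected(self):
        rng = np.random.default_rng(22)
        pow_c, pow_u = 0, 0
        for _ in range(200):
            values = rng.standard_normal((20, 4)) + 0.4
            results = inf.fwe_family(values, n_flips=300, seed=rng)
            pow_u += sum(r.p_uncorrected <= 0.05 for r in results)
            pow_c += sum(r.p_fwe <= 0.05 for r in results)
        assert pow_c <= pow_u


class TestPaired:
    def test_identical_samples_give_p_one(self, rng):
        a = rng.standard_normal(10)
        res = inf.paired_permutation(a, a.copy(), n_flips=200, seed=0)[0]
        assert res.p_uncorrected == 1.0

    def test_reduces_to_one_sample_on_differences(self, rng):
        a = rng.standard_normal(9)
        b = rng.standard_normal(9)
        paired = inf.paired_permutation(a, b, n_flips=2 ** 9, seed=1)[0]
        one = inf.signflip_one_sample(a - b, n_flips=2 ** 9, seed=1)
        assert paired.p_uncorrected == pytest.approx(one.p_uncorrected)
        assert paired.stat == pytest.approx(one.stat)

    def test_small_n_matches_manual_enumeration(self):
        d = np.array([0.3, 0.1, 0.4, 0.2, 0.5])
        res = inf.signflip_one_sample(d, n_flips=10000, seed=0)
        # brute-force all 32 sign patterns
        n = d.size
        count = 0
        tobs = d.mean() / (d.std(ddof=1) / np.sqrt(n))
        for bits in range(2 ** n):
            s = np.array([1 if bits >> i & 1 else -1 for i in range(n)])
            v = d * s
            t = v.mean() / (v.std(ddof=1) / np.sqrt(n))
            count += abs(t) >= abs(tobs) - 1e-12
        assert res.p_uncorrected == pytest.approx(count / 2 ** n)


class TestNpc:
    def test_single_analysis_equals_single_test(self, rng):
        values = rng.standard_normal(14) + 0.4
        npc = inf.npc_fisher(values[:, None], n_flips=2 ** 14, seed=2)
        single = inf.signflip_one_sample(values, n_flips=2 ** 14, seed=2)
        assert npc.p_uncorrected == pytest.approx(single.p_uncorrected,
                                                  abs=2e-3)

    def test_null_calibration_j8(self):
        rng = np.random.default_rng(33)
        rej = 0
        n_cohorts = 400
        for _ in range(n_cohorts):
            values = rng.standard_normal((20, 8))
            res = inf.npc_fisher(values, n_flips=400, seed=rng)
            rej += res.p_uncorrected <= 0.05
        assert 0.02 <= rej / n_cohorts <= 0.08

    def test_one_strong_effect_among_nulls_detected(self):
        """A single strong effect drives the combined p below the median
        single-analysis null p."""
        rng = np.random.default_rng(34)
        combined_ps, null_ps = [], []
        for _ in range(40):
            values = rng.standard_normal((20, 8))
            values[:, 0] += 1.5
            res = inf.npc_fisher(values, n_flips=400, seed=rng)
            combined_ps.append(res.p_uncorrected)
            null_ps.extend(inf.signflip_one_sample(values[:, j], n_flips=200,
                                                   seed=rng).p_uncorrected
                           for j in range(1, 8))
        assert np.median(combined_ps) < np.median(null_ps)
        assert np.median(combined_ps) < 0.25

    def test_zero_analyses_rejected(self):
        with pytest.raises(inf.InferenceError):
            inf.npc_fisher(np.empty((10, 0)), n_flips=100, seed=0)

    def test_family_version_orders_p_values(self, rng):
        values = {"A": rng.standard_normal((12, 5)) + 0.8,
                  "B": rng.standard_normal((12, 5))}
        out = inf.npc_fisher_family(values, n_flips=1000, seed=3)
        assert out["A"].p_fwe >= out["A"].p_uncorrected
        assert out["A"].p_uncorrected < out["B"].p_uncorrected


class TestAverageAcross:
    def test_identical_columns_match_single_column(self, rng):
        col = rng.standard_normal(11) + 0.3
        values = np.tile(col[:, None], (1, 6))
        a = inf.average_across_analyses_test(values, n_flips=2 ** 11, seed=0)
        b = inf.signflip_one_sample(col, n_flips=2 ** 11, seed=0)
        assert a.p_uncorrected == pytest.approx(b.p_uncorrected)

    def test_columns_summing_to_zero_give_p_one(self):
        rng = np.random.default_rng(8)
        # integer-valued effects cancel exactly in floating point
        half = rng.integers(-5, 6, size=(10, 3)).astype(float)
        values = np.concatenate([half, -half], axis=1)
        res = inf.average_across_analyses_test(values, n_flips=100, seed=0)
        assert res.stat == 0.0
        assert res.p_uncorrected == 1.0

    def test_small_n_matches_exhaustive_oracle(self):
        values = np.array([[0.2, 0.4], [0.1, 0.1], [0.5, 0.3],
                           [-0.1, 0.2], [0.3, 0.0]])
        res = inf.average_across_analyses_test(values, n_flips=10000, seed=0)
        oracle = inf.signflip_one_sample(values.mean(axis=1), n_flips=10000,
                                         seed=0)
        assert res.p_uncorrected == pytest.approx(oracle.p_uncorrected)


class TestRmAnova:
    def test_two_level_f_equals_squared_paired_t(self, rng):
        values = rng.standard_normal((14, 2, 3))
        out = inf.rm_anova_main_effects(values, ["filt", "metric"])
        Y = values.mean(axis=2)
        d = Y[:, 0] - Y[:, 1]
        t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert out.loc["filt", "F"] == pytest.approx(t ** 2, abs=1e-8)
        assert out.loc["filt", "epsilon"] == 1.0

    def test_reference_denominator_df(self, rng):
        values = rng.standard_normal((20, 8))
        out = inf.rm_anova_main_effects(values, ["nuisance"])
        assert out.loc["nuisance", "df2"] == 133  # (8-1) * (20-1)

    def test_identical_cells_degenerate(self):
        values = np.ones((6, 2, 2))
        out = inf.rm_anova_main_effects(values, ["a", "b"])
        assert (out["F"] == 0).all()
        assert (out["p"] == 1.0).all()

    def test_matches_pingouin_oracle(self, rng):
        pg = pytest.importorskip("pingouin")
        values = rng.standard_normal((12, 4)) \
            + 0.5 * rng.standard_normal((12, 1))
        out = inf.rm_anova_main_effects(values, ["factor"])
        long = pd.DataFrame({
            "y": values.ravel(),
            "subject": np.repeat(np.arange(12), 4),
            "level": np.tile(np.arange(4), 12),
        })
        ref = pg.rm_anova(data=long, dv="y", within="level",
                          subject="subject", correction=True)
        assert out.loc["factor", "F"] == pytest.approx(ref["F"][0], rel=1e-6)
        assert out.loc["factor", "epsilon"] == pytest.approx(ref["eps"][0],
                                                             rel=1e-6)
        assert out.loc["factor", "p"] == pytest.approx(ref["p_GG_corr"][0],
                                                       rel=1e-4)

    def test_four_way_grid_shapes(self, rng):
        values = rng.standard_normal((6, 2, 2, 8, 3))
        out = inf.rm_anova_main_effects(values, ["roi", "filt", "nuis", "met"])
        assert list(out.index) == ["roi", "filt", "nuis", "met"]
        assert out.loc["nuis", "df1"] == 7
        assert out.loc["met", "df1"] == 2
        assert ((out["epsilon"] > 0) & (out["epsilon"] <= 1)).all()


class TestFingerprint:
    SEGS = ("C6", "C7", "C8", "T1")

    def test_identical_patterns_distance_means_one(self):
        base = np.array([0.3, 0.25, 0.05, -0.05])
        profiles = {s: np.tile(base, (6, 1)) for s in self.SEGS}
        out = inf.fingerprint_similarity(profiles, n_flips=100, seed=0)
        assert np.allclose(out["mean_r"], 1.0)

    def test_pair_counts_by_distance(self):
        assert [len(inf.SEGMENT_PAIRS[d]) for d in (1, 2, 3)] == [3, 2, 1]

    def test_pairwise_r_matches_four_point_pearson(self, rng):
        profiles = {s: rng.standard_normal((5, 4)) for s in self.SEGS}
        out = inf.fingerprint_similarity(profiles, n_flips=100, seed=0)
        # distance 3 has a single pair C6-T1: verify by hand per subject
        manual = [np.corrcoef(profiles["C6"][i], profiles["T1"][i])[0, 1]
                  for i in range(5)]
        assert out.loc[3, "mean_r"] == pytest.approx(np.mean(manual))

    def test_constant_pattern_skipped_with_warning(self, rng):
        profiles = {s: rng.standard_normal((4, 4)) for s in self.SEGS}
        profiles["C6"][0] = 0.2  # constant 4-vector for one subject
        with pytest.warns(UserWarning, match="constant pattern"):
            out = inf.fingerprint_similarity(profiles, n_flips=100, seed=0)
        assert np.isfinite(out["mean_r"]).all()


class TestPercentPositive:
    @pytest.mark.parametrize("values,expected", [
        (np.ones(7), 100.0),
        (np.array([1.0] * 10 + [-1.0] * 10), 50.0),
        (np.array([1.0] * 18 + [-1.0] * 2), 90.0),
        (np.array([0.0, 1.0]), 50.0),  # zero is not positive
    ])
    def test_examples(self, values, expected):
        assert inf.percent_positive(values) == pytest.approx(expected)


def test_perm_result_validates_p_range():
    with pytest.raises(inf.InferenceError):
        inf.PermResult(stat=1.0, p_uncorrected=0.0, p_fwe=0.5, n_resamples=10)
    with pytest.raises(inf.InferenceError):
        inf.PermResult(stat=1.0, p_uncorrected=0.5, p_fwe=0.2, n_resamples=10)
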