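import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from hdsemg_seating.stats import (
    centroid_anova,
    dunn_adjust,
    fit_rms_mixed_model,
    ks_normality,
    pearson_corr,
    percent_change_by_trial,
    percent_change_table,
    sign_binomial_tail,
    spearman_corr,
    time_change,
    wilcoxon_signed_rank,
)
from hdsemg_seating.synthetic_data import CohortConfig, simulate_rms_table


def brute_force_wilcoxon(d: np.ndarray) -> tuple[float, float, float]:
    """Enumeration oracle: exact signed-rank p-values over all 2^n sign
    assignments of |d| (midranks for ties), zero differences dropped."""
    d = d[d != 0]
    n = d.size
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    ws = np.asarray(ws)
    p_ge = np.mean(ws >= w_obs - 1e-9)
    p_le = np.mean(ws <= w_obs + 1e-9)
    return w_obs, min(1.0, 2 * min(p_ge, p_le)), p_ge


class TestPercentChange:
    @pytest.mark.parametrize(
        "ss,a,expected", [(10.0, 7.0, 30.0), (10.0, 10.0, 0.0), (10.0, 12.0, -20.0)]
    )
    def test_worked_examples(self, ss, a, expected):
        assert percent_change_by_trial(ss, a) == pytest.approx(expected)

    def test_scale_invariance(self, rng):
        for _ in range(20):
            ss, a, s = rng.uniform(0.5, 20, size=3)
            assert percent_change_by_trial(ss * s, a * s) == pytest.approx(
                percent_change_by_trial(ss, a), rel=1e-12
            )

    def test_zero_stool_value_rejected(self):
        with pytest.raises(ValueError):
            percent_change_by_trial(0.0, 5.0)


class TestTimeChange:
    def test_examples(self):
        assert time_change([10.0, 9.0, 8.0]) == pytest.approx(-20.0)
        assert time_change([7.0, 3.0, 7.0]) == pytest.approx(0.0)

    def test_missing_endpoint_rejected(self):
        with pytest.raises(ValueError):
            time_change([np.nan, 5.0])


class TestWilcoxon:
    def test_identical_pairs_give_p_one_with_warning(self):
        with pytest.warns(UserWarning):
            res = wilcoxon_signed_rank(np.arange(5.0), np.arange(5.0))
        assert res.p_two_sided == 1.0
        assert res.n_informative == 0

    def test_six_positive_differences_one_sided_1_over_64(self):
        res = wilcoxon_signed_rank(np.array([1.0, 2.0, 0.5, 3.0, 1.5, 2.5]))
        assert res.p_one_sided == pytest.approx(1 / 64)
        assert res.method == "exact"

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_exact_p_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.normal(0.3, 1.0, size=12)
        res = wilcoxon_signed_rank(d)
        w, p2, p1 = brute_force_wilcoxon(d)
        assert res.statistic == pytest.approx(w)
        assert res.p_two_sided == pytest.approx(p2, abs=1e-12)
        assert res.p_one_sided == pytest.approx(p1, abs=1e-12)

    def test_exact_p_with_ties_matches_enumeration(self):
        d = np.array([1.0, 1.0, -1.0, 2.0, 2.0, -0.5, 3.0, 1.0])
        res = wilcoxon_signed_rank(d)
        w, p2, p1 = brute_force_wilcoxon(d)
        assert res.statistic == pytest.approx(w)
        assert res.p_two_sided == pytest.approx(p2, abs=1e-12)

    def test_matches_scipy_exact_in_no_ties_case(self, rng):
        d = rng.normal(0.5, 1.0, size=15)
        res = wilcoxon_signed_rank(d)
        ref = sps.wilcoxon(d, method="exact")
        assert res.p_two_sided == pytest.approx(ref.pvalue, abs=1e-12)

    def test_normal_approximation_close_to_exact_at_boundary(self, rng):
        d = rng.normal(0.3, 1.0, size=26)  # just beyond the exact limit
        approx = wilcoxon_signed_rank(d)
        exact = wilcoxon_signed_rank(d, exact_limit=30)
        assert approx.method == "normal-approx"
        assert approx.p_two_sided == pytest.approx(exact.p_two_sided, abs=0.01)


class TestDunnAdjust:
    def test_examples(self):
        assert dunn_adjust([0.01]).tolist() == [0.01]
        assert dunn_adjust([0.01, 0.02]).tolist() == [0.02, 0.04]
        assert dunn_adjust([0.6, 0.9]).tolist() == [1.0, 1.0]

    def test_explicit_family_size(self):
        assert dunn_adjust([0.01], family_size=32).tolist() == [0.32]

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            dunn_adjust([1.5])


class TestSignBinomialTail:
    def test_14_of_16_is_137_over_65536(self):
        p = sign_binomial_tail(14, 16)
        assert p == pytest.approx(137 / 65536, abs=0)
        assert p < 0.004

    def test_9_of_9_is_1_over_512(self):
        assert sign_binomial_tail(9, 9) == pytest.approx(1 / 512, abs=0)

    def test_zero_successes_tail_is_one(self):
        assert sign_binomial_tail(0, 7) == 1.0

    def test_point_masses_sum_to_one(self):
        n = 11
        total = sum(
            sign_binomial_tail(k, n) - (sign_binomial_tail(k + 1, n) if k < n else 0.0)
            for k in range(n + 1)
        )
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            sign_binomial_tail(5, 4)


class TestPercentChangeTable:
    def test_per_subject_and_pooled_means(self):
        rows = []
        for subj, eff in [(1, 0.3), (2, 0.5)]:
            for trial in (1, 2, 3, 4, 5, 6):
                ss = 10.0 + 0.1 * trial
                rows.append(dict(subject=subj, chair="SS", side="L", trial_index=trial, rms_roa=ss))
                rows.append(
                    dict(subject=subj, chair="A", side="L", trial_index=trial, rms_roa=ss * (1 - eff))
                )
        table = percent_change_table(pd.DataFrame(rows))
        per = table[table["subject"] != "Total"].set_index("subject")
        assert per.loc[1, "mean_pct_change"] == pytest.approx(30.0)
        assert per.loc[2, "mean_pct_change"] == pytest.approx(50.0)
        pooled = table[table["subject"] == "Total"]
        assert pooled["mean_pct_change"].iloc[0] == pytest.approx(40.0)

    def test_duplicate_rows_rejected(self):
        df = pd.DataFrame(
            [
                dict(subject=1, chair="SS", side="L", trial_index=1, rms_roa=1.0),
                dict(subject=1, chair="SS", side="L", trial_index=1, rms_roa=2.0),
            ]
        )
        with pytest.raises(ValueError, match="duplicate"):
            percent_change_table(df)


class TestMixedModel:
    def test_single_subject_rejected(self):
        tab = simulate_rms_table(CohortConfig(n_subjects=1, n_trials=4, seed=0))
        with pytest.raises(ValueError, match="two subjects"):
            fit_rms_mixed_model(tab)

    def test_single_chair_rejected(self):
        tab = simulate_rms_table(CohortConfig(n_subjects=3, n_trials=4, seed=0))
        with pytest.raises(ValueError, match="singular"):
            fit_rms_mixed_model(tab[tab["chair"] == "SS"])

    def test_chair_and_side_effects_detected_at_study_effect_sizes(self):
        """With the study-like 30/35% chair effect and right-side dominance,
        the chair and side fixed effects are significant in (nearly) every
        replicate (scaled-down power check)."""
        hits = 0
        reps = 10
        for rep in range(reps):
            tab = simulate_rms_table(CohortConfig(n_subjects=16, n_trials=12, seed=300 + rep))
            res = fit_rms_mixed_model(tab)
            hits += (res["fixed"]["chair"]["p"] < 0.01) and (res["fixed"]["side"]["p"] < 0.01)
        assert hits >= reps - 1

    def test_zero_effect_type_i_rate(self):
        """With no chair effect the chair term rejects at roughly alpha."""
        rejections = 0
        reps = 40
        for rep in range(reps):
            tab = simulate_rms_table(
                CohortConfig(
                    n_subjects=8,
                    n_trials=6,
                    seed=700 + rep,
                    chair_effect_pct=(0, 0),
                    subject_effect_sd_pct=0,
                )
            )
            res = fit_rms_mixed_model(tab)
            rejections += res["fixed"]["chair"]["p"] < 0.05
        assert rejections <= 0.20 * reps

    def test_reporting_contract(self):
        tab = simulate_rms_table(CohortConfig(n_subjects=6, n_trials=6, seed=42))
        res = fit_rms_mixed_model(tab)
        assert set(res["fixed"]) == {"chair", "side"}
        assert 0 <= res["r2_marginal"] <= res["r2_conditional"] <= 1
        assert res["residual_sd"] > 0
        assert res["subject_random_effect"]["p"] <= 1


class TestCentroidAnova:
    def _track(self, shift_x=0.0, seed=0, n_subj=6):
        rng = np.random.default_rng(seed)
        rows = []
        for subj in range(1, n_subj + 1):
            sx, sy = rng.normal(0, 2, size=2)
            for chair in ("SS", "A"):
                for side in ("L", "R"):
                    for trial in range(1, 7):
                        rows.append(
                            dict(
                                subject=subj,
                                chair=chair,
                                side=side,
                                trial_index=trial,
                                x_cm_mm=30 + sx + (shift_x if chair == "A" else 0) + rng.normal(0, 1.5),
                                y_cm_mm=70 + sy + rng.normal(0, 1.5),
                            )
                        )
        return pd.DataFrame(rows)

    def test_no_drift_chair_effect_usually_null(self):
        ps = [centroid_anova(self._track(seed=s))["x_cm_mm"]["chair"]["p"] for s in range(12)]
        # under the null the p-values are uniform: most replicates accept
        assert sum(p < 0.05 for p in ps) <= 4
        assert np.mean(ps) > 0.2

    def test_injected_shift_detected(self):
        hits = sum(
            centroid_anova(self._track(shift_x=5.0, seed=s))["x_cm_mm"]["chair"]["p"] < 0.05
            for s in range(10)
        )
        assert hits >= 9

    def test_constant_centroids_never_significant(self):
        track = self._track(seed=1)
        track["x_cm_mm"] = 30.0  # no variation at all
        res = centroid_anova(track)
        sq = res["x_cm_mm"]["chair"]
        # all sums of squares are numerical zeros: no effect can be claimed
        assert math.isnan(sq["F"]) or not (sq["p"] < 0.05)

    def test_incomplete_design_rejected(self):
        track = self._track()
        with pytest.raises(ValueError, match="incomplete"):
            centroid_anova(track[track["chair"] == "SS"])


class TestCorrelations:
    def test_spearman_perfect_monotone(self):
        x = np.array([1.0, 2, 3, 4, 5, 6])
        assert spearman_corr(x, x**3)["rho"] == pytest.approx(1.0)
        assert spearman_corr(x, -x)["rho"] == pytest.approx(-1.0)

    def test_spearman_matches_rank_formula_no_ties(self, rng):
        x = rng.permutation(6).astype(float)
        y = rng.permutation(6).astype(float)
        d = sps.rankdata(x) - sps.rankdata(y)
        rho_formula = 1 - 6 * np.sum(d**2) / (6 * (6**2 - 1))
        assert spearman_corr(x, y)["rho"] == pytest.approx(rho_formula, abs=1e-12)

    def test_spearman_validation(self):
        with pytest.raises(ValueError):
            spearman_corr([1, 1, 1, 1], [1, 2, 3, 4])

    def test_pearson_affine(self):
        x = np.arange(10.0)
        res = pearson_corr(x, 2 * x + 1)
        assert res["r"] == pytest.approx(1.0)

    def test_pearson_independent_small_r(self, rng):
        x = rng.normal(size=1000)
        y = rng.normal(size=1000)
        assert abs(pearson_corr(x, y)["r"]) < 0.1

    def test_ks_normality_calibration(self, rng):
        normal_p = ks_normality(rng.normal(size=500))["p"]
        uniform_p = ks_normality(rng.uniform(size=500))["p"]
        assert normal_p > 0.01
        assert uniform_p < 0.01
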