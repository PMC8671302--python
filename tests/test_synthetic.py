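import math

import numpy as np
import pandas as pd
import pytest

from hdsemg_seating.core import ElectrodeGridSpec
from hdsemg_seating.preprocess import channel_rms, single_differential
from hdsemg_seating.synthetic_data import (
    CohortConfig,
    make_activity_truth,
    simulate_cohort,
    simulate_questionnaires,
    simulate_rms_table,
    simulate_trial,
)


def _short(grid: ElectrodeGridSpec, **kw):
    """A 2 s epoch is long enough for RMS estimates at the few-percent level."""
    defaults = dict(epoch_s=2.0, seed=7)
    defaults.update(kw)
    return defaults


class TestActivityTruth:
    def test_bump_is_medial_and_positive(self, grid):
        right = make_activity_truth(grid, side="R")
        left = make_activity_truth(grid, side="L")
        # medial column is C1 (x=0) on the right grid, C8 on the left
        assert right.center_true_mm[0] < left.center_true_mm[0]
        assert (right.amplitude_map >= 0).all()
        assert right.roa_mask_true.any()

    def test_scaling_preserves_mask_and_scales_amplitude(self, grid):
        t = make_activity_truth(grid, side="R")
        t2 = t.scaled(0.5)
        assert np.array_equal(t.roa_mask_true, t2.roa_mask_true)
        assert np.allclose(t2.amplitude_map, 0.5 * t.amplitude_map)

    def test_negative_amplitude_rejected(self, grid):
        t = make_activity_truth(grid)
        t.amplitude_map[0, 0] = 1.0
        from hdsemg_seating.synthetic_data import ActivityGroundTruth

        with pytest.raises(ValueError):
            ActivityGroundTruth(
                amplitude_map=-np.ones((15, 8)),
                roa_mask_true=np.ones((15, 8), bool),
                center_true_mm=(0, 0),
            )


class TestSimulateTrial:
    def test_noise_only_differential_rms_is_sqrt2(self, grid):
        """Independent 1 uV noise on adjacent electrodes -> sqrt(2) uV
        differential channels."""
        t = make_activity_truth(grid, peak_uv=0.0, background_uv=0.0)
        ep = simulate_trial(
            grid,
            t,
            electrode_noise_uv=1.0,
            interference_uv=0.0,
            ecg_uv=0.0,
            **_short(grid),
        )
        rms = channel_rms(np.diff(ep.samples, axis=0))
        assert rms.mean() == pytest.approx(math.sqrt(2), rel=0.02)

    def test_common_mode_ecg_cancels_in_differential(self, grid):
        """The ECG artifact is identical on every electrode, so the
        single-differential montage removes it exactly."""
        t = make_activity_truth(grid, peak_uv=0.0, background_uv=0.0)
        ep = simulate_trial(
            grid,
            t,
            electrode_noise_uv=0.0,
            interference_uv=0.0,
            ecg_uv=200.0,
            **_short(grid),
        )
        assert channel_rms(ep.samples).max() > 10  # ECG present monopolarly
        diff = single_differential(ep)
        assert np.abs(diff.samples).max() < 1e-9

    def test_differential_rms_matches_amplitude_map(self, grid):
        t = make_activity_truth(grid, peak_uv=15.0, background_uv=3.0, sigma_mm=(12, 25))
        ep = simulate_trial(
            grid, t, electrode_noise_uv=0.0, interference_uv=0.0, ecg_uv=0.0, **_short(grid)
        )
        rms = channel_rms(np.diff(ep.samples, axis=0))
        assert np.allclose(rms, t.amplitude_map, rtol=1e-5)

    def test_energy_bookkeeping(self, grid):
        """Per-channel monopolar variance decomposes into the component
        variances (activity + ECG + interference + noise) within 2%."""
        t = make_activity_truth(grid)
        zero = make_activity_truth(grid, peak_uv=0.0, background_uv=0.0)
        kw = _short(grid, epoch_s=20.0)
        full = simulate_trial(grid, t, **kw).samples
        parts = [
            simulate_trial(grid, t, electrode_noise_uv=0.0, interference_uv=0.0, ecg_uv=0.0, **kw).samples,
            simulate_trial(grid, zero, electrode_noise_uv=0.0, interference_uv=0.0, **kw).samples,
            simulate_trial(grid, zero, electrode_noise_uv=0.0, ecg_uv=0.0, **kw).samples,
            simulate_trial(grid, zero, interference_uv=0.0, ecg_uv=0.0, **kw).samples,
        ]
        # identical seed => identical component realizations, so the parts
        # literally sum to the full signal and variances must add
        assert np.allclose(sum(parts), full, atol=1e-3)
        var_full = full.var(axis=-1)
        var_sum = sum(p.var(axis=-1) for p in parts)
        ratio = var_sum / var_full
        assert np.all(np.abs(ratio - 1) < 0.02)

    def test_burst_envelope_preserves_target_rms(self, grid):
        t = make_activity_truth(grid, burst_params=((100.0, 390.0), (1.5, 2.5)))
        ep = simulate_trial(
            grid, t, electrode_noise_uv=0.0, interference_uv=0.0, ecg_uv=0.0, **_short(grid, epoch_s=10.0)
        )
        rms = channel_rms(np.diff(ep.samples, axis=0))
        assert np.allclose(rms, t.amplitude_map, rtol=1e-5)
        # on/off modulation leaves silent gaps in the signal
        one = np.diff(ep.samples, axis=0)[7, 1]
        win = np.abs(one.reshape(-1, 256)).max(axis=1)
        assert (win < 1e-6 * np.abs(one).max()).any()

    def test_seed_determinism(self, grid):
        t = make_activity_truth(grid)
        a = simulate_trial(grid, t, **_short(grid)).samples
        b = simulate_trial(grid, t, **_short(grid)).samples
        c = simulate_trial(grid, t, **_short(grid, seed=8)).samples
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_dimension_mismatch_rejected(self, grid, small_grid):
        t = make_activity_truth(small_grid)
        with pytest.raises(ValueError):
            simulate_trial(grid, t, **_short(grid))


class TestSimulateCohort:
    def test_epoch_count_is_chairs_by_sides_by_trials(self, small_grid):
        cfg = CohortConfig(n_subjects=1, n_trials=2, epoch_s=0.5, grid=small_grid, seed=3)
        out = list(simulate_cohort(cfg))
        assert len(out) == 8  # 2 chairs x 2 sides x 2 trials
        keys = {(k.chair, k.side, k.trial_index) for k, _, _ in out}
        assert len(keys) == 8

    def test_cohort_determinism(self, small_grid):
        cfg = CohortConfig(n_subjects=1, n_trials=2, epoch_s=0.5, grid=small_grid, seed=3)
        a = [e.samples for _, e, _ in simulate_cohort(cfg)]
        b = [e.samples for _, e, _ in simulate_cohort(cfg)]
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_a_chair_amplitude_reduced(self, small_grid):
        cfg = CohortConfig(
            n_subjects=2,
            n_trials=2,
            epoch_s=0.5,
            grid=small_grid,
            seed=5,
            subject_effect_sd_pct=0.0,
            trial_jitter_sigma=0.0,
        )
        truths = {(k.chair, k.subject_id, k.side, k.trial_index): t for k, _, t in simulate_cohort(cfg)}
        for (chair, subj, side, trial), t in truths.items():
            if chair == "A":
                ss = truths[("SS", subj, side, trial)]
                expected = 1 - (30.0 if side == "L" else 35.0) / 100
                np.testing.assert_allclose(
                    t.amplitude_map.sum() / ss.amplitude_map.sum(), expected, rtol=0.2
                )

    def test_config_validation(self):
        with pytest.raises(ValueError):
            CohortConfig(n_trials=1)
        with pytest.raises(ValueError):
            CohortConfig(noise_rms_uv=-1)


class TestRmsTableFastPath:
    def test_structure_and_determinism(self):
        cfg = CohortConfig(n_subjects=3, n_trials=4, seed=9)
        a = simulate_rms_table(cfg)
        b = simulate_rms_table(cfg)
        pd.testing.assert_frame_equal(a, b)
        assert len(a) == 3 * 2 * 2 * 4
        assert (a["rms_roa"] > 0).all()
        assert set(a["chair"]) == {"SS", "A"}

    def test_injected_effect_visible_in_chair_means(self):
        cfg = CohortConfig(n_subjects=8, n_trials=12, seed=11)
        tab = simulate_rms_table(cfg)
        by = tab.groupby(["side", "chair"])["rms_roa"].mean().unstack("chair")
        for side in ("L", "R"):
            assert by.loc[side, "A"] < by.loc[side, "SS"]

    def test_zero_effect_gives_no_systematic_difference(self):
        cfg = CohortConfig(
            n_subjects=16, n_trials=12, seed=13, chair_effect_pct=(0, 0), subject_effect_sd_pct=0
        )
        tab = simulate_rms_table(cfg)
        by = tab.groupby("chair")["rms_roa"].mean()
        assert abs(by["A"] / by["SS"] - 1) < 0.03


class TestQuestionnaires:
    def test_scores_within_scale_ranges(self):
        q = simulate_questionnaires(n_subjects=8, seed=1)
        gcr = q[q["instrument"] == "GCR"]["score"]
        hz = q[q["instrument"].isin(["HZc", "HZd"])]["score"]
        bpd = q[q["instrument"] == "BPD"]["score"]
        assert gcr.between(1, 10).all() and hz.between(1, 10).all() and bpd.between(0, 10).all()
        assert (q["score"] == q["score"].astype(int)).all()

    def test_counts_per_session(self):
        q = simulate_questionnaires(n_subjects=2, seed=2)
        counts = q.groupby(["subject", "chair", "instrument"])["item"].count().unstack()
        assert (counts["GCR"] == 1).all()
        assert (counts["HZc"] == 7).all()
        assert (counts["HZd"] == 9).all()
        assert (counts["BPD"] == 10).all()

    def test_zero_effect_paired_t_type_i(self):
        """With no injected chair effect, per-statement paired t-tests reject
        at roughly the nominal 5% rate."""
        from scipy import stats as sps

        rejections = 0
        total = 0
        for rep in range(40):
            q = simulate_questionnaires(n_subjects=16, seed=100 + rep, effect="none")
            hz = q[q["instrument"].isin(["HZc", "HZd"])]
            for item, g in hz.groupby("item"):
                piv = g.pivot(index="subject", columns="chair", values="score")
                d = piv["A"] - piv["SS"]
                if d.std() == 0:
                    continue
                p = sps.ttest_rel(piv["A"], piv["SS"]).pvalue
                rejections += p < 0.05
                total += 1
        rate = rejections / total
        assert 0.005 < rate < 0.12

    def test_like_statement_mean_shift_matches_configuration(self):
        q = simulate_questionnaires(n_subjects=200, seed=5)
        like = q[(q["item"] == "I like the chair")]
        means = like.groupby("chair")["score"].mean()
        # configured group means 7.27 (A) vs 5.00 (SS): decrease ~2.27
        assert means["A"] - means["SS"] == pytest.approx(2.27, abs=0.35)

    def test_invalid_effect_rejected(self):
        with pytest.raises(ValueError):
            simulate_questionnaires(effect="huge")
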