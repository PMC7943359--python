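import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stereorsa import mousetracking as mt
from stereorsa.rsa import neural_dm
from stereorsa.stereotype import congruency_dm, scores_table
from stereorsa.synthetic import (DesignSpec, GroundTruth, SignalRegion,
                                 gen_bold_session, gen_discrimination,
                                 gen_patterns, gen_ratings, gen_trajectories,
                                 gen_volume_dataset, make_schedule)


def quiet_truth(**kw):
    noise = {"md": 0.0, "md_subject": 0.0, "ratings": 0.0, "pattern": 0.0,
             "bold": 0.0}
    noise.update(kw.pop("noise_sds", {}))
    return GroundTruth(noise_sds=noise, **kw)


class TestSchedule:
    def test_every_event_lasts_one_tr(self):
        sched = make_schedule(DesignSpec(seed=1))
        assert (sched["duration"] == 2.0).all()
        assert np.allclose(sched["onset"] % 2.0, 0.0)

    def test_event_composition_per_run(self):
        spec = DesignSpec(seed=2)
        sched = make_schedule(spec)
        for _, run in sched.groupby("run"):
            assert (run["condition"] == "null").sum() == spec.n_null_events
            # half the faces, each twice
            assert (run["condition"] != "null").sum() == spec.n_faces
            counts = run[run["face_id"] >= 0]["face_id"].value_counts()
            assert (counts == 2).all() and len(counts) == spec.n_faces // 2

    def test_masked_runs_precede_unmasked(self):
        sched = make_schedule(DesignSpec(seed=3))
        first_unmasked = sched[sched["masking"] == "unmasked"]["run"].min()
        assert (sched[sched["masking"] == "masked"]["run"]
                < first_unmasked).all()

    def test_zero_nulls_empty_case(self):
        sched = make_schedule(DesignSpec(n_null_events=0, seed=0))
        assert (sched["condition"] != "null").all()

    def test_deterministic_under_seed(self):
        a = make_schedule(DesignSpec(seed=7))
        b = make_schedule(DesignSpec(seed=7))
        pd.testing.assert_frame_equal(a, b)

    @pytest.mark.parametrize("kw", [
        {"n_faces_per_cell": 0}, {"n_null_events": -1}, {"n_runs": 3},
        {"trial_duration_ms": 1500},
    ])
    def test_invalid_specs_rejected(self, kw):
        with pytest.raises(ValueError):
            DesignSpec(seed=0, **kw)


class TestRatings:
    def test_noiseless_extreme_bias_exact(self):
        df, _ = gen_ratings(5, 2.0, 0.0, 0.0, seed=1, amp=0.8)
        scores = scores_table(df)["score"]
        assert np.allclose(scores, 2.0)

    def test_rating_trials_and_scale(self):
        df, _ = gen_ratings(3, 0.5, 0.3, 0.3, seed=2)
        per_subject = df.groupby("subject").size()
        assert (per_subject == 120).all()
        assert df["rating"].between(1, 7).all()

    def test_zero_bias_monte_carlo(self):
        df, _ = gen_ratings(200, 0.0, 0.0, 0.3, seed=3)
        scores = scores_table(df)["score"]
        se = scores.std(ddof=1) / np.sqrt(len(scores))
        assert abs(scores.mean()) < 2 * se + 1e-9

    def test_recovery_tracks_planted_bias(self):
        df, planted = gen_ratings(120, 0.49, 0.62, 0.3, seed=4)
        scores = scores_table(df).set_index("subject")["score"]
        resid = scores.to_numpy() - planted
        se = resid.std(ddof=1) / np.sqrt(len(resid))
        assert abs(resid.mean()) < 2 * se + 5e-3
        assert np.corrcoef(scores, planted)[0, 1] > 0.9

    def test_deterministic_and_bounds(self):
        a, _ = gen_ratings(4, 1.0, 0.0, 0.2, seed=9)
        b, _ = gen_ratings(4, 1.0, 0.0, 0.2, seed=9)
        pd.testing.assert_frame_equal(a, b)
        with pytest.raises(ValueError):
            gen_ratings(2, 2.5, 0.1, 0.1, seed=0)


class TestTrajectories:
    def test_null_effects_md_identical_across_conditions(self):
        truth = quiet_truth(congruency_effect=0.0, moderation=0.0)
        ts = gen_trajectories(np.array([0.5, 0.2]), truth,
                              n_faces_per_cell=4, timeout_rate=0,
                              error_rate=0, seed=5)
        m = mt.metrics_table(ts.t_ms, ts.xy,
                             ts.trials["response_side"].to_numpy())
        by_cond = ts.trials.join(m).groupby("condition")["md"].mean()
        assert by_cond.max() - by_cond.min() < 1e-3

    def test_congruency_effect_recovered(self):
        truth = quiet_truth(congruency_effect=0.075, moderation=0.0,
                            noise_sds={"md": 0.2})
        ts = gen_trajectories(np.full(30, 0.49), truth, seed=6,
                              timeout_rate=0, error_rate=0)
        m = mt.metrics_table(ts.t_ms, ts.xy,
                             ts.trials["response_side"].to_numpy())
        trials = ts.trials.join(m)
        incong = trials["condition"].isin(["angry_female", "happy_male"])
        diff = trials.loc[incong, "md"].mean() - trials.loc[~incong, "md"].mean()
        assert diff == pytest.approx(0.075, abs=0.02)

    def test_timeout_rate_binomial_band(self):
        truth = quiet_truth()
        n_trials = 1000
        ts = gen_trajectories(np.array([0.5]), truth,
                              n_faces_per_cell=125,   # 2 blocks x 4 x 125
                              timeout_rate=0.1, error_rate=0, seed=7)
        assert len(ts.trials) == n_trials
        n_to = int((ts.trials["rt_ms"] > 2000).sum())
        lo, hi = stats.binom.ppf([0.005, 0.995], n_trials, 0.1)
        assert lo <= n_to <= hi
        assert (ts.trials["timeout"].sum()) == n_to

    def test_rates_validated_and_deterministic(self):
        truth = quiet_truth()
        with pytest.raises(ValueError):
            gen_trajectories(np.array([0.0]), truth, 2, timeout_rate=1.2)
        a = gen_trajectories(np.array([0.1]), truth, 3, seed=8)
        b = gen_trajectories(np.array([0.1]), truth, 3, seed=8)
        np.testing.assert_array_equal(a.xy, b.xy)

    def test_paths_start_at_origin_and_end_at_target(self):
        ts = gen_trajectories(np.array([0.3]), quiet_truth(), 3, seed=9,
                              timeout_rate=0, error_rate=0)
        np.testing.assert_allclose(ts.xy[:, 0, :], 0.0)
        for i in range(len(ts.trials)):
            m = ~np.isnan(ts.t_ms[i])
            end = ts.xy[i, m][-1]
            sx = 1.0 if ts.trials.loc[i, "response_side"] == "right" else -1.0
            np.testing.assert_allclose(end, [sx, 1.5], atol=1e-9)


class TestPatterns:
    def test_identity_target_sampling_band(self):
        from stereorsa.core import DissimilarityMatrix
        dm = DissimilarityMatrix(np.ones((4, 4)) - np.eye(4))
        pats = gen_patterns(dm, 10000, 0.0, seed=1)
        realized = neural_dm(pats).values
        off = realized[~np.eye(4, dtype=bool)]
        assert np.all(np.abs(off - 1.0) < 0.05)

    def test_perfect_correlation_distance_zero(self):
        from stereorsa.core import DissimilarityMatrix
        vals = np.zeros((4, 4))
        vals[2:, :2] = vals[:2, 2:] = 1.0
        dm = DissimilarityMatrix(vals)   # two pairs of identical conditions
        pats = gen_patterns(dm, 200, 0.0, seed=2)
        assert neural_dm(pats).values[0, 1] == pytest.approx(0.0, abs=1e-10)

    def test_non_psd_target_rejected(self):
        with pytest.raises(ValueError, match="eigenvalue"):
            gen_patterns(congruency_dm(), 100)

    def test_deterministic(self, valid_dm):
        np.testing.assert_array_equal(gen_patterns(valid_dm, 50, 0.1, seed=3),
                                      gen_patterns(valid_dm, 50, 0.1, seed=3))


class TestBoldSession:
    def _schedule(self):
        return make_schedule(DesignSpec(n_faces_per_cell=4, n_null_events=8,
                                        seed=4))

    def test_null_coupling_noiseless_target_equals_seed(self):
        truth = quiet_truth(ppi_coupling=0.0)
        s = gen_bold_session(self._schedule(), truth, noise_sd=0.0, a=1.0)
        np.testing.assert_allclose(s.target_bold, s.seed_bold, atol=1e-12)

    def test_condition_coding_follows_masking(self):
        s = gen_bold_session(self._schedule(), quiet_truth(), noise_sd=0.0)
        assert set(np.unique(s.condition)) == {-1.0, 1.0}
        assert (s.condition[s.run <= 2] == -1.0).all()

    def test_single_masking_schedule_rejected(self):
        sched = self._schedule()
        with pytest.raises(ValueError, match="both"):
            gen_bold_session(sched[sched["masking"] == "masked"],
                             quiet_truth())


class TestVolumes:
    def test_signal_region_carries_planted_structure(self, valid_dm):
        ds = gen_volume_dataset((10, 10, 10),
                                [SignalRegion((5, 5, 5), 3.0)],
                                [valid_dm], noise_sd=1.0,
                                signal_noise_sd=0.0, seed=5)
        inside = ds.region_labels > 0
        realized = neural_dm(ds.volumes[0][:, inside]).values
        assert np.abs(realized - valid_dm.values).max() < 0.35
        assert inside.sum() == 123

    def test_overlap_and_fit_rejected(self, valid_dm):
        with pytest.raises(ValueError, match="overlap"):
            gen_volume_dataset((10, 10, 10),
                               [SignalRegion((5, 5, 5), 3.0, 1),
                                SignalRegion((6, 5, 5), 3.0, 2)],
                               [valid_dm], seed=0)
        with pytest.raises(ValueError, match="fit"):
            gen_volume_dataset((10, 10, 10),
                               [SignalRegion((1, 5, 5), 3.0)],
                               [valid_dm], seed=0)

    def test_deterministic(self, valid_dm):
        a = gen_volume_dataset((8, 8, 8), [], [valid_dm], seed=6)
        b = gen_volume_dataset((8, 8, 8), [], [valid_dm], seed=6)
        np.testing.assert_array_equal(a.volumes[0], b.volumes[0])


def test_discrimination_recovers_planted_sensitivity():
    from stereorsa.behavior import dprime_table
    responses, planted = gen_discrimination(60, 35, dprime_mean=0.22,
                                            dprime_sd=0.0, seed=7)
    table = dprime_table(responses)
    assert table["d_prime"].mean() == pytest.approx(0.22, abs=0.1)
    assert set(responses["gender"]) == {"male", "female"}
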