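import numpy as np
import pandas as pd
import pytest

from stereorsa import mousetracking as mt
from stereorsa.synthetic import GroundTruth, gen_trajectories


def make_trial(t, xy, side="right", **kw):
    defaults = dict(subject_id="s0", block="gender", condition="angry_male",
                    chosen_response="male", rt_ms=float(t[-1]))
    defaults.update(kw)
    return mt.TrialTrajectory(t_ms=np.asarray(t, float),
                              xy=np.asarray(xy, float),
                              response_side=side, **defaults)


def md_oracle(coords):
    """Brute force: signed point-line distance of the farthest point."""
    best = 0.0
    for x, y in coords:
        d = (1.0 * y - 1.5 * x) / np.hypot(1.0, 1.5)
        if abs(d) > abs(best):
            best = d
    return best


class TestExclusion:
    def _trials(self):
        rows = []
        for i in range(10):
            rows.append({"subject": 0, "condition": "angry_male",
                         "rt_ms": 1000.0, "correct": True})
        df = pd.DataFrame(rows)
        df.loc[0, "rt_ms"] = 2100.0
        df.loc[[1, 2], "correct"] = False
        return df

    def test_hand_counted_case(self):
        retained, report = mt.exclude_trials(self._trials())
        assert len(retained) == 7
        assert report["n_timeout"] == 1 and report["n_incorrect"] == 2
        assert report["frac_retained"] == pytest.approx(0.7)

    def test_all_good_is_identity(self):
        df = self._trials().assign(rt_ms=1500.0, correct=True)
        retained, _ = mt.exclude_trials(df)
        assert len(retained) == len(df)

    def test_deadline_boundary_retained(self):
        df = self._trials().assign(correct=True)
        df.loc[0, "rt_ms"] = 2000.0   # deadline must be *exceeded*
        retained, _ = mt.exclude_trials(df)
        assert len(retained) == 10

    def test_empty_cell_raises_with_cell_name(self):
        df = self._trials()
        df.loc[df["condition"] == "angry_male", "correct"] = False
        with pytest.raises(ValueError, match="angry_male"):
            mt.exclude_trials(df)


class TestNormalization:
    def test_straight_line_preserved(self):
        traj = make_trial([0, 500, 1000], [[0, 0], [0.5, 0.75], [1, 1.5]])
        n = mt.normalize_trajectory(traj)
        assert n.coords.shape == (101, 2)
        np.testing.assert_allclose(n.coords[0], [0, 0])
        np.testing.assert_allclose(n.coords[-1], [1, 1.5])
        np.testing.assert_allclose(n.coords[:, 1], 1.5 * n.coords[:, 0],
                                   atol=1e-12)

    def test_left_response_mirrored(self):
        path = [[0, 0], [-0.3, 0.7], [-1, 1.5]]
        left = mt.normalize_trajectory(make_trial([0, 400, 900], path, "left"))
        right = mt.normalize_trajectory(
            make_trial([0, 400, 900], np.asarray(path) * [-1, 1], "right"))
        np.testing.assert_allclose(left.coords, right.coords)

    def test_irregular_times_hand_interpolation(self):
        # three samples at 0/300/1000 ms, querying the 50-bin grid by hand
        traj = make_trial([0, 300, 1000], [[0, 0], [0.6, 0.3], [1, 1.5]])
        n = mt.normalize_trajectory(traj, n_bins=2)
        # midpoint of the grid is t=500 ms: between samples 2 and 3
        frac = (500 - 300) / (1000 - 300)
        np.testing.assert_allclose(
            n.coords[1], [0.6 + frac * 0.4, 0.3 + frac * 1.2])

    def test_start_translated_to_origin(self):
        traj = make_trial([0, 500, 1000], [[2, 3], [2.5, 3.75], [3, 4.5]])
        assert tuple(mt.normalize_trajectory(traj).coords[0]) == (0.0, 0.0)


class TestMaximumDeviation:
    def test_straight_line_zero(self):
        coords = np.column_stack([np.linspace(0, 1, 101),
                                  np.linspace(0, 1.5, 101)])
        assert mt.compute_md(coords).md == pytest.approx(0.0)

    def test_planar_point_line_example(self):
        coords = np.array([[0, 0], [-0.5, 0.75], [1, 1.5]])
        m = mt.compute_md(coords)
        assert m.md == pytest.approx(1.5 / np.sqrt(3.25))

    def test_bulge_toward_chosen_side_clamps(self):
        u = np.linspace(0, 1, 101)
        chord = np.column_stack([u, 1.5 * u])
        normal = np.array([-1.5, 1]) / np.hypot(1, 1.5)
        coords = chord - (2 * u * (1 - u))[:, None] * 0.4 * normal
        m = mt.compute_md(coords)
        assert m.md < 0 and m.md_norm == 0.0

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(100):
            k = rng.integers(5, 40)
            coords = np.cumsum(rng.normal(0, 0.1, (k, 2)), axis=0)
            coords[0] = 0
            assert mt.compute_md(coords).md == pytest.approx(
                md_oracle(coords), abs=1e-12)

    def test_mirroring_invariance(self, rng):
        t = np.sort(rng.uniform(0, 1000, 20))
        t[0] = 0.0
        xy = np.cumsum(rng.normal(0, 0.1, (20, 2)), axis=0)
        right = make_trial(t, xy, "right")
        left = make_trial(t, xy * [-1, 1], "left")
        md_r = mt.compute_md(mt.normalize_trajectory(right)).md
        md_l = mt.compute_md(mt.normalize_trajectory(left)).md
        assert md_r == pytest.approx(md_l)

    def test_batch_matches_single_trial_path(self, rng):
        truth = GroundTruth()
        ts = gen_trajectories(np.array([0.5, 0.1]), truth, n_faces_per_cell=3,
                              seed=rng)
        sides = ts.trials["response_side"].to_numpy()
        batch = mt.metrics_table(ts.t_ms, ts.xy, sides)
        for i in (0, 5, 11):
            m = ~np.isnan(ts.t_ms[i])
            traj = make_trial(ts.t_ms[i, m], ts.xy[i, m], sides[i])
            single = mt.compute_md(mt.normalize_trajectory(traj))
            assert batch.loc[i, "md"] == pytest.approx(single.md)


class TestBiasVectors:
    def test_hand_arithmetic(self):
        vec = mt.condition_bias_vector({"emotion": 0.2, "gender": 0.1},
                                       "angry_male")
        np.testing.assert_allclose(vec, [0.8, 0.2, 0.9, 0.1])

    def test_uniform_half(self):
        vec = mt.condition_bias_vector({"emotion": 0.5, "gender": 0.5},
                                       "happy_female")
        np.testing.assert_allclose(vec, 0.5)

    def test_zero_deviation_is_one_hot_pairs(self):
        vec = mt.condition_bias_vector({"emotion": 0.0, "gender": 0.0},
                                       "happy_female")
        np.testing.assert_allclose(vec, [0.0, 1.0, 0.0, 1.0])

    def test_missing_block_raises(self):
        with pytest.raises(ValueError, match="gender"):
            mt.condition_bias_vector({"emotion": 0.2}, "angry_male")

    def test_block_pair_similarities_sum_to_one(self):
        vec = mt.condition_bias_vector({"emotion": 0.37, "gender": 0.12},
                                       "angry_female")
        assert vec[0] + vec[1] == pytest.approx(1.0)
        assert vec[2] + vec[3] == pytest.approx(1.0)


class TestSubjectiveDm:
    def test_identical_and_affine_vectors_distance_zero(self):
        v = np.array([0.8, 0.2, 0.9, 0.1])
        mat = np.stack([v, v, 3 + 2 * v, 1 - v])
        dm = mt.subjective_dm(mat)
        assert dm.values[0, 1] == pytest.approx(0.0)
        assert dm.values[0, 2] == pytest.approx(0.0)   # affine-invariant
        assert dm.values[0, 3] == pytest.approx(2.0)   # mirrored ranks

    def test_constant_vector_rejected(self):
        mat = np.stack([np.full(4, 0.5), np.arange(4.0),
                        np.arange(4.0), np.arange(4.0)])
        with pytest.raises(ValueError, match="zero-variance"):
            mt.subjective_dm(mat)

    def test_group_average_is_mean_then_distance(self, rng):
        a = rng.uniform(0.1, 0.9, (4, 4))
        b = rng.uniform(0.1, 0.9, (4, 4))
        group = mt.group_average_dm([a, b])
        np.testing.assert_allclose(
            group.values, mt.subjective_dm((a + b) / 2).values)
        # single subject and duplicated subjects reduce to the subject DM
        np.testing.assert_allclose(mt.group_average_dm([a]).values,
                                   mt.subjective_dm(a).values)
        np.testing.assert_allclose(mt.group_average_dm([a, a]).values,
                                   mt.subjective_dm(a).values)

    def test_produced_dms_are_valid(self, rng):
        truth = GroundTruth()
        ts = gen_trajectories(rng.normal(0.5, 0.5, 4), truth,
                              n_faces_per_cell=6, seed=rng)
        m = mt.metrics_table(ts.t_ms, ts.xy,
                             ts.trials["response_side"].to_numpy())
        retained, _ = mt.exclude_trials(ts.trials.join(m))
        dms, group = mt.subject_dms(retained)
        for dm in list(dms.values()) + [group]:
            assert np.all(dm.values >= 0) and np.all(dm.values <= 2)
            np.testing.assert_allclose(dm.values, dm.values.T)
            np.testing.assert_allclose(np.diag(dm.values), 0)


def test_trajectory_csv_round_trip(tmp_path, rng):
    truth = GroundTruth()
    ts = gen_trajectories(np.array([0.3]), truth, n_faces_per_cell=2, seed=rng)
    path = tmp_path / "traj.csv"
    mt.write_trajectories_csv(path, ts.trials, ts.t_ms, ts.xy)
    trials, t_ms, xy = mt.read_trajectories_csv(path)
    assert len(trials) == len(ts.trials)
    m1 = mt.metrics_table(ts.t_ms, ts.xy, ts.trials["response_side"].to_numpy())
    m2 = mt.metrics_table(t_ms, xy, trials["response_side"].to_numpy())
    np.testing.assert_allclose(m1["md"], m2["md"], atol=1e-9)
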