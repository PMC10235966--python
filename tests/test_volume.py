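"""Volume normalization, behavior classification and contraction statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from follipulse import synth
from follipulse import volume as vol
from follipulse.errors import InsufficientDataError, ValidationError


def _traj(volumes, times=None, cells=None):
    volumes = np.asarray(volumes, dtype=float)
    times = np.arange(volumes.size) * 6.0 if times is None else times
    return vol.VolumeTrajectory("f0", "telogen1", times, volumes, cells)


class TestNormalize:
    @pytest.mark.parametrize(
        "volumes,expected",
        [
            ([500, 450, 400], [100, 90, 80]),
            ([7, 7, 7], [100, 100, 100]),
            ([1, 2, 4], [25, 50, 100]),
        ],
    )
    def test_percent_of_maximum(self, volumes, expected):
        rel = vol.normalize_trajectory(_traj(volumes))
        np.testing.assert_allclose(rel.percentages, expected)

    def test_argmax_matches_brute_force_scan(self, rng):
        v = rng.uniform(300, 900, size=50)
        rel = vol.normalize_trajectory(_traj(v))
        best, best_i = -np.inf, -1
        for i, x in enumerate(v):  # independent max scan
            if x > best:
                best, best_i = x, i
        assert rel.argmax_index == best_i
        assert rel.percentages[best_i] == 100.0

    def test_idempotent(self, rng):
        rel = vol.normalize_trajectory(_traj(rng.uniform(300, 900, 20)))
        again = vol.normalize_trajectory(rel)
        np.testing.assert_array_equal(again.percentages, rel.percentages)

    def test_tie_broken_by_earliest_index(self):
        rel = vol.normalize_trajectory(_traj([5, 9, 9, 3]))
        assert rel.argmax_index == 1

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(ValidationError):
            _traj([100, 0, 50])


class TestClassify:
    @pytest.mark.parametrize(
        "pct,expected",
        [
            (np.linspace(80, 100, 10), "continuous_enlargement"),
            (np.linspace(100, 75, 10), "continuous_contraction"),
            ([100, 85, 100, 84], "pulsatile"),
            ([100, 100, 100], "continuous_enlargement"),  # flat, no drawdown
        ],
    )
    def test_rule_set(self, pct, expected):
        pct = np.asarray(pct, dtype=float)
        rel = vol.RelativeTrajectory(pct, int(np.argmax(pct)))
        assert vol.classify_behavior(rel).category == expected

    def test_metrics_populated(self):
        call = vol.classify_behavior(vol.RelativeTrajectory(np.array([100.0, 85, 100, 84]), 0))
        assert call.net_change_pct == pytest.approx(-16.0)
        assert call.max_drawdown_pct == pytest.approx(16.0)
        assert call.crossings_below_90 == 2

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            vol.classify_behavior(vol.RelativeTrajectory(np.array([100.0, 90]), 0))

    def test_truth_recovery_on_generated_cohort(self):
        trajs, truth = synth.gen_volume_trajectories(
            synth.telogen_params(seed=7, n_follicles=60)
        )
        calls = [vol.classify_behavior(vol.normalize_trajectory(t)) for t in trajs]
        acc = np.mean([c.category == t for c, t in zip(calls, truth)])
        assert acc >= 0.95


class TestSummaries:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ({"enl": 2, "pul": 25, "con": 4}, {"enl": 6.5, "pul": 80.6, "con": 12.9}),
            ({"dyn": 19, "enl": 2}, {"dyn": 90.5, "enl": 9.5}),
            ({"only": 5}, {"only": 100.0}),
        ],
    )
    def test_percentages_half_up_one_decimal(self, counts, expected):
        out = vol.summarize_categories(counts)
        assert {k: v["percent"] for k, v in out.items()} == expected

    def test_from_behavior_calls(self):
        calls = [vol.BehaviorCall("pulsatile", 0, 0, 0)] * 3 + [
            vol.BehaviorCall("continuous_contraction", -20, 20, 1)
        ]
        out = vol.summarize_categories(calls)
        assert out["pulsatile"]["count"] == 3
        assert out["continuous_contraction"]["percent"] == 25.0

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            vol.summarize_categories({})

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.integers(1, 40), min_size=1, max_size=6))
    def test_rounded_percentages_sum_to_100(self, counts):
        out = vol.summarize_categories({f"c{i}": c for i, c in enumerate(counts)})
        assert sum(v["percent"] for v in out.values()) == pytest.approx(100.0, abs=0.31)


class TestContractionFraction:
    def test_constant_set_is_zero(self):
        rels = [vol.normalize_trajectory(_traj([5, 5, 5]))] * 3
        assert vol.contraction_fraction(rels).fraction_pct == 0.0

    def test_two_of_four_below(self):
        rel = vol.RelativeTrajectory(np.array([100.0, 85, 85, 100]), 0)
        summary = vol.contraction_fraction([rel])
        assert summary.fraction_pct == 50.0
        assert summary.n_below_threshold == 2

    def test_matches_brute_force_point_count(self):
        trajs, _ = synth.gen_volume_trajectories(synth.telogen_params(seed=3))
        rels = [vol.normalize_trajectory(t) for t in trajs]
        summary = vol.contraction_fraction(rels)
        n_below = sum(1 for r in rels for p in r.percentages if p < 90.0)
        n_total = sum(r.percentages.size for r in rels)
        assert summary.n_below_threshold == n_below
        assert summary.fraction_pct == pytest.approx(100.0 * n_below / n_total)

    def test_order_and_pooling_invariance(self):
        trajs, _ = synth.gen_volume_trajectories(
            synth.telogen_params(seed=4, n_follicles=10)
        )
        rels = [vol.normalize_trajectory(t) for t in trajs]
        a = vol.contraction_fraction(rels)
        b = vol.contraction_fraction(rels[::-1])
        assert a == b

    def test_follicle_weighting_equals_mean_of_per_follicle_fractions(self):
        rels = [
            vol.RelativeTrajectory(np.array([100.0, 85, 85, 100]), 0),  # 50% below
            vol.RelativeTrajectory(np.array([100.0, 95]), 0),  # 0% below
        ]
        by_points = vol.contraction_fraction(rels)
        by_follicles = vol.contraction_fraction(rels, weight="follicles")
        assert by_points.fraction_pct == pytest.approx(100 * 2 / 6)
        assert by_follicles.fraction_pct == pytest.approx(25.0)

    def test_smoothing_suppresses_single_point_spike(self):
        spiky = _traj([100, 100, 300, 100, 100, 100])
        rel = vol.normalize_trajectory(spiky, smooth=True)
        assert rel.percentages.max() == 100.0
        assert np.all(rel.percentages == 100.0)

    def test_unnormalized_input_rejected(self):
        with pytest.raises(ValidationError):
            vol.contraction_fraction([_traj([100, 90, 80])])


class TestCellVolumeAndBulge:
    def test_mean_cell_volume_arithmetic(self):
        out = vol.mean_cell_volume(_traj([4540, 4540], cells=10))
        assert out["mean_um3"] == pytest.approx(454.0)

    def test_missing_cell_count(self):
        with pytest.raises(ValidationError):
            vol.mean_cell_volume(_traj([100, 100]))

    def test_generator_defaults_within_configured_range(self):
        params = synth.telogen_params(seed=9, noise_pct=0.0, n_follicles=20)
        trajs, _ = synth.gen_volume_trajectories(params)
        for t in trajs:
            mean = vol.mean_cell_volume(t)["mean_um3"]
            # pulses/drift move the instantaneous value; the baseline per-cell
            # volume stays inside the configured biological range (+/- dynamics)
            assert 454 * 0.7 <= mean <= 735 * 1.3

    @pytest.mark.parametrize(
        "series,expected",
        [([4, 4, 4], 0.0), ([10, 11], 10.0)],
    )
    def test_bulge_drift(self, series, expected):
        out = vol.bulge_drift_metrics(series, series, series)
        assert out["width_max_dev_pct"] == pytest.approx(expected)

    def test_bulge_noise_bound(self, rng):
        # with pure measurement noise the max deviation is the max of n-1
        # absolute Gaussians; the empirical pass rate of a 3-sigma bound must
        # match the closed-form (2*Phi(3)-1)^(n-1) within binomial error
        from scipy.stats import norm

        cv, n, reps = 0.01, 40, 200
        ok = 0
        for _ in range(reps):
            series = 10 * (1 + cv * rng.standard_normal(n))
            series[0] = 10.0
            dev = vol.bulge_drift_metrics(series, series, series)["width_max_dev_pct"]
            ok += dev <= 3 * cv * 100
        expected = (2 * norm.cdf(3) - 1) ** (n - 1)
        sd = np.sqrt(expected * (1 - expected) / reps)
        assert abs(ok / reps - expected) <= 4 * sd

    def test_empty_series_rejected(self):
        with pytest.raises(ValidationError):
            vol.bulge_drift_metrics([], [1], [1])
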