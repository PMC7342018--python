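"""Trajectory kinetics: MSD estimator, power-law fits, segmentation,
velocities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iknm import (
    MSDProfile,
    NuclearTrack,
    align_and_average,
    average_instantaneous_velocity,
    classify_motion,
    compute_msd,
    fit_power_law,
    instantaneous_velocity,
    mitotic_velocity,
    normalize_velocity,
    pooled_msd,
    segment_phases,
    simulate_tracks,
    SimConfig,
)


def brute_force_msd(p, dt, max_n):
    """Independent oracle: direct double loop over all overlapping pairs."""
    p = list(map(float, p))
    out = []
    for n in range(1, max_n + 1):
        pairs = [(p[n + i] - p[i]) ** 2 for i in range(len(p) - n)]
        out.append(sum(pairs) / len(pairs))
    return out


positions_strategy = st.lists(
    st.floats(min_value=0.0, max_value=100.0, allow_nan=False),
    min_size=3, max_size=12,
)

# positions on a dyadic grid: differences, squares and sums are then exact
# in double precision, so estimator and oracle agree bit-for-bit no matter
# the summation order
dyadic_positions = st.lists(
    st.integers(min_value=0, max_value=64 * 100).map(lambda k: k / 64.0),
    min_size=3, max_size=12,
)


class TestMSD:
    @pytest.mark.parametrize(
        "positions, expected",
        [
            ([5, 5, 5, 5], [0.0, 0.0, 0.0]),
            ([0, 1, 2, 3], [1.0, 4.0, 9.0]),
            ([0, 2, 1], [2.5, 1.0]),
        ],
    )
    def test_hand_enumerated_examples(self, positions, expected):
        prof = compute_msd(np.array(positions, dtype=float), dt=1.0)
        np.testing.assert_allclose(prof.msd, expected, rtol=0, atol=1e-15)
        np.testing.assert_array_equal(
            prof.n_pairs, len(positions) - np.arange(1, len(positions))
        )

    @given(dyadic_positions)
    def test_equals_brute_force_pair_enumeration(self, positions):
        p = np.array(positions)
        prof = compute_msd(p, dt=1.0)
        expected = brute_force_msd(positions, 1.0, len(positions) - 1)
        np.testing.assert_array_equal(prof.msd, expected)

    @given(positions_strategy)
    def test_matches_brute_force_for_arbitrary_floats(self, positions):
        prof = compute_msd(np.array(positions), dt=1.0)
        expected = brute_force_msd(positions, 1.0, len(positions) - 1)
        np.testing.assert_allclose(prof.msd, expected, rtol=1e-12, atol=1e-15)

    @given(positions_strategy,
           st.floats(min_value=-50, max_value=50, allow_nan=False))
    def test_translation_invariance(self, positions, shift):
        p = np.array(positions)
        base = compute_msd(p, dt=1.0).msd
        moved = compute_msd(p + 200.0 + shift, dt=1.0).msd
        np.testing.assert_allclose(moved, base, rtol=1e-9, atol=1e-9)

    @given(positions_strategy,
           st.floats(min_value=0.1, max_value=10, allow_nan=False))
    def test_scaling_multiplies_msd_by_c_squared(self, positions, c):
        p = np.array(positions)
        base = compute_msd(p, dt=1.0).msd
        scaled = compute_msd(c * p, dt=1.0).msd
        np.testing.assert_allclose(scaled, c * c * base, rtol=1e-9, atol=1e-12)

    def test_lag_beyond_segment_rejected(self):
        with pytest.raises(ValueError, match="max_lag"):
            compute_msd(np.arange(5.0), dt=1.0, max_lag=5.0)

    def test_start_index_analyzes_late_segment_only(self, linear_track):
        full = compute_msd(linear_track)
        late = compute_msd(linear_track, start_index=10)
        assert late.lags.size == 10
        np.testing.assert_allclose(late.msd, full.msd[:10])


class TestPowerLawFit:
    def test_exact_power_law_recovered_to_machine_precision(self):
        lags = np.arange(1.0, 6.0)
        msd = 2.0 * 0.3 * lags**1.4
        fit = fit_power_law(MSDProfile(lags=lags, msd=msd,
                                       n_pairs=np.full(5, 10)))
        assert fit.slope_a == pytest.approx(1.4, abs=1e-12)
        assert fit.diffusion_d == pytest.approx(0.3, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_ballistic_track_slope_exactly_two(self, linear_track):
        fit = fit_power_law(compute_msd(linear_track, max_lag=10.0))
        assert abs(fit.slope_a - 2.0) < 1e-9

    @given(st.floats(min_value=0.5, max_value=5.0, allow_nan=False))
    def test_scaling_leaves_slope_fixed_and_scales_d(self, c):
        lags = np.arange(1.0, 8.0)
        msd = 2.0 * 0.2 * lags**1.1
        base = fit_power_law(MSDProfile(lags, msd, np.full(7, 9)))
        scaled = fit_power_law(MSDProfile(lags, c * c * msd, np.full(7, 9)))
        assert scaled.slope_a == pytest.approx(base.slope_a, abs=1e-10)
        assert scaled.diffusion_d == pytest.approx(c * c * base.diffusion_d,
                                                   rel=1e-10)

    def test_brownian_ensemble_slope_and_d(self, brownian_cohort):
        """Pooled-cohort exponent ~ 1 and D within 10% of truth; per-track
        fits carry the known small downward Jensen bias of regressing the
        log of a noisy MSD, so their mean sits slightly below the pooled
        slope."""
        profs = [compute_msd(t, max_lag=25.0) for t in brownian_cohort.tracks]
        pooled_fit = fit_power_law(pooled_msd(profs))
        assert 0.95 <= pooled_fit.slope_a <= 1.05
        assert pooled_fit.diffusion_d == pytest.approx(0.05, rel=0.10)
        per_track = np.mean([fit_power_law(p).slope_a for p in profs])
        assert per_track < pooled_fit.slope_a
        assert 0.85 <= per_track <= 1.05

    def test_immobile_track_raises_named_error(self):
        prof = compute_msd(np.full(6, 3.0), dt=1.0)
        with pytest.raises(ValueError, match="immobile"):
            fit_power_law(prof)

    def test_too_few_lags_rejected(self):
        prof = MSDProfile(np.array([1.0, 2.0]), np.array([1.0, 2.0]),
                          np.array([5, 4]))
        with pytest.raises(ValueError, match=">= 3"):
            fit_power_law(prof)


class TestMotionClassification:
    @pytest.mark.parametrize(
        "slope, label",
        [
            (0.78, "constrained"),   # early-phase sub-diffusion
            (1.0, "diffusive"),
            (1.06, "diffusive"),
            (1.18, "directed"),
            (1.45, "directed"),
            (1.66, "directed"),
            (1.95, "ballistic"),
            (2.0, "ballistic"),
        ],
    )
    def test_exponent_bands(self, slope, label):
        assert classify_motion(slope).label == label

    def test_band_widths_are_configurable(self):
        assert classify_motion(1.18, diffusive_band=0.2).label == "diffusive"


class TestAveraging:
    def test_identical_tracks_average_to_themselves(self, linear_track):
        avg = align_and_average([linear_track, linear_track])
        np.testing.assert_allclose(avg["mean_um"], linear_track.positions)
        np.testing.assert_array_equal(avg["sem_um"], 0.0)

    def test_linearity_of_offsets(self):
        times = np.arange(10.0) - 9.0
        f = np.sin(times) + 5.0
        a = NuclearTrack("a", times, f + 1.0)
        b = NuclearTrack("b", times, f + 3.0)
        avg = align_and_average([a, b])
        np.testing.assert_allclose(avg["mean_um"], f + 2.0)

    def test_unequal_lengths_contribute_where_they_exist(self):
        long = NuclearTrack("l", np.arange(10.0) - 9.0, np.full(10, 4.0))
        short = NuclearTrack("s", np.arange(5.0) - 4.0, np.full(5, 8.0))
        avg = align_and_average([long, short])
        assert avg["n_tracks"].tolist() == [1] * 5 + [2] * 5
        np.testing.assert_allclose(avg["mean_um"].tail(5), 6.0)

    def test_mixed_dt_rejected(self, linear_track):
        other = NuclearTrack("o", np.arange(6.0) * 2 - 10.0, np.full(6, 1.0))
        with pytest.raises(ValueError, match="mixed frame intervals"):
            align_and_average([linear_track, other])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            align_and_average([])

    def test_drifting_cohort_average_slope_matches_v_late(self):
        cfg = SimConfig(seed=5, dt=1.0, n_steps=60, d_early=0.05,
                        v_late=0.5, d_late=0.02, t_onset=-15.0, p0=20.0,
                        n_tracks=30)
        cohort = simulate_tracks(cfg)
        avg = align_and_average(cohort.tracks)
        late = avg[avg["time_min"] >= -15.0]
        slope = np.polyfit(late["time_min"], late["mean_um"], 1)[0]
        assert slope == pytest.approx(-0.5, rel=0.10)


class TestInstantaneousVelocity:
    def test_constant_track_zero_velocity(self):
        t = NuclearTrack("c", np.arange(5.0) - 4.0, np.full(5, 7.0))
        assert np.all(instantaneous_velocity(t)["velocity_um_min"] == 0.0)

    def test_apical_motion_is_positive(self, linear_track):
        v = instantaneous_velocity(linear_track)["velocity_um_min"]
        np.testing.assert_allclose(v, 0.5)

    def test_brownian_mean_velocity_fluctuates_around_zero(
        self, brownian_cohort
    ):
        avg = average_instantaneous_velocity(brownian_cohort.tracks)
        grand = avg["mean_velocity_um_min"].mean()
        # zero-drift ensemble: grand mean within ~3 SE of 0
        se = avg["mean_velocity_um_min"].std() / np.sqrt(len(avg))
        assert abs(grand) < 3 * se + 1e-3


class TestSegmentation:
    def test_noiseless_breakpoint_recovered_exactly(self):
        cfg = SimConfig(seed=1, dt=1.0, n_steps=30, d_early=0.0, v_late=0.5,
                        d_late=0.0, t_onset=-12.0, p0=15.0, n_tracks=1)
        t = simulate_tracks(cfg).tracks[0]
        split = segment_phases(t, "automatic")
        assert split is not None
        assert split.onset_time == -12.0

    def test_supplied_mode_uses_caller_onset(self, linear_track):
        split = segment_phases(linear_track, "supplied", onset_time=-8.0)
        assert split.onset_index == 12
        assert split.method == "supplied"

    def test_short_track_rejected(self):
        t = NuclearTrack("s", np.arange(5.0) - 4.0, np.arange(5.0)[::-1] * 1.0)
        with pytest.raises(ValueError, match=">= 8 points"):
            segment_phases(t, "automatic")

    def test_brownian_false_positive_rate_is_low(self, brownian_cohort):
        """Pure diffusion should mostly yield 'no directed phase'."""
        hits = sum(
            segment_phases(t, "automatic") is not None
            for t in brownian_cohort.tracks
        )
        assert hits / len(brownian_cohort.tracks) < 0.2

    def test_myosin_gate_restricts_candidate_onsets(self):
        cfg = SimConfig(seed=1, dt=1.0, n_steps=30, d_early=0.0, v_late=0.5,
                        d_late=0.0, t_onset=-12.0, p0=15.0, n_tracks=1)
        t = simulate_tracks(cfg).tracks[0]
        myo = np.where(t.times >= -6.0, 2.0, 1.0)
        gated = NuclearTrack(t.track_id, t.times, t.positions, myosin=myo)
        split = segment_phases(gated, "automatic", myosin_threshold=1.5)
        assert split.onset_time >= -6.0


class TestMitoticVelocity:
    def test_arithmetic_example(self):
        # 12 um at onset (-15 min), 3 um at metaphase -> 0.6 um/min
        times = np.arange(21.0) - 20.0
        pos = np.concatenate([np.full(5, 12.0), np.linspace(12.0, 3.0, 16)])
        t = NuclearTrack("v", times, pos)
        split = segment_phases(t, "supplied", onset_time=-15.0)
        rec = mitotic_velocity(t, split)
        assert rec["velocity_um_min"] == pytest.approx(0.6)
        assert rec["duration_min"] == 15.0

    def test_no_net_displacement_gives_zero(self):
        t = NuclearTrack("z", np.arange(10.0) - 9.0, np.full(10, 6.0))
        split = segment_phases(t, "supplied", onset_time=-5.0)
        assert mitotic_velocity(t, split)["velocity_um_min"] == 0.0

    def test_cohort_velocity_recovers_generator_truth(self, drift_cohort):
        vels = []
        for t, onset in zip(drift_cohort.tracks,
                            drift_cohort.truth["onset_time"]):
            split = segment_phases(t, "supplied", onset_time=onset)
            vels.append(mitotic_velocity(t, split)["velocity_um_min"])
        assert np.mean(vels) == pytest.approx(0.6, rel=0.10)

    def test_normalize_velocity(self):
        out = normalize_velocity(np.array([0.3, 0.6]), control_mean=0.6)
        np.testing.assert_allclose(out, [0.5, 1.0])
        with pytest.raises(ValueError, match="positive"):
            normalize_velocity(np.array([0.3]), control_mean=0.0)

    def test_halved_drift_normalizes_to_half(self):
        slow = simulate_tracks(
            SimConfig(seed=6, dt=1.0, n_steps=60, d_early=0.1, v_late=0.3,
                      d_late=0.02, t_onset=-15.0, p0=20.0, n_tracks=50)
        )
        vels = []
        for t, onset in zip(slow.tracks, slow.truth["onset_time"]):
            split = segment_phases(t, "supplied", onset_time=onset)
            vels.append(mitotic_velocity(t, split)["velocity_um_min"])
        norm = normalize_velocity(np.array(vels), control_mean=0.6)
        assert norm.mean() == pytest.approx(0.5, rel=0.10)
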