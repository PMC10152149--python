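import math

import numpy as np
import pytest

from cometpool.trajectory_analysis import (
    CometTrack,
    CycleSeries,
    consumption_rate,
    cumulative_polymerized,
    cycle_count,
    decay_time_constant,
    disassembly_speed,
    estimate_kplus,
    instantaneous_velocity,
    motility_half_life,
    read_tracks_csv,
    tail_fraction,
    write_tracks_csv,
)


def make_track(time, **kwargs):
    return CometTrack(track_id="t0", time_min=np.asarray(time, float), **kwargs)


class TestCometTrack:
    def test_non_monotone_time_rejected(self):
        with pytest.raises(ValueError):
            make_track([0.0, 2.0, 1.0])

    def test_mismatched_series_rejected(self):
        with pytest.raises(ValueError):
            make_track([0.0, 1.0], comet_length_um=[1.0])

    def test_negative_length_rejected(self):
        with pytest.raises(ValueError):
            make_track([0.0, 1.0], comet_length_um=[-1.0, 0.0])

    def test_csv_round_trip(self, tmp_path):
        t = np.arange(6.0)
        track = make_track(
            t, x_um=t * 1.5, y_um=np.zeros(6), comet_length_um=t * 2.0,
            bead_velocity_um_per_min=np.full(6, 2.0),
        )
        path = tmp_path / "tracks.csv"
        write_tracks_csv([track], path)
        (loaded,) = read_tracks_csv(path)
        assert loaded.track_id == "t0"
        np.testing.assert_allclose(loaded.comet_length_um, track.comet_length_um)
        assert loaded.comet_area_um2 is None  # all-NaN column comes back as absent

    def test_missing_required_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("foo,bar\n1,2\n")
        with pytest.raises(ValueError, match="missing"):
            read_tracks_csv(path)


class TestInstantaneousVelocity:
    def test_straight_line_constant_speed(self):
        t = np.arange(0.0, 40.0, 2.0)
        track = make_track(t, x_um=1.1 * t, y_um=np.zeros_like(t))
        v = instantaneous_velocity(track)
        np.testing.assert_allclose(v, 1.1, rtol=1e-12)

    def test_stationary_bead(self):
        t = np.arange(0.0, 20.0, 2.0)
        track = make_track(t, x_um=np.zeros_like(t), y_um=np.zeros_like(t))
        assert instantaneous_velocity(track) == pytest.approx(np.zeros_like(t))

    def test_matches_closed_form_derivative(self):
        from cometpool.model_core import assembly_closed_form

        v0, l_max, sigma = 1.0, 100.0, 1.0
        t = np.arange(0.0, 200.0, 2.0)
        l, _ = assembly_closed_form(t, v0, l_max, sigma)
        track = make_track(t, comet_length_um=l)
        v = instantaneous_velocity(track, window=1, source="length")
        expected = v0 * np.exp(-(1 + sigma) * v0 * t / l_max)
        # central differences + one-sided endpoints: compare interior
        np.testing.assert_allclose(v[2:-2], expected[2:-2], rtol=5e-3)

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            instantaneous_velocity(make_track([0.0], x_um=[0.0], y_um=[0.0]))

    def test_even_window_rejected(self):
        t = np.arange(5.0)
        with pytest.raises(ValueError):
            instantaneous_velocity(make_track(t, x_um=t, y_um=t), window=4)


class TestMotilityHalfLife:
    def test_two_hour_half_life(self):
        t_h = np.linspace(0.0, 10.0, 50)
        v = np.exp(-0.3466 * t_h)
        fit = motility_half_life(v, t_h, time_unit="h")
        assert fit.ok
        assert fit.half_life == pytest.approx(math.log(2) / 0.3466, rel=1e-6)
        assert fit.half_life == pytest.approx(2.0, abs=2e-3)

    def test_flow_chamber_rate(self):
        # decay rate 0.1/h -> half-life 6.93 h
        t_h = np.linspace(0.0, 30.0, 100)
        fit = motility_half_life(np.exp(-0.1 * t_h), t_h, time_unit="h")
        assert fit.half_life == pytest.approx(math.log(2) / 0.1, rel=1e-6)

    def test_half_life_identity(self):
        t = np.linspace(0.0, 100.0, 60)
        fit = motility_half_life(2.0 * np.exp(-0.05 * t), t)
        assert fit.half_life == math.log(2) / fit.rate  # exact identity
        assert fit.half_life == pytest.approx(math.log(2) * fit.tau, rel=1e-15)

    def test_constant_velocity_no_fit(self):
        t = np.linspace(0.0, 100.0, 30)
        fit = motility_half_life(np.ones_like(t), t)
        assert not fit.ok
        assert "not decaying" in fit.message

    def test_too_few_positive_points(self):
        fit = motility_half_life(np.array([1.0, 0.5, 0.0, 0.0, 0.0]), np.arange(5.0))
        assert not fit.ok


class TestCumulativePolymerized:
    def test_constant_velocity_rectangle(self):
        t = np.linspace(0.0, 100.0, 101)
        series = cumulative_polymerized(np.full_like(t, 1.1), t)
        assert series.cumulative_length_um[-1] == pytest.approx(110.0)
        assert np.all(np.diff(series.cumulative_length_um) >= 0)

    def test_zero_velocity(self):
        t = np.linspace(0.0, 10.0, 11)
        series = cumulative_polymerized(np.zeros_like(t), t)
        assert series.cumulative_length_um == pytest.approx(np.zeros_like(t))

    def test_exponential_closed_form(self):
        t = np.linspace(0.0, 1000.0, 2001)
        series = cumulative_polymerized(np.exp(-0.01 * t), t)
        expected = (1.0 / 0.01) * (1.0 - math.exp(-10.0))
        assert series.cumulative_length_um[-1] == pytest.approx(expected, rel=1e-4)

    def test_negative_velocity_rejected_unless_clipped(self):
        t = np.arange(4.0)
        v = np.array([1.0, -0.1, 1.0, 1.0])
        with pytest.raises(ValueError, match="clip"):
            cumulative_polymerized(v, t)
        series = cumulative_polymerized(v, t, clip_negative=True)
        assert np.all(np.diff(series.cumulative_length_um) >= 0)

    def test_grid_refinement_invariance(self):
        # halving dt changes the integral by < 0.1%
        coarse_t = np.linspace(0.0, 600.0, 301)
        fine_t = np.linspace(0.0, 600.0, 601)
        v = lambda t: np.exp(-0.005 * t)
        coarse = cumulative_polymerized(v(coarse_t), coarse_t).cumulative_length_um[-1]
        fine = cumulative_polymerized(v(fine_t), fine_t).cumulative_length_um[-1]
        assert abs(fine - coarse) / fine < 1e-3


class TestCycleCount:
    def test_one_cycle(self):
        series = CycleSeries(np.array([0.0, 1.0]), np.array([0.0, 110.0]))
        out = cycle_count(series, l_max=110.0)
        assert out.cycles[-1] == pytest.approx(1.0)

    def test_six_cycles(self):
        series = CycleSeries(np.array([0.0, 1.0]), np.array([0.0, 660.0]))
        assert cycle_count(series, l_max=110.0).cycles[-1] == pytest.approx(6.0)

    def test_zero(self):
        series = CycleSeries(np.array([0.0]), np.array([0.0]))
        assert cycle_count(series, l_max=110.0).cycles[0] == 0.0

    def test_invalid_l_max(self):
        series = CycleSeries(np.array([0.0]), np.array([0.0]))
        with pytest.raises(ValueError):
            cycle_count(series, l_max=0.0)


class TestConsumptionRate:
    def test_constant_velocity(self):
        t = np.linspace(0.0, 100.0, 51)
        series = cumulative_polymerized(np.full_like(t, 1.1), t)
        out = consumption_rate(series, G_bar=3.0, l_max=110.0, window_min=10.0)
        assert out.consumption_rate_uM_per_h == pytest.approx(np.full_like(t, 1.8))

    def test_zero_velocity(self):
        t = np.linspace(0.0, 100.0, 51)
        series = cumulative_polymerized(np.zeros_like(t), t)
        out = consumption_rate(series, window_min=10.0)
        assert out.consumption_rate_uM_per_h == pytest.approx(np.zeros_like(t))

    def test_linearity_in_G_bar(self):
        t = np.linspace(0.0, 100.0, 51)
        series = cumulative_polymerized(np.full_like(t, 1.1), t)
        single = consumption_rate(series, G_bar=3.0, window_min=10.0)
        double = consumption_rate(series, G_bar=6.0, window_min=10.0)
        np.testing.assert_allclose(
            double.consumption_rate_uM_per_h, 2.0 * single.consumption_rate_uM_per_h
        )

    def test_window_too_short(self):
        t = np.linspace(0.0, 100.0, 51)
        series = cumulative_polymerized(np.zeros_like(t), t)
        with pytest.raises(ValueError, match="window"):
            consumption_rate(series, window_min=1.0)


class TestTailFraction:
    def test_paper_value(self):
        assert tail_fraction(57.0, 100.0) == pytest.approx(0.57)

    def test_all_in_comet(self):
        assert tail_fraction(100.0, 100.0) == pytest.approx(1.0)

    def test_background_pair(self):
        assert tail_fraction(120.0, 200.0, 20.0) == pytest.approx(100.0 / 180.0)
        assert tail_fraction(120.0, 200.0, (20.0, 20.0)) == pytest.approx(100.0 / 180.0)

    def test_nonpositive_total_rejected(self):
        with pytest.raises(ValueError):
            tail_fraction(1.0, 10.0, 10.0)


class TestDecayTimeConstant:
    @pytest.mark.parametrize("tau", [55.0, 22.0])
    def test_noiseless_recovery(self, tau):
        t = np.arange(0.0, 120.0, 2.0)
        fit = decay_time_constant(100.0 * np.exp(-t / tau), t)
        assert fit.ok
        assert fit.tau == pytest.approx(tau, rel=1e-8)

    def test_constant_trace_no_fit(self):
        t = np.arange(0.0, 20.0, 2.0)
        fit = decay_time_constant(np.full_like(t, 5.0), t)
        assert not fit.ok

    def test_increasing_trace_no_fit(self):
        t = np.arange(0.0, 20.0, 2.0)
        fit = decay_time_constant(np.exp(0.1 * t), t)
        assert not fit.ok

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            decay_time_constant(np.array([1.0, 0.5]), np.array([0.0, 1.0]))


class TestDisassemblySpeed:
    @pytest.mark.parametrize(
        "length,tau,expected", [(60.0, 60.0, 1.0), (66.0, 55.0, 1.2), (26.4, 22.0, 1.2)]
    )
    def test_values(self, length, tau, expected):
        assert disassembly_speed(length, tau) == pytest.approx(expected)

    def test_zero_tau_rejected(self):
        with pytest.raises(ValueError):
            disassembly_speed(60.0, 0.0)


class TestEstimateKplus:
    def test_kon_scale(self):
        t = np.linspace(0.0, 100.0, 20)
        lengths = 0.1 + 0.0216 * t
        k_plus, depol = estimate_kplus(lengths, t, G_uM=0.8, subunit_rise_um=0.0027)
        assert k_plus == pytest.approx(10.0, rel=1e-6)
        assert not depol

    def test_zero_slope(self):
        t = np.linspace(0.0, 100.0, 10)
        k_plus, depol = estimate_kplus(np.full_like(t, 2.0), t, G_uM=0.8)
        assert k_plus == pytest.approx(0.0, abs=1e-12)

    def test_inverse_in_G(self):
        t = np.linspace(0.0, 100.0, 10)
        lengths = 0.0216 * t
        k1, _ = estimate_kplus(lengths, t, G_uM=0.8)
        k2, _ = estimate_kplus(lengths, t, G_uM=1.6)
        assert k1 == pytest.approx(2.0 * k2)

    def test_depolymerizing_flagged(self):
        t = np.linspace(0.0, 100.0, 10)
        _, depol = estimate_kplus(5.0 - 0.01 * t, t, G_uM=0.8)
        assert depol

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            estimate_kplus(np.array([1.0, 2.0]), np.array([0.0, 1.0]), G_uM=0.8)
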