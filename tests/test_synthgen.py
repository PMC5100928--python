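"""Generator statistics: gating, rendering, noise calibration, fixtures."""

import dataclasses

import numpy as np
import pytest

from trpa1pore import synthgen
from trpa1pore.synthgen import (
    CLOSED,
    OPEN_LARGE,
    OPEN_SMALL,
    BlockModelParams,
    GatingFixture,
    VoltageProtocol,
    fixture_registry,
    get_fixture,
    hold_protocol,
    make_control_sweep,
    render_sweep,
    simulate_block_dataset,
    simulate_gating,
)


class TestVoltageProtocol:
    def test_ramp_is_linear_between_endpoints(self):
        proto = synthgen.RAMP_PROTOCOL
        v = proto.voltage()
        assert v[0] == proto.ramp_start_mV
        assert v[-1] == proto.ramp_end_mV
        assert np.allclose(np.diff(v), np.diff(v)[0])

    def test_sampling_must_cover_filter_band(self):
        with pytest.raises(ValueError):
            VoltageProtocol(kind="hold", sample_rate_Hz=8000.0, filter_cutoff_Hz=5000.0)

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            VoltageProtocol(kind="hold", duration_s=0.0)


class TestSimulateGating:
    def test_zero_open_rate_never_opens(self, wt150, hold_minus60):
        stuck = dataclasses.replace(wt150, open_rate_per_s=0.0)
        traj = simulate_gating(stuck, hold_minus60, seed=0)
        assert np.all(traj == CLOSED)

    def test_stationary_open_fraction(self, wt150):
        fx = dataclasses.replace(wt150, open_rate_per_s=100.0, close_rate_per_s=100.0)
        proto = hold_protocol(-60.0, duration_s=30.0)
        traj = simulate_gating(fx, proto, seed=1)
        assert (traj != CLOSED).mean() == pytest.approx(0.5, abs=0.02)

    def test_mean_open_dwell_matches_close_rate(self, wt150):
        proto = hold_protocol(-60.0, duration_s=60.0)
        traj = simulate_gating(wt150, proto, seed=2)
        opens = (traj != CLOSED).astype(np.int8)
        edges = np.flatnonzero(np.diff(opens))
        bounds = np.concatenate(([0], edges + 1, [len(traj)]))
        dwells = [
            (b - a) / proto.sample_rate_Hz
            for a, b in zip(bounds[:-1], bounds[1:])
            if opens[a]
        ][1:-1]  # interior events only: edge dwells are censored
        assert len(dwells) >= 1000
        assert np.mean(dwells) == pytest.approx(1.0 / wt150.close_rate_per_s, rel=0.05)

    def test_sublevel_choice_frequency(self, wt150, hold_minus60):
        proto = hold_protocol(-60.0, duration_s=30.0)
        traj = simulate_gating(wt150, proto, seed=3)
        starts = np.flatnonzero(np.diff((traj != CLOSED).astype(np.int8)) == 1) + 1
        levels = traj[starts]
        frac_small = (levels == OPEN_SMALL).mean()
        n = len(levels)
        sigma = np.sqrt(wt150.p_small * (1 - wt150.p_small) / n)
        assert frac_small == pytest.approx(wt150.p_small, abs=3.5 * sigma)

    def test_identical_seed_identical_trajectory(self, wt150, hold_minus60):
        a = simulate_gating(wt150, hold_minus60, seed=7)
        b = simulate_gating(wt150, hold_minus60, seed=7)
        assert np.array_equal(a, b)

    def test_negative_rates_rejected(self, wt150):
        with pytest.raises(ValueError):
            dataclasses.replace(wt150, open_rate_per_s=-1.0)


class TestRenderSweep:
    def test_all_closed_zero_leak_zero_noise_is_silent(self, quiet_wt150, hold_minus60):
        traj = np.zeros(hold_minus60.n_samples, dtype=np.int8)
        sweep = render_sweep(traj, quiet_wt150, hold_minus60, seed=0)
        assert np.all(sweep.current_pA == 0.0)

    def test_open_large_current_is_gamma_times_drive(self, quiet_wt150, hold_minus60):
        traj = np.full(hold_minus60.n_samples, OPEN_LARGE, dtype=np.int8)
        sweep = render_sweep(traj, quiet_wt150, hold_minus60, seed=0)
        # 251 pS * (-60 mV) * 1e-3 = -15.06 pA, inward negative
        assert np.allclose(sweep.current_pA, -15.06)

    def test_current_linear_in_gamma_and_drive(self, quiet_wt150):
        traj0 = np.full(100, OPEN_LARGE, dtype=np.int8)
        p1 = hold_protocol(-60.0, duration_s=0.01)
        p2 = hold_protocol(-120.0, duration_s=0.01)
        i1 = render_sweep(traj0, quiet_wt150, p1, 0).current_pA[0]
        i2 = render_sweep(traj0, quiet_wt150, p2, 0).current_pA[0]
        assert i2 == pytest.approx(2 * i1)
        doubled = dataclasses.replace(
            quiet_wt150, gamma_large_pS=2 * quiet_wt150.gamma_large_pS,
            gamma_small_pS=2 * quiet_wt150.gamma_small_pS,
        )
        i3 = render_sweep(traj0, doubled, p1, 0).current_pA[0]
        assert i3 == pytest.approx(2 * i1)

    def test_reversal_is_unique_zero_crossing_of_open_trace(self, quiet_wt150):
        shifted = dataclasses.replace(quiet_wt150, reversal_potential_mV=10.0)
        trace = synthgen.render_noiseless_open_trace(shifted, synthgen.RAMP_PROTOCOL)
        v = synthgen.RAMP_PROTOCOL.voltage()
        signs = np.sign(trace[np.abs(v - 10.0) > 0.2])
        crossings = np.sum(np.diff(signs) != 0)
        assert crossings == 1
        assert np.interp(10.0, v, trace) == pytest.approx(0.0, abs=0.05)

    def test_noise_rms_calibrated(self, wt150, hold_minus60):
        quiet = dataclasses.replace(wt150, leak_conductance_pS=0.0)
        proto = hold_protocol(0.0, duration_s=2.0)
        traj = np.zeros(proto.n_samples, dtype=np.int8)
        sweep = render_sweep(traj, quiet, proto, seed=5)
        assert sweep.current_pA.std() == pytest.approx(wt150.noise_rms_pA, abs=0.1)

    def test_render_deterministic_given_seed(self, wt150, hold_minus60):
        traj = simulate_gating(wt150, hold_minus60, seed=1)
        a = render_sweep(traj, wt150, hold_minus60, seed=2)
        b = render_sweep(traj, wt150, hold_minus60, seed=2)
        assert np.array_equal(a.current_pA, b.current_pA)

    def test_length_mismatch_rejected(self, wt150, hold_minus60):
        with pytest.raises(ValueError):
            render_sweep(np.zeros(10, dtype=np.int8), wt150, hold_minus60, seed=0)


class TestControlSweep:
    def test_zero_leak_zero_noise_silent(self, quiet_wt150, hold_minus60):
        sweep = make_control_sweep(quiet_wt150, hold_minus60, seed=0)
        assert np.all(sweep.current_pA == 0.0)

    def test_leak_mean_at_positive_voltage(self, wt150):
        fx = dataclasses.replace(wt150, leak_conductance_pS=50.0)
        proto = hold_protocol(100.0, duration_s=1.0)
        sweep = make_control_sweep(fx, proto, seed=1)
        # 50 pS * 100 mV * 1e-3 = +5 pA
        sem = wt150.noise_rms_pA / np.sqrt(proto.n_samples / 10)  # correlated noise
        assert sweep.current_pA.mean() == pytest.approx(5.0, abs=4 * sem)

    def test_two_controls_differ_only_in_noise(self, wt150):
        proto = hold_protocol(100.0, duration_s=1.0)
        a = make_control_sweep(wt150, proto, seed=1)
        b = make_control_sweep(wt150, proto, seed=2)
        sem = wt150.noise_rms_pA / np.sqrt(proto.n_samples / 10)
        assert a.current_pA.mean() - b.current_pA.mean() == pytest.approx(0.0, abs=3 * sem)


class TestBlockDataset:
    def test_zero_concentration_curve_is_linear_through_reversal(self):
        params = get_fixture("WT-Ba")
        ds = simulate_block_dataset(params, 251.0, [0.0])
        _, v, i = ds.curves[0]
        expected = (v - 0.0) / (ds.normalization_voltage_mV - 0.0)
        assert np.allclose(i, expected)

    def test_normalization_point_is_one_for_every_concentration(self):
        params = get_fixture("WT-Ba")
        ds = simulate_block_dataset(
            params, 251.0, [0.5, 2.0, 8.0], noise_fraction=0.05, seed=3
        )
        for _, v, i in ds.curves:
            assert i[np.argmax(v)] == pytest.approx(1.0)

    def test_divalent_block_causes_outward_rectification(self):
        params = get_fixture("WT-Ba")
        ds = simulate_block_dataset(params, 251.0, [2.0])
        _, v, i = ds.curves[0]
        inward = abs(np.interp(-80.0, v, i))
        outward = abs(np.interp(80.0, v, i))
        assert inward < outward

    def test_empty_concentration_list_rejected(self):
        with pytest.raises(ValueError):
            simulate_block_dataset(get_fixture("WT-Ba"), 251.0, [])


class TestFixtureRegistry:
    def test_wild_type_main_conductance(self):
        assert get_fixture("WT-150").gamma_large_pS == 251.0
        assert get_fixture("WT-150").gamma_small_pS == 170.0

    def test_high_cesium_and_barium_conditions(self):
        assert get_fixture("WT-500").gamma_large_pS == 345.0
        assert get_fixture("WT-150-Ba100").gamma_large_pS == 161.0

    def test_e920a_histogram_levels_and_branch_ratio(self):
        fx = get_fixture("E920A-150")
        assert fx.gamma_large_pS == 172.0
        assert fx.gamma_small_pS == 99.0
        assert fx.branch_conductances.negative_pS == pytest.approx(0.54 * 251.0)

    def test_block_truth_kd_at_zero(self):
        params = get_fixture("WT-Ba")
        assert isinstance(params, BlockModelParams)
        assert params.kd_zero_mM == pytest.approx(0.6)
        assert params.delta == 0.5

    def test_unknown_fixture_raises(self):
        with pytest.raises(KeyError, match="unknown fixture"):
            get_fixture("WT-9000")

    def test_registry_fixture_invariants(self):
        for name, fx in fixture_registry().items():
            if isinstance(fx, GatingFixture):
                assert 0 <= fx.p_small <= 1
                assert fx.gamma_small_pS < fx.gamma_large_pS
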