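"""Event detection, amplitude mixtures and I-V analysis."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from trpa1pore import singlechan, synthgen
from trpa1pore.singlechan import (
    average_open_iv,
    detect_events,
    fit_amplitude_states,
    slope_conductance,
    subtract_leak,
)
from trpa1pore.synthgen import (
    OPEN_LARGE,
    hold_protocol,
    make_control_sweep,
    render_sweep,
    simulate_gating,
    simulate_sweep_pairs,
)

FS = 10_000.0


def brute_force_events(trace, threshold, min_len):
    """Oracle: per-sample scan for maximal runs of |I| >= threshold."""
    events = []
    start = None
    for i, x in enumerate(list(trace) + [0.0]):  # sentinel terminates a final run
        if abs(x) >= threshold and start is None:
            start = i
        elif abs(x) < threshold and start is not None:
            if i - start >= min_len:
                events.append((start, i, float(np.mean(trace[start:i]))))
            start = None
    return events


class TestSubtractLeak:
    def test_sweep_minus_itself_is_zero(self, wt150, hold_minus60):
        sweep = make_control_sweep(wt150, hold_minus60, seed=1)
        assert np.all(subtract_leak(sweep, sweep) == 0.0)

    def test_removes_leak_leaving_open_current(self, quiet_wt150, hold_minus60):
        leaky = dataclasses.replace(quiet_wt150, leak_conductance_pS=100.0)
        traj = np.zeros(hold_minus60.n_samples, dtype=np.int8)
        traj[1000:2000] = OPEN_LARGE
        sweep = render_sweep(traj, leaky, hold_minus60, seed=0)
        control = make_control_sweep(leaky, hold_minus60, seed=0)
        residual = subtract_leak(sweep, control)
        assert np.allclose(residual[1000:2000], -15.06)
        assert np.allclose(residual[:1000], 0.0)

    def test_protocol_mismatch_rejected(self, wt150, hold_minus60):
        sweep = make_control_sweep(wt150, hold_minus60, seed=1)
        other = make_control_sweep(wt150, hold_protocol(-60.0, 0.25), seed=1)
        with pytest.raises(ValueError):
            subtract_leak(sweep, other)


class TestDetectEvents:
    def test_square_pulse_detected_with_exact_amplitude(self):
        trace = np.zeros(1000)
        trace[200:300] = -15.06  # 10 ms opening
        events = detect_events(trace, FS)
        assert len(events) == 1
        ev = events.iloc[0]
        assert (ev["start"], ev["stop"]) == (200, 300)
        assert ev["amplitude_pA"] == pytest.approx(-15.06, abs=0.05)

    def test_subthreshold_constant_current_ignored(self):
        assert len(detect_events(np.full(1000, 2.9), FS)) == 0

    def test_pure_noise_yields_essentially_no_events(self):
        rng = np.random.default_rng(0)
        trace = rng.standard_normal(100_000)  # 10 s of 1 pA RMS noise
        events = detect_events(trace, FS)
        assert len(events) <= 1

    def test_run_shorter_than_min_duration_dropped(self):
        trace = np.zeros(100)
        trace[50:53] = 10.0  # 0.3 ms < 0.5 ms minimum
        assert len(detect_events(trace, FS)) == 0

    def test_event_voltage_is_mean_over_run(self):
        trace = np.zeros(1000)
        trace[100:200] = 8.0
        v = np.linspace(-100, 100, 1000)
        events = detect_events(trace, FS, voltage_mV=v)
        assert events.iloc[0]["voltage_mV"] == pytest.approx(v[100:200].mean())

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        data=st.data(),
        threshold=st.floats(0.5, 5.0),
        min_len=st.integers(1, 8),
    )
    def test_matches_brute_force_scan(self, data, threshold, min_len):
        """Threshold-run detection agrees exactly with a per-sample oracle."""
        n = data.draw(st.integers(1, 300))
        trace = np.array(
            data.draw(
                st.lists(
                    st.floats(-20, 20, allow_nan=False), min_size=n, max_size=n
                )
            )
        )
        got = detect_events(
            trace, FS, threshold_pA=threshold, min_duration_s=min_len / FS
        )
        expected = brute_force_events(trace, threshold, min_len)
        assert len(got) == len(expected)
        for (_, row), (s, e, amp) in zip(got.iterrows(), expected):
            assert (row["start"], row["stop"]) == (s, e)
            assert row["amplitude_pA"] == pytest.approx(amp, rel=1e-12, abs=1e-12)


class TestFitAmplitudeStates:
    def _simulated_events(self, fixture, n_sweeps=60, seed=11):
        proto = hold_protocol(-60.0, 0.5)
        sweeps, controls = simulate_sweep_pairs(fixture, proto, n_sweeps, seed)
        tables = [
            detect_events(subtract_leak(s, c), proto.sample_rate_Hz)
            for s, c in zip(sweeps, controls)
        ]
        return pd.concat(tables, ignore_index=True)

    def test_single_level_patch_recovers_main_conductance(self, wt150):
        one_level = dataclasses.replace(wt150, p_small=0.0)
        events = self._simulated_events(one_level)
        fit = fit_amplitude_states(events, -60.0)
        assert fit.n_components == 1
        assert fit.conductances_pS[0] == pytest.approx(251.0, abs=10.0)

    def test_two_level_patch_recovers_sublevel_ratio(self, wt150):
        events = self._simulated_events(wt150)
        fit = fit_amplitude_states(events, -60.0)
        assert fit.n_components == 2
        assert fit.ratio_small_large == pytest.approx(170.0 / 251.0, abs=0.05)
        assert sum(fit.weights) == pytest.approx(1.0)

    def test_recovers_generator_means_within_two_se(self, wt150):
        events = self._simulated_events(wt150, n_sweeps=120, seed=13)
        assert len(events) >= 500
        fit = fit_amplitude_states(events, -60.0)
        for mean, width, weight, truth in zip(
            fit.means_pA, fit.widths_pA, fit.weights, (-15.06, -10.2)
        ):
            se = width / np.sqrt(weight * len(events))
            assert mean == pytest.approx(truth, abs=2 * se + 0.02)

    def test_degenerate_identical_amplitudes_do_not_crash(self):
        events = pd.DataFrame({"amplitude_pA": np.full(100, -12.0)})
        fit = fit_amplitude_states(events, -60.0)
        assert fit.means_pA[0] == pytest.approx(-12.0)
        assert fit.widths_pA[0] >= 0.0

    def test_too_few_events_rejected(self):
        events = pd.DataFrame({"amplitude_pA": [-12.0] * 10})
        with pytest.raises(ValueError, match="at least"):
            fit_amplitude_states(events, -60.0)


def _ohmic_fixture(gamma=200.0, **kwargs):
    defaults = dict(
        name="ohmic",
        gamma_large_pS=gamma,
        gamma_small_pS=0.6 * gamma,
        p_small=0.0,
        leak_conductance_pS=0.0,
        noise_rms_pA=0.5,
    )
    defaults.update(kwargs)
    return synthgen.GatingFixture(**defaults)


class TestAverageOpenIV:
    def test_no_openings_all_bins_empty(self):
        fx = _ohmic_fixture(open_rate_per_s=0.0)
        sweeps, controls = simulate_sweep_pairs(fx, synthgen.RAMP_PROTOCOL, 10, 1)
        iv = average_open_iv(sweeps, controls)
        assert (iv["n"] == 0).all()

    def test_ohmic_channel_reproduces_line_with_gap(self):
        fx = _ohmic_fixture()
        sweeps, controls = simulate_sweep_pairs(fx, synthgen.RAMP_PROTOCOL, 150, 2)
        iv = average_open_iv(sweeps, controls)
        # outside the gap the binned means lie on I = 0.2 V
        far = iv[(iv["voltage_mV"].abs() > 25) & (iv["n"] > 0)]
        assert len(far) >= 20
        assert np.allclose(far["mean_pA"], 0.2 * far["voltage_mV"], atol=1.0)
        assert np.median(np.abs(far["mean_pA"] - 0.2 * far["voltage_mV"])) < 0.3
        # |0.2 V| < 3 pA for |V| < 15 mV: those bins stay empty
        gap = iv[iv["voltage_mV"].abs() < 12.5]
        assert (gap["n"] == 0).all()

    def test_conductance_invariant_to_pure_leak(self):
        lo = _ohmic_fixture()
        hi = _ohmic_fixture(leak_conductance_pS=150.0, name="leaky")
        iv_lo = average_open_iv(*simulate_sweep_pairs(lo, synthgen.RAMP_PROTOCOL, 40, 3))
        iv_hi = average_open_iv(*simulate_sweep_pairs(hi, synthgen.RAMP_PROTOCOL, 40, 3))
        g_lo = slope_conductance(iv_lo).negative.slope_pS
        g_hi = slope_conductance(iv_hi).negative.slope_pS
        assert g_hi == pytest.approx(g_lo, abs=5.0)

    def test_requires_ramp_sweeps(self, wt150, hold_minus60):
        sweeps, controls = simulate_sweep_pairs(wt150, hold_minus60, 3, 1)
        with pytest.raises(ValueError, match="ramp"):
            average_open_iv(sweeps, controls)


class TestSlopeConductance:
    def test_exact_line_recovered_on_both_branches(self):
        v = np.arange(-97.5, 100, 5.0)
        iv = pd.DataFrame(
            {"voltage_mV": v, "mean_pA": 0.2 * v, "sd_pA": 0.1, "n": 100}
        )
        est = slope_conductance(iv)
        assert est.negative.slope_pS == pytest.approx(200.0, abs=1e-9)
        assert est.positive.slope_pS == pytest.approx(200.0, abs=1e-9)
        assert est.negative.stderr_pS == pytest.approx(0.0, abs=1e-9)

    def test_sparse_branch_reported_absent(self):
        v = np.arange(-97.5, 100, 5.0)
        iv = pd.DataFrame(
            {"voltage_mV": v, "mean_pA": 0.2 * v, "sd_pA": 0.1, "n": 100}
        )
        iv.loc[iv["voltage_mV"] < 0, "n"] = 0
        est = slope_conductance(iv)
        assert est.negative is None
        assert est.positive is not None

    def test_wild_type_ramp_ensemble_recovers_main_conductance(self, wt150):
        sweeps, controls = simulate_sweep_pairs(wt150, synthgen.RAMP_PROTOCOL, 120, 5)
        est = slope_conductance(average_open_iv(sweeps, controls))
        assert est.negative.slope_pS == pytest.approx(251.0, abs=10.0)
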