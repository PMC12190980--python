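"""Forward-model unit and property tests: waveforms, integrators, spike trains."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import gfdkit as g
from gfdkit.errors import (
    ConfigurationError,
    InvalidParameterError,
    StabilityError,
)
from gfdkit.sim_dynamics import Phase, draw_spike_times


class TestRelaxation:
    def test_scalar_values(self):
        p = g.RelaxationParams(v_inf=10.0, dv=5.0, tau=100.0)
        t = np.array([0.0, 100.0, 1e7])
        v = g.relaxation_trace(p, t)
        assert v[0] == pytest.approx(15.0)
        assert v[1] == pytest.approx(10.0 + 5.0 / math.e, rel=1e-12)
        assert v[2] == pytest.approx(10.0, abs=1e-9)

    def test_invalid_tau_rejected(self):
        with pytest.raises(InvalidParameterError):
            g.RelaxationParams(v_inf=0.0, dv=1.0, tau=0.0)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        v_inf=st.floats(-100, 100),
        dv=st.floats(-50, 50),
        tau=st.floats(1.0, 1e5),
    )
    def test_monotone_and_bounded(self, v_inf, dv, tau):
        """The relaxation stays between its endpoints and is monotone."""
        t = np.linspace(0.0, 5 * tau, 200)
        v = g.relaxation_trace(g.RelaxationParams(v_inf, dv, tau), t)
        lo, hi = sorted((v_inf, v_inf + dv))
        assert np.all(v >= lo - 1e-9) and np.all(v <= hi + 1e-9)
        d = np.diff(v)
        if dv > 0:
            assert np.all(d <= 1e-12)
        elif dv < 0:
            assert np.all(d >= -1e-12)


class TestRenderSpike:
    def test_baseline_before_and_at_onset(self):
        sh = g.SpikeShape(baseline=-20.0, amplitude=4.0, tau_rise=2.0, tau_decay=20.0, t0=50.0)
        t = np.array([0.0, 49.9, 50.0, 1e6])
        v = g.render_spike(sh, t)
        assert v[0] == v[1] == v[2] == pytest.approx(-20.0)
        assert v[3] == pytest.approx(-20.0, abs=1e-9)  # returns to baseline

    def test_peak_time_matches_closed_form(self):
        """argmax on a dense grid agrees with ln(td/tr) tr td/(td-tr)."""
        sh = g.SpikeShape(baseline=0.0, amplitude=1.0, tau_rise=1.0, tau_decay=5.0, t0=0.0)
        assert sh.peak_time == pytest.approx(math.log(5.0) / (1 - 1 / 5), rel=1e-12)
        t = np.linspace(0.0, 30.0, 3_000_001)
        v = g.render_spike(sh, t)
        t_num = t[np.argmax(v)]
        assert t_num == pytest.approx(sh.peak_time, abs=2e-5)
        # value at the analytic peak is the true extremum to ~quadratic error
        v_peak = g.render_spike(sh, np.array([sh.peak_time]))[0]
        assert v.max() <= v_peak + 1e-9

    def test_positive_amplitude_is_positive_going(self):
        sh = g.SpikeShape(baseline=0.0, amplitude=3.0, tau_rise=0.5, tau_decay=4.0, t0=0.0)
        t = np.linspace(0, 20, 2001)
        assert g.render_spike(sh, t).max() > 0
        flipped = g.render_spike(sh, t, convention="rise_minus_decay")
        assert flipped.min() < 0

    def test_equal_time_constants_rejected(self):
        with pytest.raises(InvalidParameterError):
            g.SpikeShape(baseline=0.0, amplitude=1.0, tau_rise=2.0, tau_decay=2.0, t0=0.0)


class TestMembrane:
    def test_fixed_point_and_steady_state(self):
        t = np.arange(0.0, 1000.1, 0.1)
        p = g.MembraneParams(cm=1.0, g_ion=0.01, v_eq=-5.0)
        assert np.allclose(g.simulate_membrane(p, -5.0, t), -5.0)
        p2 = g.MembraneParams(cm=1.0, g_ion=0.01, v_eq=0.0, i_ion=((0.0, 0.2),))
        v = g.simulate_membrane(p2, 0.0, np.arange(0.0, 3000.1, 0.1))
        assert v[-1] == pytest.approx(0.2 / 0.01, rel=1e-4)  # v_eq + I/g

    def test_matches_exponential_with_first_order_convergence(self):
        """Halving dt halves the global Euler error (first-order scheme)."""
        p = g.MembraneParams(cm=1.0, g_ion=0.01, v_eq=0.0)
        errs = []
        for dt in (0.4, 0.2, 0.1):
            t = np.arange(0.0, 100.0 + dt / 2, dt)
            v = g.simulate_membrane(p, 10.0, t)
            errs.append(abs(v[-1] - 10.0 * math.exp(-1.0)))
        assert errs[-1] < 5e-3  # within O(dt) of the closed form
        for e_coarse, e_fine in zip(errs, errs[1:]):
            assert e_coarse / e_fine == pytest.approx(2.0, rel=0.05)

    def test_stability_error(self):
        p = g.MembraneParams(cm=1.0, g_ion=1.0, v_eq=0.0)
        with pytest.raises(StabilityError):
            g.simulate_membrane(p, 1.0, np.arange(0.0, 10.0, 2.0))


class TestBistable:
    def test_fixed_points(self):
        t = np.arange(0.0, 1000.5, 0.5)
        p = g.BistableParams(alpha=0.01, v1=-10.0, v2=5.0, sigma=0.0)
        assert np.allclose(g.simulate_bistable(p, -10.0, t), -10.0)
        assert np.allclose(g.simulate_bistable(p, 0.0, t), 0.0)

    @pytest.mark.parametrize("v0,target", [(1.0, 5.0), (-1.0, -10.0), (40.0, 5.0), (-40.0, -10.0)])
    def test_sigma_zero_converges_to_a_stable_root(self, v0, target):
        p = g.BistableParams(alpha=0.01, v1=-10.0, v2=5.0, sigma=0.0)
        t = np.arange(0.0, 10000.5, 0.5)
        v = g.simulate_bistable(p, v0, t)
        assert abs(v[-1] - target) < 1e-3

    def test_noisy_occupancy_is_bimodal(self):
        """With noise the long-run histogram concentrates near both wells."""
        p = g.BistableParams(alpha=0.05, v1=-5.0, v2=5.0, sigma=1.5)
        t = np.arange(0.0, 20000.1, 0.1)
        v = g.simulate_bistable(p, 5.0, t, seed=0)
        near_wells = np.mean((np.abs(v - p.v1) < 2.5) | (np.abs(v - p.v2) < 2.5))
        assert near_wells > 0.8
        assert (v > 0).any() and (v < 0).any()  # both wells visited


class TestNernstPlanck:
    def test_zero_gradients_give_zero_flux(self):
        inp = g.NernstPlanckInputs(d_coeff=1.0, conc=10.0, dconc_dr=0.0,
                                   dv_dr=0.0, z_charge=1.0, temperature=298.0)
        assert g.nernst_planck_flux(inp) == 0.0

    def test_pure_fickian_term(self):
        inp = g.NernstPlanckInputs(d_coeff=2.0, conc=10.0, dconc_dr=3.0,
                                   dv_dr=0.0, z_charge=1.0, temperature=298.0)
        assert g.nernst_planck_flux(inp) == pytest.approx(-2.0 * 3.0 * 1e-18, rel=1e-12)

    def test_drift_term_linear_in_concentration(self):
        base = dict(d_coeff=1.0, dconc_dr=0.0, dv_dr=2.0, z_charge=2.0, temperature=310.0)
        j1 = g.nernst_planck_flux(g.NernstPlanckInputs(conc=5.0, **base))
        j2 = g.nernst_planck_flux(g.NernstPlanckInputs(conc=10.0, **base))
        assert j2 == pytest.approx(2.0 * j1, rel=1e-12)


class TestSpikeTrains:
    def test_counts_match_rate_across_seeds(self):
        """Renewal-with-dead-time counts stay in the Poisson 99.9% interval."""
        rate, T = 0.6, 1000.0
        mean = rate * T
        half = 3.29 * math.sqrt(mean)
        for seed in range(100):
            n = draw_spike_times(rate, 0.0, T, 1.0, np.random.default_rng(seed)).size
            assert mean - half <= n <= mean + half

    def test_refractory_enforced(self):
        on = draw_spike_times(0.4, 0.0, 5000.0, 2.0, np.random.default_rng(3))
        assert np.all(np.diff(on) >= 2.0)

    def test_zero_rate_is_silent(self):
        assert draw_spike_times(0.0, 0.0, 1000.0, 2.0, np.random.default_rng(0)).size == 0


class TestChannelSimulators:
    def test_fiber_drift_net_change(self, rec_grid_1hz):
        """Fig-8a-style drift: about +6 mV over 20,000 s from 41 mV."""
        reg = g.ChannelRegime(morphology="fiber", mode="drift",
                              steady_target=47.0, v_start=41.0, tau_s=4000.0)
        tr = g.simulate_fiber_channel(reg, rec_grid_1hz, seed=1)
        assert tr[-1] - tr[0] == pytest.approx(6.0, abs=0.5)

    def test_drift_constant_when_already_settled(self, rec_grid_1hz):
        reg = g.ChannelRegime(morphology="fiber", mode="drift", steady_target=30.0,
                              v_start=30.0, options={"osc_amp_mv": 0.0, "noise_sigma_mv": 0.0})
        tr = g.simulate_fiber_channel(reg, rec_grid_1hz, seed=0)
        assert np.allclose(tr, 30.0)

    def test_slow_wave_dominant_period(self):
        from scipy.signal import periodogram
        reg = g.ChannelRegime(morphology="fiber", mode="slow_wave", steady_target=49.5)
        t = np.arange(0.0, 60000.0, 1.0)
        tr = g.simulate_fiber_channel(reg, t, seed=2)
        f, p = periodogram(tr - tr.mean(), fs=1.0)
        period = 1.0 / f[np.argmax(p[1:]) + 1]
        assert 5000.0 <= period <= 10000.0

    def test_wrong_morphology_rejected(self, rec_grid_1hz):
        reg = g.ChannelRegime(morphology="microsphere", mode="threshold_spiker",
                              phase_schedule=(Phase(0.0, 100.0, 0.1, (5, 15)),))
        with pytest.raises(ConfigurationError):
            g.simulate_fiber_channel(
                g.ChannelRegime(morphology="microsphere", mode="drift"), rec_grid_1hz, 0
            )
        with pytest.raises(ConfigurationError):
            g.simulate_microsphere_channel(
                g.ChannelRegime(morphology="fiber", mode="banded",
                                phase_schedule=(Phase(0.0, 1.0),)),
                None, rec_grid_1hz, 0,
            )

    def test_silent_schedule_gives_flat_baseline(self):
        t = np.arange(0.0, 2000.0, 1.0)
        reg = g.ChannelRegime(
            morphology="microsphere", mode="threshold_spiker",
            phase_schedule=(Phase(0.0, 2000.0, rate_hz=0.0, band=(-5.0, -5.0)),),
            steady_target=-5.0, options={"noise_sigma_mv": 0.0},
        )
        tr = g.simulate_microsphere_channel(reg, None, t, seed=0)
        assert np.allclose(tr, -5.0, atol=1e-9)

    def test_initial_phase_amplitudes_center_on_ten(self):
        """Peak amplitudes drawn Uniform(5, 15) average to 10 within CI."""
        rng = np.random.default_rng(0)
        t = np.arange(0.0, 2000.1, 0.1)
        reg = g.ChannelRegime(
            morphology="microsphere", mode="threshold_spiker",
            phase_schedule=(Phase(0.0, 2000.0, rate_hz=0.1, amp_range=(5.0, 15.0),
                                  band=(0.0, 0.0)),),
            options={"noise_sigma_mv": 0.05},
        )
        from gfdkit import ephys_analysis as ep
        amps = []
        for seed in range(10):
            tr = g.simulate_microsphere_channel(reg, None, t, seed=seed)
            amps += [e.amplitude for e in ep.detect_spikes(tr, fs=10.0, times=t)]
        amps = np.asarray(amps)
        se = amps.std(ddof=1) / math.sqrt(amps.size)
        assert np.mean(amps) == pytest.approx(10.0, abs=max(4 * se, 0.5))

    def test_modulation_scales_rate_monotonically(self):
        base = g.ModulationFactors()
        assert base.rate_multiplier() == pytest.approx(1.0)
        hotter = g.ModulationFactors(temperature_c=37.0)
        acidic = g.ModulationFactors(ph=5.0)
        salty = g.ModulationFactors(ionic_strength_scale=2.0)
        divalent = g.ModulationFactors(divalent_mM=5.0)
        for m in (hotter, acidic, salty, divalent):
            assert m.rate_multiplier() > 1.0
        assert g.ModulationFactors(temperature_c=15.0).rate_multiplier() < 1.0


class TestRecordings:
    def test_same_seed_bitwise_identical(self):
        cfg = g.default_config("mixture", duration_s=5000.0)
        r1 = g.simulate_recording(cfg, seed=3)
        r2 = g.simulate_recording(cfg, seed=3)
        assert all(np.array_equal(r1.channels[c], r2.channels[c]) for c in r1.channels)
        r3 = g.simulate_recording(cfg, seed=4)
        assert any(not np.array_equal(r1.channels[c], r3.channels[c]) for c in r1.channels)

    def test_overlapping_phases_rejected(self):
        with pytest.raises(ConfigurationError):
            g.ChannelRegime(
                morphology="microsphere", mode="threshold_spiker",
                phase_schedule=(Phase(0.0, 100.0), Phase(50.0, 200.0)),
            )

    def test_default_configs_build_for_all_morphologies(self):
        for m in ("microsphere", "fiber", "mixture", "control"):
            cfg = g.default_config(m, duration_s=10000.0)
            rec = g.simulate_recording(cfg, seed=0)
            assert rec.meta["morphology"] == m
            assert len(rec.channel_names) == len(cfg.channels)
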