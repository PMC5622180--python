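"""Waveform feature extraction: peaks, threshold crossings, invariants."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from ergtherm.core import Stimulus, baseline_correct
from ergtherm.exceptions import DetectionError, PreconditionError
from ergtherm.features import (
    FEATURE_NAMES,
    FeatureConfig,
    a_inflection,
    a_time_to_pct,
    b_time_to_pct,
    detect_a_peak,
    extract_observation,
    fit_b_peak,
    integration_time,
    lrs,
)
from ergtherm.simulator import (
    WaveformGenSpec,
    bright_template,
    dim_template,
    simulate_waveform,
)

from conftest import make_trace

FS = 10_000.0
NOFILT = FeatureConfig(apply_filters=False)
DT = 1.0 / FS


def _t(n):
    return np.arange(n) / FS


class TestDetectAPeak:
    def test_symmetric_sine_trough(self):
        t = _t(201)  # 0..20 ms
        tr = make_trace(-np.sin(np.pi * t / 0.020))
        t_apeak, v_apeak = detect_a_peak(tr, NOFILT)
        assert t_apeak == pytest.approx(0.010, abs=2 * DT)
        assert v_apeak == pytest.approx(-1.0, abs=1e-3)

    def test_parabola_trough_location(self):
        a = 0.0123
        t = _t(400)
        tr = make_trace((t - a) ** 2 - 1.0)
        t_apeak, _ = detect_a_peak(tr, NOFILT)
        assert t_apeak == pytest.approx(a, abs=2 * DT)

    def test_matches_brute_force_argmin_on_simulated_awave(self):
        spec = WaveformGenSpec(noise_sd_uV=0.0)
        stim = Stimulus(wavelength_nm=532, strength_rstar=170.0, cls="bright")
        tr = simulate_waveform(stim, 39.0, spec)
        config = FeatureConfig()
        filtered = config._maybe_filter(baseline_correct(tr), "bright")
        t_apeak, _ = detect_a_peak(filtered, config)
        v = filtered.voltage_uV
        i0 = filtered.flash_index
        i_min = i0 + int(np.argmin(v[i0 : i0 + 2000]))
        t_argmin = (i_min - i0) / FS
        assert t_apeak == pytest.approx(t_argmin, abs=2 * DT)

    def test_monotone_trace_raises(self):
        tr = make_trace(-_t(300))
        with pytest.raises(DetectionError):
            detect_a_peak(tr, NOFILT)


class TestATimeToPct:
    def test_linear_descent_crossings(self):
        t_apeak, v_apeak = 0.020, -10.0
        t = _t(201)
        tr = make_trace(v_apeak * t / t_apeak)
        for x in (10, 30, 50, 70, 90):
            tx = a_time_to_pct(tr, x, v_apeak, t_apeak)
            assert tx == pytest.approx(x / 100 * t_apeak, abs=2 * DT)

    def test_sine_closed_form(self):
        t = _t(201)
        tr = make_trace(-np.sin(np.pi * t / 0.020))
        tx = a_time_to_pct(tr, 50, -1.0, 0.010)
        expected = (0.020 / np.pi) * math.asin(0.5)  # 3.333 ms
        assert tx == pytest.approx(expected, abs=2 * DT)

    def test_monotone_in_pct(self):
        t = _t(301)
        tr = make_trace(-(t / 0.03) ** 1.5)
        times = [a_time_to_pct(tr, x, -1.0, 0.030) for x in range(10, 100, 10)]
        assert times == sorted(times)

    def test_positive_peak_rejected(self):
        with pytest.raises(PreconditionError):
            a_time_to_pct(make_trace(np.zeros(10)), 50, 1.0)

    def test_uncrossed_threshold_raises(self):
        tr = make_trace(np.full(100, -0.01))
        with pytest.raises(DetectionError):
            a_time_to_pct(tr, 90, -1.0, 0.005)


class TestAInflection:
    def test_exact_cubic_interior_minimum(self):
        t0 = 0.025
        t = _t(401)  # [0, 40 ms]
        tr = make_trace((t - t0) ** 3 * 1e6)
        assert a_inflection(tr, 0.040) == pytest.approx(t0, abs=1e-6)

    def test_quadratic_data_uses_endpoint_rule(self):
        t = _t(401)
        tr = make_trace(1e4 * t**2)  # p' minimized at the left endpoint
        assert a_inflection(tr, 0.040) == pytest.approx(0.0, abs=1e-6)

    def test_matches_dense_grid_argmin_of_fitted_derivative(self):
        spec = WaveformGenSpec(noise_sd_uV=0.0)
        stim = Stimulus(wavelength_nm=532, strength_rstar=170.0, cls="bright")
        config = FeatureConfig()
        tr = config._maybe_filter(
            baseline_correct(simulate_waveform(stim, 38.0, spec)), "bright"
        )
        t_apeak, _ = detect_a_peak(tr, config)
        got = a_inflection(tr, t_apeak)
        # independent grid oracle on the same cubic fit, 1 us resolution
        i0, i1 = tr.flash_index, tr.sample_at(t_apeak) + 1
        tt = (np.arange(i0, i1) - tr.flash_index) / FS
        coef = np.polyfit(tt, tr.voltage_uV[i0:i1], 3)
        grid = np.arange(tt[0], tt[-1], 1e-6)
        dp = np.polyval(np.polyder(coef), grid)
        assert got == pytest.approx(grid[np.argmin(dp)], abs=2e-6)

    def test_too_few_samples_rejected(self):
        tr = make_trace(np.zeros(100))
        with pytest.raises(DetectionError):
            a_inflection(tr, 0.0004)


class TestFitBPeak:
    def test_exact_parabola_vertex(self):
        t = _t(2001)
        tr = make_trace(100.0 - 5e4 * (t - 0.080) ** 2)
        t_bpeak, v_bpeak = fit_b_peak(tr, NOFILT)
        assert t_bpeak == pytest.approx(0.080, abs=1e-5)
        assert v_bpeak == pytest.approx(100.0, rel=1e-6)

    def test_symmetric_triangle_apex(self):
        t = _t(2001)
        tr = make_trace(np.maximum(0.0, 50.0 * (1 - np.abs(t - 0.1) / 0.08)))
        t_bpeak, _ = fit_b_peak(tr, NOFILT)
        assert t_bpeak == pytest.approx(0.100, abs=2 * DT)

    def test_gamma_bump_matches_grid_argmax(self):
        spec = WaveformGenSpec(noise_sd_uV=0.0, undershoot_frac=0.0)
        t = _t(10001)
        tr = make_trace(dim_template(t, spec, 532, 37.0))
        t_bpeak, v_bpeak = fit_b_peak(tr, NOFILT)
        grid = np.arange(0.0, 1.0, 1e-5)
        dense = dim_template(grid, spec, 532, 37.0)
        assert t_bpeak == pytest.approx(grid[np.argmax(dense)], abs=5e-4)
        assert v_bpeak == pytest.approx(dense.max(), rel=1e-3)

    def test_edge_maximum_rejected(self):
        tr = make_trace(_t(500))  # rising to the record edge
        with pytest.raises(DetectionError):
            fit_b_peak(tr, NOFILT)


def _triangle(t_p=0.1, height=40.0, n=4001):
    t = _t(n)
    v = np.maximum(0.0, height * (1 - np.abs(t - t_p) / t_p))
    return make_trace(v), t_p, height


class TestBTimeToPct:
    def test_triangle_closed_form(self):
        tr, t_p, h = _triangle()
        for x in (10, 30, 50, 70, 90):
            lead = b_time_to_pct(tr, x, "leading", t_p, h, NOFILT)
            trail = b_time_to_pct(tr, x, "trailing", t_p, h, NOFILT)
            assert lead == pytest.approx(x / 100 * t_p, abs=2 * DT)
            assert trail == pytest.approx((2 - x / 100) * t_p, abs=2 * DT)

    def test_monotone_in_pct(self):
        tr, t_p, h = _triangle()
        leads = [b_time_to_pct(tr, x, "leading", t_p, h, NOFILT) for x in range(10, 100, 10)]
        trails = [b_time_to_pct(tr, x, "trailing", t_p, h, NOFILT) for x in range(10, 100, 10)]
        assert leads == sorted(leads)
        assert trails == sorted(trails, reverse=True)

    def test_filtered_crossings_near_analytic(self):
        # filter bias bound: crossings on filtered trace within 2 ms of the
        # analytic crossings of the unfiltered template
        spec = WaveformGenSpec(noise_sd_uV=0.0, undershoot_frac=0.0)
        n = int(1.5 * FS)
        t = _t(n)
        tr = make_trace(dim_template(t, spec, 532, 37.0))
        config = FeatureConfig()
        lead_tr = config._maybe_filter(tr, "leading")
        trail_tr = config._maybe_filter(tr, "trailing")
        grid = np.arange(0.0, 1.5, 1e-6)
        dense = dim_template(grid, spec, 532, 37.0)
        peak_v = dense.max()
        i_peak = int(np.argmax(dense))
        for x in (20, 50, 80):
            lead = b_time_to_pct(lead_tr, x, "leading", spec.b_tpeak_s, peak_v, NOFILT)
            trail = b_time_to_pct(trail_tr, x, "trailing", spec.b_tpeak_s, peak_v, NOFILT)
            exact_lead = grid[np.argmax(dense > x / 100 * peak_v)]
            exact_trail = grid[i_peak + np.argmax(dense[i_peak:] < x / 100 * peak_v)]
            assert abs(lead - exact_lead) < 2e-3
            assert abs(trail - exact_trail) < 2e-3

    def test_trailing_never_reached_raises(self):
        t = _t(1000)
        tr = make_trace(np.minimum(t * 1000, 50.0))  # plateau, never descends
        with pytest.raises(DetectionError):
            b_time_to_pct(tr, 50, "trailing", 0.05, 50.0, NOFILT)


class TestIntegrationTime:
    def test_triangle_closed_form(self):
        # triangle of height A over [0, 2*tau]: integral A*tau, result tau
        tr, t_p, h = _triangle(t_p=0.1, height=40.0)
        assert integration_time(tr, t_p, h, NOFILT) == pytest.approx(0.1, rel=1e-3)

    def test_scale_invariance(self):
        tr, t_p, h = _triangle()
        scaled = tr.with_voltage(3.0 * tr.voltage_uV)
        a = integration_time(tr, t_p, h, NOFILT)
        b = integration_time(scaled, t_p, 3 * h, NOFILT)
        assert a == pytest.approx(b, rel=1e-12)

    def test_gamma_bump_matches_quadrature_oracle(self):
        spec = WaveformGenSpec(noise_sd_uV=0.0)
        n = int(1.5 * FS)
        t = _t(n)
        tr = make_trace(dim_template(t, spec, 532, 37.0))
        t_bpeak, v_bpeak = fit_b_peak(tr, NOFILT)
        got = integration_time(tr, t_bpeak, v_bpeak, NOFILT)
        # adaptive quadrature on the analytic template up to its zero crossing
        grid = np.arange(t_bpeak, 1.5, 1e-6)
        dense = dim_template(grid, spec, 532, 37.0)
        t_zero = grid[np.argmax(dense <= 0)]
        # integrate to the sampled zero-crossing time used by the implementation
        i_peak = tr.sample_at(t_bpeak)
        v = tr.voltage_uV
        i_zero = i_peak + 1 + int(np.argmax(v[i_peak + 1 :] <= 0))
        t_zero_sampled = i_zero / FS
        assert abs(t_zero_sampled - t_zero) < 2 * DT
        integral, _ = quad(
            lambda x: abs(dim_template(np.array([x]), spec, 532, 37.0)[0]),
            0.0,
            t_zero_sampled,
            limit=200,
        )
        oracle = integral / dense.max() if dense.max() > v_bpeak else integral / v_bpeak
        assert got == pytest.approx(integral / v_bpeak, rel=1e-3)

    def test_no_zero_crossing_raises(self):
        spec = WaveformGenSpec(noise_sd_uV=0.0, undershoot_frac=0.0)
        t = _t(int(1.5 * FS))
        tr = make_trace(dim_template(t, spec, 532, 37.0))  # pure bump, stays > 0
        with pytest.raises(DetectionError):
            integration_time(tr, spec.b_tpeak_s, spec.b_amp_uV, NOFILT)


class TestLrs:
    def test_equal_amplitudes_give_one(self):
        assert lrs(20.0, 20.0) == 1.0

    def test_ratio(self):
        assert lrs(20.0, 25.0) == pytest.approx(0.8)

    def test_nonpositive_amplitude_rejected(self):
        with pytest.raises(PreconditionError):
            lrs(-1.0, 20.0)

    def test_declines_when_780_boosted(self):
        # simulator ground truth: at elevated T the 780 nm amplitude grows
        spec = WaveformGenSpec(noise_sd_uV=0.0)
        t = _t(int(1.5 * FS))
        v532 = dim_template(t, spec, 532, 41.0).max()
        v780 = dim_template(t, spec, 780, 41.0).max()
        assert lrs(v532, v780) < 1.0


def _block(spec, T, rng=None, n_dim=4):
    dim532 = [
        simulate_waveform(Stimulus(532, 1.0, "dim"), T, spec, rng) for _ in range(n_dim)
    ]
    dim780 = [
        simulate_waveform(Stimulus(780, 1.0, "dim"), T, spec, rng) for _ in range(n_dim)
    ]
    bright = simulate_waveform(Stimulus(532, 170.0, "bright"), T, spec, rng)
    return bright, dim532, dim780


class TestExtractObservation:
    def test_identical_wavelength_responses(self):
        # same template for both wavelengths -> averaged kinetics match, LRS = 1
        spec = WaveformGenSpec(noise_sd_uV=0.0, amp_coeff_532=0.0, lrs_coeff=0.0)
        bright, dim532, dim780 = _block(spec, 37.0)
        obs = extract_observation(bright, dim532, dim780)
        assert obs.features["LRS"] == pytest.approx(1.0, abs=1e-9)
        assert obs.is_reference
        assert np.isfinite([obs.features[f] for f in FEATURE_NAMES]).all()

    def test_feature_ordering_invariants(self, rng):
        spec = WaveformGenSpec(noise_sd_uV=0.5)
        for T in (35.5, 38.0, 43.0):
            obs = extract_observation(*_block(spec, T, rng)).features
            a_times = [obs[f"a{x}"] for x in range(10, 101, 10)]
            assert all(np.diff(a_times) >= 0)
            lead = [obs[f"b{x}L"] for x in range(10, 91, 10)] + [obs["b100"]]
            assert all(np.diff(lead) >= 0)
            trail = [obs["b100"]] + [obs[f"b{x}T"] for x in range(90, 9, -10)]
            assert all(np.diff(trail) >= 0)
            assert obs["aa"] < 0 and obs["ba"] > 0 and obs["LRS"] > 0

    def test_amplitude_scaling_invariance(self):
        spec = WaveformGenSpec(noise_sd_uV=0.0)
        bright, dim532, dim780 = _block(spec, 39.0)
        obs1 = extract_observation(bright, dim532, dim780).features
        k = 2.7
        scale = lambda tr: tr.with_voltage(k * tr.voltage_uV)
        obs2 = extract_observation(
            scale(bright), [scale(t) for t in dim532], [scale(t) for t in dim780]
        ).features
        for name in FEATURE_NAMES:
            if name in ("aa", "ba"):
                assert obs2[name] == pytest.approx(k * obs1[name], rel=1e-9)
            else:
                assert obs2[name] == pytest.approx(obs1[name], rel=1e-9)

    def test_time_axis_scaling(self):
        # V(t) vs V(t/s): every time feature scales by s (filters disabled)
        spec = WaveformGenSpec(noise_sd_uV=0.0)
        s = 1.1

        def stretch(tr):
            t = tr.time_s
            if tr.stimulus.cls == "bright":
                v = bright_template(t / s, spec, 38.5)
            else:
                v = dim_template(t / s, spec, tr.stimulus.wavelength_nm, 38.5)
            return tr.with_voltage(v)

        bright, dim532, dim780 = _block(spec, 38.5, n_dim=1)
        config = FeatureConfig(apply_filters=False)
        obs1 = extract_observation(bright, dim532, dim780, config).features
        obs2 = extract_observation(
            stretch(bright), [stretch(dim532[0])], [stretch(dim780[0])], config
        ).features
        for name in FEATURE_NAMES:
            if name in ("aa", "ba", "LRS"):
                continue
            assert obs2[name] == pytest.approx(s * obs1[name], abs=2.5 * DT)

    def test_replicate_averaging_reduces_noise(self):
        # features from 4 replicates scatter ~1/2 as much as from 1
        spec = WaveformGenSpec(noise_sd_uV=3.0)
        sds = {1: [], 4: []}
        for n_dim in (1, 4):
            vals = []
            for seed in range(12):
                rng = np.random.default_rng(seed)
                obs = extract_observation(*_block(spec, 39.0, rng, n_dim=n_dim))
                vals.append(obs.features["b70T"])
            sds[n_dim] = np.std(vals)
        assert sds[4] < sds[1]

    def test_missing_dim_traces_rejected(self):
        spec = WaveformGenSpec(noise_sd_uV=0.0)
        bright, dim532, _ = _block(spec, 39.0)
        with pytest.raises(PreconditionError):
            extract_observation(bright, dim532, [])

    def test_noiseless_template_crossings_within_one_sample(self):
        # extraction on the raw template matches 1 us dense-grid crossings
        spec = WaveformGenSpec(noise_sd_uV=0.0)
        T = 40.0
        bright, dim532, dim780 = _block(spec, T, n_dim=1)
        config = FeatureConfig(apply_filters=False)
        obs = extract_observation(bright, dim532, dim780, config).features
        grid = np.arange(1e-6, 1.2, 1e-6)
        dense = dim_template(grid, spec, 532, T)
        peak_v = dense.max()
        i_peak = int(np.argmax(dense))
        for x in (20, 50, 80):
            exact_lead = grid[np.argmax(dense > x / 100 * peak_v)]
            exact_trail = grid[i_peak + np.argmax(dense[i_peak:] < x / 100 * peak_v)]
            assert abs(obs[f"b{x}L"] - exact_lead) <= 2 * DT
            assert abs(obs[f"b{x}T"] - exact_trail) <= 2 * DT
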