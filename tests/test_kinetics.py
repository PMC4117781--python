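"""Mixing arithmetic, binning, SVD and exponential rate fitting."""

import numpy as np
import pytest

from ncsaxs import (NoiseModel, TimeSeries, bin_time, fit_exponential,
                    mixing_concentration, model_selection, scheme_5s,
                    scheme_601, simulate_disassembly, svd_analysis,
                    species_fractions, trace_i0_rg)
from ncsaxs.scatter import ScatteringProfile


def make_series(I_matrix, sigma_matrix, times, q=None):
    nq = I_matrix.shape[0]
    q = np.linspace(0.01, 0.25, nq) if q is None else q
    frames = [ScatteringProfile(q, I_matrix[:, j], sigma_matrix[:, j],
                                meta={"time": float(t)})
              for j, t in enumerate(times)]
    return TimeSeries(frames, times, frame_duration=0.02)


class TestMixing:
    def test_stopped_flow_condition(self):
        assert mixing_concentration(0.2, 3.0, (2, 3)) == pytest.approx(1.88)

    def test_equal_concentrations_unchanged(self):
        assert mixing_concentration(0.7, 0.7, (5, 2)) == pytest.approx(0.7)

    def test_one_to_one(self):
        assert mixing_concentration(0.2, 3.0, (1, 1)) == pytest.approx(1.6)

    def test_zero_volume_rejected(self):
        with pytest.raises(ValueError):
            mixing_concentration(0.2, 3.0, (0, 0))


class TestBinning:
    def test_identical_frames_reduce_sigma(self):
        nq, nt = 30, 8
        I = np.ones((nq, nt))
        S = 0.1 * np.ones((nq, nt))
        ts = make_series(I, S, 0.02 * np.arange(1, nt + 1))
        b = bin_time(ts, 1, scheme="fixed")
        assert len(b) == 1
        np.testing.assert_allclose(b.frames[0].I, 1.0)
        np.testing.assert_allclose(b.frames[0].sigma, 0.1 / np.sqrt(nt))

    def test_single_frame_bins_are_identity(self):
        nq, nt = 20, 5
        rng = np.random.default_rng(0)
        I = rng.random((nq, nt)) + 1
        S = 0.05 * I
        ts = make_series(I, S, 0.02 * np.arange(1, nt + 1))
        b = bin_time(ts, nt, scheme="fixed")
        assert len(b) == nt
        for j in range(nt):
            np.testing.assert_allclose(b.frames[j].I, I[:, j])

    def test_total_inverse_variance_conserved(self):
        nq, nt = 25, 40
        rng = np.random.default_rng(1)
        I = rng.random((nq, nt)) + 1
        S = 0.02 * (rng.random((nq, nt)) + 0.5)
        ts = make_series(I, S, 0.02 * np.arange(1, nt + 1))
        b = bin_time(ts, 6, scheme="log")
        iv_in = np.sum(1.0 / S ** 2)
        iv_out = sum(np.sum(1.0 / f.sigma ** 2) for f in b.frames)
        assert iv_out == pytest.approx(iv_in, rel=1e-9)

    def test_log_bin_times_span_window(self):
        nq, nt = 10, 3000
        I = np.ones((nq, nt))
        S = 0.1 * np.ones((nq, nt))
        times = 0.02 * np.arange(1, nt + 1)
        ts = make_series(I, S, times)
        b = bin_time(ts, 12, scheme="log")
        assert np.all(np.diff(b.times) > 0)
        assert b.times[0] < 0.1 and b.times[-1] > 30.0


class TestSVD:
    def test_single_species_rank_one(self):
        q = np.linspace(0.01, 0.25, 40)
        shape = np.exp(-(q * 30) ** 2 / 3)
        amp = np.linspace(1, 0.2, 15)
        I = np.outer(shape, amp)
        S = 0.01 * np.ones_like(I)
        ts = make_series(I, S, 0.02 * np.arange(1, 16), q)
        assert svd_analysis(ts).n_significant == 1

    def test_two_species_interconversion_rank_two(self):
        q = np.linspace(0.01, 0.25, 150)
        s1 = np.exp(-(q * 40) ** 2 / 3)
        s2 = 1.0 / (1 + (q * 60) ** 2)
        t = 0.1 * np.arange(1, 31)
        f = np.exp(-1.5 * t)
        I = np.outer(s1, f) + np.outer(s2, 1 - f)
        S = 1e-4 * np.ones_like(I)
        ts = make_series(I, S, t, q)
        assert svd_analysis(ts).n_significant == 2

    def test_three_species_disassembly_at_least_two(self):
        # wrapped -> open -> free with 1% noise across 10 seeds
        scheme = scheme_5s()
        times = np.arange(0.02, 8.0, 0.04)
        for seed in range(10):
            ts, _ = simulate_disassembly(
                scheme, times, sucrose=0.0, seed=seed,
                noise=NoiseModel(relative_gaussian=0.01))
            b = bin_time(ts, 30, scheme="log")
            assert svd_analysis(b).n_significant >= 2

    def test_ragged_grids_rejected(self):
        f1 = ScatteringProfile([0.01, 0.02], [1, 1], [0.1, 0.1])
        f2 = ScatteringProfile([0.01, 0.03], [1, 1], [0.1, 0.1])
        ts = TimeSeries([f1, f2], np.array([0.02, 0.04]))
        with pytest.raises(ValueError):
            svd_analysis(ts)


class TestExponentialFits:
    def test_single_exponential_exact(self):
        t = np.linspace(0.05, 10, 60)
        y = 2.0 + 3.0 * np.exp(-0.9 * t)
        fit = fit_exponential(t, y, 1e-6 * np.ones_like(y), n_exp=1)
        assert fit.rates[0] == pytest.approx(0.9, rel=1e-6)
        assert fit.baseline == pytest.approx(2.0, rel=1e-6)

    def test_double_exponential_ratio_40(self):
        t = np.geomspace(0.005, 10, 120)
        y = 1.0 + 2.0 * np.exp(-40.0 * t) + 1.5 * np.exp(-1.0 * t)
        fit = fit_exponential(t, y, 1e-6 * np.ones_like(y), n_exp=2)
        assert fit.rates[0] == pytest.approx(40.0, rel=0.01)
        assert fit.rates[1] == pytest.approx(1.0, rel=0.01)

    def test_second_component_degenerate_on_single_exp_data(self):
        t = np.linspace(0.05, 10, 80)
        rng = np.random.default_rng(2)
        y = 1.0 + 2.0 * np.exp(-0.8 * t)
        y = y * (1 + 1e-4 * rng.standard_normal(len(t)))
        fit = fit_exponential(t, y, 1e-4 * y, n_exp=2)
        amp_scale = abs(fit.amplitudes).max()
        assert fit.degenerate or abs(fit.amplitudes).min() < 0.05 * amp_scale

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_exponential([0.1, 0.2, 0.3], [1, 2, 3], n_exp=1)

    def test_rate_recovery_unbiased_with_coverage(self):
        # 20 seeds at the generator's default 2% noise: median bias
        # within 5% and ~68% of fits within one reported sigma
        k_true = 0.74
        t = np.geomspace(0.05, 12, 80)
        clean = 1.0 + 1.6 * np.exp(-k_true * t)
        rng = np.random.default_rng(7)
        rates, hits = [], 0
        for _ in range(20):
            y = clean * (1 + 0.02 * rng.standard_normal(len(t)))
            fit = fit_exponential(t, y, 0.02 * clean, n_exp=1)
            rates.append(fit.rates[0])
            if np.isfinite(fit.rate_errors[0]) and \
                    abs(fit.rates[0] - k_true) <= fit.rate_errors[0]:
                hits += 1
        assert np.median(rates) == pytest.approx(k_true, rel=0.05)
        assert 0.45 <= hits / 20 <= 0.90


class TestModelSelection:
    def test_synthetic_601_trace_single_phase(self):
        scheme = scheme_601()
        t = np.arange(0.22, 20, 0.05)
        frac = species_fractions(scheme, t)
        y = (frac.T @ [1.0, 0.55])
        rng = np.random.default_rng(3)
        y = y * (1 + 0.01 * rng.standard_normal(len(t)))
        assert model_selection(t, y, 0.01 * y) == 1

    def test_synthetic_5s_trace_double_phase(self):
        scheme = scheme_5s()
        t = np.geomspace(0.005, 10, 150)
        frac = species_fractions(scheme, t)
        y = (frac.T @ [1.0, 0.72, 0.55])
        rng = np.random.default_rng(4)
        y = y * (1 + 0.005 * rng.standard_normal(len(t)))
        assert model_selection(t, y, 0.005 * y) == 2

    def test_flat_trace_single_phase(self):
        t = np.linspace(0.05, 10, 50)
        rng = np.random.default_rng(5)
        y = 1.0 + 0.002 * rng.standard_normal(len(t))
        assert model_selection(t, y, 0.002 * np.ones_like(y)) == 1


class TestTraces:
    def test_stationary_series_gives_flat_traces(self, wrapped147):
        from ncsaxs import debye_profile

        prof = debye_profile(wrapped147, smear_sigma=1.5)
        prof.sigma = 0.01 * prof.I
        frames = [prof] * 6
        ts = TimeSeries(list(frames), 0.02 * np.arange(1, 7))
        t, i0, rg, ok = trace_i0_rg(ts, method="ift", dmax=150.0)
        assert ok.all()
        assert np.ptp(i0) / i0.mean() < 1e-9
        assert np.ptp(rg) / rg.mean() < 1e-9

    def test_601_sucrose_i0_flat_while_rg_rises(self):
        # protein blanked: I(0) constant within noise, Rg grows
        scheme = scheme_601()
        times = np.arange(0.02, 12, 0.02)
        ts, _ = simulate_disassembly(scheme, times, sucrose=0.5, seed=0)
        b = bin_time(ts, 24, scheme="log")
        t, i0, rg, ok = trace_i0_rg(b, method="ift", dmax=560.0)
        i0, rg, t = i0[ok], rg[ok], t[ok]
        assert np.ptp(i0) / i0.mean() < 0.08
        assert rg[-1] > rg[0] + 10.0

    def test_601_no_sucrose_i0_holds_then_decays(self):
        scheme = scheme_601()
        times = np.arange(0.02, 12, 0.02)
        ts, _ = simulate_disassembly(scheme, times, sucrose=0.0, seed=0)
        b = bin_time(ts, 24, scheme="log")
        t, i0, rg, ok = trace_i0_rg(b, method="ift", dmax=560.0)
        early = i0[ok & (t < 0.18)]
        late = i0[ok & (t > 8.0)]
        assert np.ptp(early) / early.mean() < 0.05
        assert late.mean() < 0.75 * early.mean()
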