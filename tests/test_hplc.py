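"""Tests for the synthetic-chromatogram generator and the double-Gaussian fit."""

from dataclasses import replace

import numpy as np
import pytest
from scipy.integrate import trapezoid

from phageforge import (
    Chromatogram,
    DoubleGaussianPeak,
    FitResult,
    SimSpec,
    display_ratio,
    fit_double_gaussians,
    pick_initial_params,
    simulate_chromatogram,
)
from phageforge.hplc import _peak_from_shape, recover_ratio


class TestSimulator:
    def test_zero_antigen_single_peak(self):
        chrom, truth = simulate_chromatogram(SimSpec(antigen_area_fraction=0.0))
        assert truth == 0.0
        spec = SimSpec(antigen_area_fraction=0.0)
        wt = _peak_from_shape(spec.wt_center, spec.total_area, spec.wt_shape)
        assert np.allclose(chrom.signal, wt(chrom.time))

    def test_symmetry_at_half(self):
        """Equal areas and shapes give a trace symmetric about the midpoint."""
        spec = SimSpec(antigen_area_fraction=0.5,
                       wt_shape=replace(SimSpec().wt_shape, tail_offset=0.0,
                                        sigma2=0.35, sigma1=0.18))
        spec = replace(spec, antigen_shape=spec.wt_shape)
        chrom, _ = simulate_chromatogram(spec)
        mid = spec.wt_center + spec.shoulder_offset / 2
        t = np.linspace(mid - 2, mid + 2, 2001)
        wt = _peak_from_shape(spec.wt_center, 50.0, spec.wt_shape)
        ant = _peak_from_shape(spec.wt_center + spec.shoulder_offset, 50.0,
                               spec.antigen_shape)
        y = wt(t) + ant(t)
        assert np.allclose(y, y[::-1], atol=1e-9)

    @pytest.mark.parametrize("f", [0.0, 0.136, 0.5, 0.9])
    def test_quadrature_oracle(self, f):
        """Numerically integrated antigen share equals the spec value to 1e-6."""
        spec = SimSpec(antigen_area_fraction=f)
        _, truth = simulate_chromatogram(spec)
        wt = _peak_from_shape(spec.wt_center, spec.total_area * (1 - f),
                              spec.wt_shape)
        ant = _peak_from_shape(spec.wt_center + spec.shoulder_offset,
                               spec.total_area * f, spec.antigen_shape)
        t = np.linspace(spec.wt_center - 12, spec.wt_center + 12, 400001)
        a_wt = trapezoid(wt(t), t)
        a_ant = trapezoid(ant(t), t)
        assert abs(a_ant / (a_wt + a_ant) - f) < 1e-6
        assert truth == f

    def test_noise_deterministic(self):
        a, _ = simulate_chromatogram(SimSpec(noise_sd=1.0, seed=42))
        b, _ = simulate_chromatogram(SimSpec(noise_sd=1.0, seed=42))
        c, _ = simulate_chromatogram(SimSpec(noise_sd=1.0, seed=43))
        assert np.array_equal(a.signal, b.signal)
        assert not np.array_equal(a.signal, c.signal)

    def test_chromatogram_validation(self):
        with pytest.raises(ValueError):
            Chromatogram(np.array([1.0, 1.0, 2.0]), np.zeros(3))
        with pytest.raises(ValueError):
            Chromatogram(np.array([1.0, 2.0]), np.array([np.nan, 0.0]))


class TestInitialization:
    def test_single_peak_small_antigen_init(self):
        chrom, _ = simulate_chromatogram(SimSpec(antigen_area_fraction=0.0))
        init = pick_initial_params(chrom)
        ant_height = max(init.antigen_peak.a1, init.antigen_peak.a2)
        wt_height = max(init.wt_peak.a1, init.wt_peak.a2)
        assert ant_height <= 0.1 * wt_height

    def test_two_peak_centers_close_to_truth(self):
        chrom, _ = simulate_chromatogram(SimSpec(antigen_area_fraction=0.136))
        init = pick_initial_params(chrom)
        assert abs(init.wt_peak.mu1 - 51.3) < 0.3
        assert abs(init.antigen_peak.mu1 - 51.9) < 0.3

    def test_flat_trace_error(self):
        with pytest.raises(ValueError):
            pick_initial_params(
                Chromatogram(np.linspace(48, 55, 200), np.zeros(200)))


class TestFitRecovery:
    @pytest.mark.parametrize("f", [0.05, 0.122, 0.136, 0.363, 0.5,
                                   0.574, 0.703, 0.9])
    def test_noiseless_recovery(self, f):
        rec, truth = recover_ratio(SimSpec(antigen_area_fraction=f))
        assert abs(rec - truth) <= 0.005

    def test_null_antigen(self):
        chrom, _ = simulate_chromatogram(SimSpec(antigen_area_fraction=0.0))
        fit = fit_double_gaussians(chrom)
        assert fit.converged and fit.display_ratio <= 0.01

    def test_noisy_mean_recovery(self):
        """1% noise: mean over 20 seeds within 2 percentage points."""
        for f in (0.136, 0.574):
            clean, _ = simulate_chromatogram(SimSpec(antigen_area_fraction=f))
            sd = 0.01 * float(clean.signal.max())
            recs = [
                recover_ratio(SimSpec(antigen_area_fraction=f,
                                      noise_sd=sd, seed=s))[0]
                for s in range(20)
            ]
            assert abs(float(np.mean(recs)) - f) <= 0.02

    @pytest.mark.parametrize("offset", [0.3, 0.6, 1.2])
    def test_overlap_stress(self, offset):
        rec, _ = recover_ratio(
            SimSpec(antigen_area_fraction=0.136, shoulder_offset=offset))
        assert abs(rec - 0.136) <= 0.01

    def test_monotone_in_truth(self):
        prev = -1.0
        for f in np.linspace(0.05, 0.95, 8):
            rec, _ = recover_ratio(SimSpec(antigen_area_fraction=float(f)))
            assert rec >= prev - 1e-6
            prev = rec

    def test_free_14_parameter_mode_runs(self):
        chrom, _ = simulate_chromatogram(SimSpec(antigen_area_fraction=0.363))
        fit = fit_double_gaussians(chrom, share_shape=False)
        assert fit.converged
        assert abs(fit.display_ratio - 0.363) <= 0.02

    def test_baseline_and_drift_handled(self):
        spec = SimSpec(antigen_area_fraction=0.363, baseline_intercept=2.0,
                       baseline_slope=0.15)
        rec, _ = recover_ratio(spec)
        assert abs(rec - 0.363) <= 0.01

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            fit_double_gaussians(
                Chromatogram(np.linspace(0, 1, 10), np.ones(10)))


class TestDisplayRatio:
    def test_identical_peaks_half(self):
        pk = DoubleGaussianPeak(1.0, 0.5, 51.3, 51.5, 0.2, 0.3)
        pk2 = DoubleGaussianPeak(1.0, 0.5, 51.9, 52.1, 0.2, 0.3)
        fit = FitResult(pk, pk2, (0.0, 0.0), 0.5, 0.0, True)
        assert display_ratio(fit) == pytest.approx(0.5)

    def test_zero_antigen(self):
        pk = DoubleGaussianPeak(1.0, 0.5, 51.3, 51.5, 0.2, 0.3)
        null = DoubleGaussianPeak(0.0, 0.0, 51.9, 52.1, 0.2, 0.3)
        fit = FitResult(pk, null, (0.0, 0.0), 0.0, 0.0, True)
        assert display_ratio(fit) == 0.0

    def test_zero_total_area_error(self):
        null = DoubleGaussianPeak(0.0, 0.0, 51.3, 51.5, 0.2, 0.3)
        fit = FitResult(null, null, (0.0, 0.0), 0.0, 0.0, True)
        with pytest.raises(ValueError):
            display_ratio(fit)
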