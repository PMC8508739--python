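"""Reconvolution forward model, global fitting, and decay-associated spectra."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from unfoldscope import simulate, tcspc
from unfoldscope.errors import (
    DomainError,
    GridError,
    InsufficientDataError,
    RangeError,
)


def make_model(taus, amps, bg=0.0):
    return tcspc.MultiExpModel(lifetimes=taus, amplitudes=amps, background=bg)


class TestConvolution:
    def test_delta_irf_reduces_to_pure_exponential(self, delta_irf):
        model = make_model([2.0], [1000.0])
        out = tcspc.convolve_decay(model, delta_irf, 400)
        k = np.arange(1, 400)
        # bin-integrated kernel: exact exponential shape, amplitude within
        # (channel_width/tau)^2/24 of nominal
        np.testing.assert_allclose(out[1:], 1000.0 * np.exp(-k * 0.027 / 2.0),
                                   rtol=1e-4)
        # the excitation channel itself holds only the causal half-bin
        assert out[0] == pytest.approx(500.0, rel=5e-3)

    def test_zero_amplitudes_give_flat_background(self, delta_irf):
        model = make_model([2.0, 1.0], [0.0, 0.0], bg=5.0)
        out = tcspc.convolve_decay(model, delta_irf, 400)
        np.testing.assert_allclose(out, 5.0)

    def test_output_never_below_background(self, delta_irf):
        model = make_model([1.5], [300.0], bg=7.0)
        out = tcspc.convolve_decay(model, delta_irf, 400)
        assert np.all(out >= 7.0 - 1e-12)

    def test_matches_dense_grid_quadrature_oracle(self):
        # Gaussian IRF, sigma = 0.5 ns, tau = 5.1 ns: compare the channel-grid
        # convolution against trapezoid quadrature on a 50x finer grid.
        dt, n, tau, sigma, center = 0.027, 1024, 5.1, 0.5, 3.0
        t = np.arange(n) * dt
        irf = tcspc.InstrumentResponse(
            counts=1e4 * np.exp(-0.5 * ((t - center) / sigma) ** 2),
            channel_width=dt,
        )
        out = tcspc.convolve_decay(make_model([tau], [1.0]), irf, n)

        over = 50
        tf = np.arange(n * over) * (dt / over)
        gf = np.exp(-0.5 * ((tf - center) / sigma) ** 2)
        gf /= np.trapezoid(gf, tf)
        oracle = np.array([
            np.trapezoid(
                gf[: i * over + 1] * np.exp(-(tk - tf[: i * over + 1]) / tau),
                tf[: i * over + 1],
            )
            for i, tk in enumerate(t)
        ])
        sel = oracle > 0.1 * oracle.max()
        np.testing.assert_allclose(out[sel], oracle[sel], rtol=1e-3)
        assert np.abs(out - oracle).max() < 1e-3 * oracle.max()

    def test_channel_width_mismatch_raises(self, delta_irf):
        with pytest.raises(GridError):
            tcspc.convolve_decay(make_model([2.0], [1.0]), delta_irf, 400,
                                 channel_width=0.05)

    def test_nonpositive_lifetime_rejected(self):
        with pytest.raises(DomainError):
            make_model([2.0, -1.0], [1.0, 1.0])


class TestFitting:
    def test_noiseless_single_exponential_recovered_to_4_digits(self, delta_irf):
        model = make_model([2.0], [5000.0])
        counts = np.round(tcspc.convolve_decay(model, delta_irf, 400))
        trace = tcspc.DecayTrace(wavelength=350.0, counts=counts,
                                 channel_width=0.027)
        fit = tcspc.fit_single_decay(trace, delta_irf, n_components=1)
        assert fit.converged
        assert fit.model.lifetimes[0] == pytest.approx(2.0, rel=5e-4)

    def test_all_zero_trace_is_insufficient(self, delta_irf):
        trace = tcspc.DecayTrace(wavelength=350.0, counts=np.zeros(400),
                                 channel_width=0.027)
        with pytest.raises(InsufficientDataError):
            tcspc.fit_single_decay(trace, delta_irf, n_components=1)

    def test_lifetimes_sorted_descending(self, bundle_fit):
        assert np.all(np.diff(bundle_fit.model.lifetimes) < 0)

    def test_lifetimes_shared_across_wavelengths(self, bundle_fit):
        # the global model carries exactly one lifetime vector for all 19
        # traces: per-wavelength linkage is structural, not approximate
        assert bundle_fit.model.lifetimes.shape == (3,)
        assert bundle_fit.model.amplitudes.shape == (19, 3)

    def test_three_component_recovery_within_5_percent(self):
        errs = []
        for seed in range(3):
            bundle = simulate.simulate_decays(simulate.DecaySimSpec(seed=seed))
            fit = tcspc.global_fit(bundle.traces, bundle.irf, 3, seed=seed)
            assert fit.converged
            errs.append([
                abs(fit.model.lifetimes[0] - 5.1) / 5.1,
                abs(fit.model.lifetimes[1] - 1.9) / 1.9,
            ])
        assert np.max(errs) < 0.05

    def test_reduced_chi2_near_one_on_well_specified_data(self, bundle_fit):
        assert 0.8 < bundle_fit.chi2_reduced < 1.2

    def test_global_fit_consistent_with_single_trace_fit(self, delta_irf):
        model = make_model([3.0, 1.0], [4000.0, 3000.0])
        counts = np.round(tcspc.convolve_decay(model, delta_irf, 400))
        traces = [
            tcspc.DecayTrace(wavelength=wl, counts=counts, channel_width=0.027)
            for wl in (340.0, 360.0)
        ]
        single = tcspc.fit_single_decay(traces[0], delta_irf, 2)
        joint = tcspc.global_fit(traces, delta_irf, 2)
        np.testing.assert_allclose(joint.model.lifetimes,
                                   single.model.lifetimes, rtol=1e-4)

    def test_fit_invariant_under_count_rescaling(self, delta_irf):
        model = make_model([3.0, 1.0], [4000.0, 3000.0])
        expected = tcspc.convolve_decay(model, delta_irf, 400)
        fits = []
        for factor in (1, 4):
            trace = tcspc.DecayTrace(wavelength=350.0,
                                     counts=np.round(expected * factor),
                                     channel_width=0.027)
            fits.append(tcspc.fit_single_decay(trace, delta_irf, 2))
        np.testing.assert_allclose(fits[0].model.lifetimes,
                                   fits[1].model.lifetimes, rtol=1e-3)

    def test_inconsistent_grids_rejected(self, delta_irf):
        traces = [
            tcspc.DecayTrace(wavelength=340.0, counts=np.full(400, 200.0),
                             channel_width=0.05),
        ]
        with pytest.raises(GridError):
            tcspc.global_fit(traces, delta_irf, 1)


class TestSpectralFractions:
    def _fit_like(self, taus, amps):
        model = tcspc.MultiExpModel(lifetimes=taus, amplitudes=amps)
        return tcspc.GlobalFitResult(
            model=model, chi2_global=0.0, chi2_reduced=1.0,
            weighted_residuals=[], covariance=None, converged=True,
            n_data=1, n_free=1,
        )

    def test_equal_amplitudes_equal_lifetimes_split_evenly(self):
        frac, mean = tcspc.spectral_fractions(
            self._fit_like([2.0, 2.0], [[1.0, 1.0]])
        )
        np.testing.assert_allclose(frac, 0.5)

    def test_amplitude_lifetime_weighting(self):
        frac, _ = tcspc.spectral_fractions(
            self._fit_like([3.0, 1.0], [[1.0, 1.0]])
        )
        np.testing.assert_allclose(frac[0], [0.75, 0.25])

    def test_fractions_sum_to_one_on_real_fit(self, bundle_fit):
        frac, mean = tcspc.spectral_fractions(bundle_fit)
        np.testing.assert_allclose(frac.sum(axis=1), 1.0, atol=1e-9)
        assert mean.sum() == pytest.approx(1.0, abs=1e-9)

    def test_all_zero_wavelength_reported_missing(self):
        with pytest.warns(UserWarning):
            frac, mean = tcspc.spectral_fractions(
                self._fit_like([3.0, 1.0], [[1.0, 1.0], [0.0, 0.0]])
            )
        assert np.isnan(frac[1]).all()
        assert not np.isnan(mean).any()


class TestDecayAssociatedSpectra:
    def spectrum(self):
        wl = np.arange(305.0, 451.0, 1.0)
        return tcspc.SteadyStateSpectrum(wl, np.full(wl.size, 100.0))

    def test_single_component_das_equals_steady_state(self):
        wl = np.arange(320.0, 411.0, 5.0)
        das = tcspc.decay_associated_spectra(np.ones((wl.size, 1)), wl,
                                             self.spectrum())
        np.testing.assert_allclose(das.component_spectra[:, 0], 100.0)

    def test_fraction_45_55_partition(self):
        # two components holding constant 45%/55% of a flat spectrum
        wl = np.arange(320.0, 411.0, 5.0)
        frac = np.tile([0.45, 0.55], (wl.size, 1))
        das = tcspc.decay_associated_spectra(frac, wl, self.spectrum())
        np.testing.assert_allclose(das.component_spectra[:, 0], 45.0)
        np.testing.assert_allclose(das.component_spectra[:, 1], 55.0)
        np.testing.assert_allclose(das.mean_fractions, [0.45, 0.55])

    def test_component_spectra_conserve_steady_state(self, bundle_fit):
        frac, _ = tcspc.spectral_fractions(bundle_fit)
        wl = bundle_fit.model.wavelengths
        das = tcspc.decay_associated_spectra(frac, wl, self.spectrum())
        np.testing.assert_allclose(
            das.component_spectra.sum(axis=1), das.fractions.sum(axis=1) * 100.0,
            rtol=1e-12,
        )
        np.testing.assert_allclose(das.component_spectra.sum(axis=1), 100.0,
                                   atol=1e-7)

    def test_wavelength_outside_spectrum_raises(self):
        wl = np.array([300.0, 320.0])
        with pytest.raises(RangeError):
            tcspc.decay_associated_spectra(np.ones((2, 1)), wl, self.spectrum())

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_random_fractions_conserve_spectrum(self, seed):
        rng = np.random.default_rng(seed)
        wl = np.arange(320.0, 411.0, 5.0)
        raw = rng.uniform(0.01, 1.0, (wl.size, 3))
        frac = raw / raw.sum(axis=1, keepdims=True)
        iss = tcspc.SteadyStateSpectrum(
            np.arange(305.0, 451.0), rng.uniform(1.0, 500.0, 146)
        )
        das = tcspc.decay_associated_spectra(frac, wl, iss)
        np.testing.assert_allclose(
            das.component_spectra.sum(axis=1), iss.at(wl), rtol=1e-9
        )
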