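"""Rev-OCE estimation chain: scaling, demodulation, kernel, recovery, volumetry."""
import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_
from scipy.integrate import quad
from scipy.special import j0

import organoidlab as ol
from organoidlab import revoce as rv
from organoidlab.pipeline import Thresholds, process_organoid


class TestPhaseToVelocity:
    def test_formula_spot_value(self, default_acq):
        """Δφ = π with λ0=840 nm, n=1.34, Δt=40 µs gives vz = 3.918 mm/s."""
        p = ol.PhaseVolume(
            np.full((default_acq.n_timepoints, 2, 2), np.pi), default_acq
        )
        vz = ol.phase_to_velocity(p).vz
        expected = 840e-9 / (4 * 1.34 * 40e-6)
        assert vz == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(3.918e-3, rel=1e-3)

    def test_zero_and_linearity(self, small_acq, rng):
        dphi = rng.uniform(-1.0, 1.0, (small_acq.n_timepoints, 3, 3))
        v1 = ol.phase_to_velocity(ol.PhaseVolume(dphi, small_acq)).vz
        v2 = ol.phase_to_velocity(ol.PhaseVolume(2 * dphi, small_acq)).vz
        np.testing.assert_allclose(v2, 2 * v1, rtol=1e-12)
        z = ol.phase_to_velocity(
            ol.PhaseVolume(np.zeros_like(dphi), small_acq)
        ).vz
        assert np.all(z == 0)

    def test_nonfinite_phase_rejected(self, small_acq):
        dphi = np.zeros((small_acq.n_timepoints, 2, 2))
        dphi[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            ol.phase_to_velocity(ol.PhaseVolume(dphi, small_acq))


class TestExtractHarmonic:
    def test_bin_centered_tone_amplitude_exact(self, small_acq):
        t = np.arange(small_acq.n_timepoints) * small_acq.delta_t
        tone = 2.5e-3 * np.cos(2 * np.pi * 3000.0 * t)
        v = ol.VelocityField(np.tile(tone[:, None, None], (1, 2, 2)), small_acq)
        h = ol.extract_harmonic(v)
        assert np.abs(h.amplitude[0, 0]) == pytest.approx(2.5e-3, rel=1e-6)

    def test_dc_field_has_no_harmonic(self, small_acq):
        v = ol.VelocityField(
            np.ones((small_acq.n_timepoints, 2, 2)) * 1e-3, small_acq
        )
        h = ol.extract_harmonic(v)
        assert np.abs(h.amplitude).max() < 1e-9

    def test_beyond_nyquist_rejected(self, small_acq):
        v = ol.VelocityField(
            np.zeros((small_acq.n_timepoints, 2, 2)), small_acq
        )
        with pytest.raises(ValueError, match="Nyquist"):
            ol.extract_harmonic(v, freq=small_acq.aline_rate)

    def test_white_noise_periodogram_level(self, small_acq):
        """Expected harmonic power of pure noise matches periodogram theory."""
        rng = np.random.default_rng(0)
        sigma = 1e-4
        powers = []
        w = np.abs(np.fft.rfft(np.ones(small_acq.n_timepoints)))  # placeholder
        from scipy.signal import get_window

        win = get_window("flattop", small_acq.n_timepoints, fftbins=True)
        for _ in range(500):
            noise = rng.normal(0, sigma, (small_acq.n_timepoints, 1, 1))
            h = ol.extract_harmonic(ol.VelocityField(noise, small_acq))
            powers.append(np.abs(h.amplitude[0, 0]) ** 2)
        expected = 4 * sigma**2 * np.sum(win**2) / win.sum() ** 2
        assert np.mean(powers) == pytest.approx(expected, rel=0.2)


class TestSpatialBandpass:
    @staticmethod
    def _annulus_field(acq, k_min, k_max, seed=0):
        """Random field whose spectrum is strictly inside [k_min, k_max]."""
        nx, ny = acq.grid_points
        dx, dy = acq.grid_spacing
        kx = 2 * np.pi * np.fft.fftfreq(nx, d=dx)
        ky = 2 * np.pi * np.fft.fftfreq(ny, d=dy)
        kr = np.hypot(kx[:, None], ky[None, :])
        rng = np.random.default_rng(seed)
        spec = (rng.normal(size=(nx, ny)) + 1j * rng.normal(size=(nx, ny)))
        spec[(kr < k_min) | (kr > k_max)] = 0.0
        return np.fft.ifft2(spec)

    def test_in_band_field_passes_unchanged(self, default_acq):
        amp = self._annulus_field(default_acq, 10000.0, 18000.0)
        h = ol.HarmonicField(amp, 3000.0, default_acq)
        out = ol.spatial_bandpass(h, 8000.0, 30000.0)
        ref = np.linalg.norm(amp)
        assert np.linalg.norm(out.amplitude - amp) / ref < 1e-3

    def test_out_of_band_plane_wave_suppressed(self, default_acq):
        nx = default_acq.grid_points[0]
        dx = default_acq.grid_spacing[0]
        dk = 2 * np.pi / (nx * dx)
        k_wave = 19 * dk  # bin-aligned, ~59 krad/m, above the band
        x = np.arange(nx) * dx
        amp = np.exp(1j * k_wave * x)[:, None] * np.ones(default_acq.grid_points[1])
        h = ol.HarmonicField(amp, 3000.0, default_acq)
        out = ol.spatial_bandpass(h, 8000.0, 30000.0)
        assert (
            np.sum(np.abs(out.amplitude) ** 2) / np.sum(np.abs(amp) ** 2) <= 1e-4
        )

    def test_energy_never_increases(self, homogeneous_harmonic):
        out = ol.spatial_bandpass(homogeneous_harmonic, 5000.0, 20000.0)
        assert np.sum(np.abs(out.amplitude) ** 2) <= np.sum(
            np.abs(homogeneous_harmonic.amplitude) ** 2
        ) * (1 + 1e-12)

    def test_invalid_band_rejected(self, homogeneous_harmonic):
        with pytest.raises(ValueError):
            ol.spatial_bandpass(homogeneous_harmonic, 2e4, 1e4)
        with pytest.raises(ValueError, match="Nyquist"):
            ol.spatial_bandpass(homogeneous_harmonic, 1e4, 1e9)


class TestReverberantKernel:
    def test_matches_sphere_average_quadrature(self):
        """Closed form equals the direct sphere-average integral.

        The transverse-lag autocorrelation of the axial component is
        (3/4)∫ sin³θ J0(a sinθ) dθ — evaluated numerically as the oracle.
        """
        a_vals = np.linspace(0.0, 2 * np.pi, 40)
        for a in a_vals:
            oracle = quad(lambda th: np.sin(th) ** 3 * j0(a * np.sin(th)), 0, np.pi)[0]
            oracle /= 4.0 / 3.0
            assert ol.reverberant_kernel(a) == pytest.approx(oracle, abs=1e-10)

    def test_matches_simulation_derived_kernel(self):
        """Analytic kernel within 2% RMS of the empirical kernel from
        simulated homogeneous fields, over kΔr in [0, 2π]."""
        klag, prof = ol.empirical_autocorrelation_kernel(n_realizations=10, seed=3)
        sel = klag <= 2 * np.pi
        rms = np.sqrt(np.mean((prof[sel] - ol.reverberant_kernel(klag[sel])) ** 2))
        assert rms < 0.02

    def test_normalisation_and_sign_structure(self):
        assert ol.reverberant_kernel(0.0) == pytest.approx(1.0)
        a = np.linspace(0, 2 * np.pi, 200)
        b = ol.reverberant_kernel(a)
        assert b.min() < 0  # anticorrelation lobe beyond the first zero


class TestWavenumberEstimation:
    def test_homogeneous_recovery_within_5pct(self, homogeneous_harmonic, default_acq):
        km = ol.estimate_wavenumber_map(homogeneous_harmonic, default_acq)
        sm = ol.wavenumber_to_speed(km, 3000.0)
        med = np.median(sm.vs[sm.valid])
        assert med == pytest.approx(2.0, rel=0.05)

    def test_shell_core_k_ordering(self, two_compartment_phantom, default_acq):
        """Softer core (1.5 m/s) shows larger wavenumbers than the shell."""
        wins = 0
        for seed in range(3):
            summary, _ = process_organoid(
                two_compartment_phantom, default_acq,
                ol.SimSpec(rng_seed=seed), Thresholds(),
            )
            wins += summary.surface_mean > summary.core_mean
        assert wins >= 2

    def test_white_noise_yields_no_valid_windows(self, default_acq, rng):
        amp = rng.normal(size=default_acq.grid_points) + 1j * rng.normal(
            size=default_acq.grid_points
        )
        h = ol.HarmonicField(amp, 3000.0, default_acq)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            km = ol.estimate_wavenumber_map(h, default_acq)
        assert km.valid.mean() <= 0.10

    def test_window_below_three_samples_rejected(self):
        acq = ol.AcquisitionConfig(
            grid_points=(11, 11), scan_extent=(2e-3, 2e-3), window_size=0.2e-3
        )
        h = ol.HarmonicField(np.ones((11, 11), complex), 3000.0, acq)
        with pytest.raises(ValueError, match="3-sample"):
            ol.estimate_wavenumber_map(h, acq)


class TestWavenumberToSpeed:
    def test_direct_arithmetic(self):
        km = ol.WavenumberMap(
            k=np.array([[2 * np.pi * 1000.0]]), fit_quality=np.ones((1, 1)),
            valid=np.ones((1, 1), bool), x_centers=np.zeros(1),
            y_centers=np.zeros(1), window_size=5e-4,
        )
        sm = ol.wavenumber_to_speed(km, 3000.0)
        assert sm.vs[0, 0] == pytest.approx(3.0)

    def test_product_invariant_and_inverse_proportionality(self, rng):
        k = rng.uniform(3000, 30000, (4, 4))
        km = ol.WavenumberMap(
            k=k, fit_quality=np.ones_like(k), valid=np.ones_like(k, bool),
            x_centers=np.zeros(4), y_centers=np.zeros(4), window_size=5e-4,
        )
        sm = ol.wavenumber_to_speed(km, 3000.0)
        np.testing.assert_allclose(sm.vs * k, 2 * np.pi * 3000.0)
        sm2 = ol.wavenumber_to_speed(
            ol.WavenumberMap(
                k=2 * k, fit_quality=np.ones_like(k), valid=np.ones_like(k, bool),
                x_centers=np.zeros(4), y_centers=np.zeros(4), window_size=5e-4,
            ),
            3000.0,
        )
        np.testing.assert_allclose(sm2.vs, sm.vs / 2)


class TestRegionSummary:
    @staticmethod
    def _uniform_map(value, n=7):
        vs = np.full((n, n), value)
        return ol.SpeedMap(
            vs=vs, valid=np.ones_like(vs, bool),
            x_centers=np.linspace(0, 2e-3, n), y_centers=np.linspace(0, 2e-3, n),
            freq=3000.0,
        )

    def test_uniform_speed_equal_region_means(self):
        sm = self._uniform_map(2.5)
        mask = np.ones((7, 7), bool)
        s = ol.regionwise_speed_summary(sm, mask)
        assert s.surface_mean == pytest.approx(2.5)
        assert s.core_mean == pytest.approx(2.5)
        assert not s.errors

    def test_empty_mask_flags_both_regions(self):
        sm = self._uniform_map(2.5)
        s = ol.regionwise_speed_summary(sm, np.zeros((7, 7), bool))
        assert "surface region empty" in s.errors
        assert "core region empty" in s.errors


class TestMorphometry:
    def test_unit_sphere_volume(self):
        m = ol.organoid_volume(d_horizontal=1.0, d_vertical=1.0)
        assert m.volume == pytest.approx((4 / 3) * math.pi * 0.5**3)
        assert m.volume == pytest.approx(0.5236, abs=5e-5)

    def test_diameter_averaging(self):
        m = ol.organoid_volume(d_horizontal=0.8, d_vertical=1.2)
        assert m.d_mean == pytest.approx(1.0)
        assert m.volume == pytest.approx(0.5236, abs=5e-5)

    def test_cubic_scaling(self):
        v1 = ol.organoid_volume(d_horizontal=1.0, d_vertical=1.0).volume
        v2 = ol.organoid_volume(d_horizontal=2.0, d_vertical=2.0).volume
        assert v2 == pytest.approx(8 * v1, rel=1e-12)

    def test_nonpositive_diameter_rejected(self):
        with pytest.raises(ValueError):
            ol.organoid_volume(d_horizontal=0.0, d_vertical=1.0)

    @given(
        d1=st_.floats(0.1, 5.0), d2=st_.floats(0.1, 5.0), delta=st_.floats(0.01, 1.0)
    )
    @settings(max_examples=50, deadline=None)
    def test_volume_monotone_in_mean_diameter(self, d1, d2, delta):
        base = ol.organoid_volume(d_horizontal=d1, d_vertical=d2)
        bigger = ol.organoid_volume(d_horizontal=d1 + delta, d_vertical=d2)
        assert bigger.volume > base.volume


class TestEndToEndRecovery:
    def test_speed_recovery_noiseless_vs2(self, default_acq):
        """Full simulate -> encode -> decode -> estimate chain at vs = 2 m/s."""
        from organoidlab.pipeline import speed_recovery_study

        rec = speed_recovery_study(
            speeds=(2.0,), n_acquisitions=4, seed=21, acq=default_acq
        )
        assert rec[2.0] == pytest.approx(2.0, rel=0.05)
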