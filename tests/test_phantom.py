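"""Synthetic generators: spectral structure, determinism, ground-truth hooks."""
import numpy as np
import pandas as pd
import pytest

import organoidlab as ol
from organoidlab import phantom as ph


def _ring_peak_wavenumber(amplitude: np.ndarray, dx: float) -> float:
    """Peak of the radially averaged 2D spatial power spectrum (rad/m)."""
    nx, ny = amplitude.shape
    spec = np.abs(np.fft.fft2(amplitude)) ** 2
    kx = 2 * np.pi * np.fft.fftfreq(nx, d=dx)
    ky = 2 * np.pi * np.fft.fftfreq(ny, d=dx)
    kr = np.hypot(kx[:, None], ky[None, :])
    dk = 2 * np.pi / (nx * dx)
    idx = np.round(kr / dk).astype(int)
    power = np.bincount(idx.ravel(), weights=spec.ravel())
    counts = np.bincount(idx.ravel())
    radial = power / np.maximum(counts, 1)
    return float(np.argmax(radial[1:]) + 1) * dk  # skip DC


class TestReverberantField:
    def test_spatial_spectrum_concentrates_on_ring(self, default_acq):
        """Homogeneous vs=2 m/s at 3 kHz: spectrum peaks at |k|=2πF/vs ≈ 9424.8."""
        phantom = ol.homogeneous_phantom(2.0, default_acq)
        v = ol.simulate_reverberant_field(phantom, default_acq, ol.SimSpec(rng_seed=0))
        h = ol.extract_harmonic(v)
        k_peak = _ring_peak_wavenumber(h.amplitude, default_acq.grid_spacing[0])
        k_true = 2 * np.pi * 3000.0 / 2.0
        dk = 2 * np.pi / (default_acq.grid_points[0] * default_acq.grid_spacing[0])
        assert abs(k_peak - k_true) <= dk

    def test_single_plane_wave_is_monochromatic(self, small_acq):
        phantom = ol.homogeneous_phantom(2.0, small_acq)
        sim = ol.SimSpec(n_plane_waves=1, rng_seed=5)
        v = ol.simulate_reverberant_field(phantom, small_acq, sim)
        spec = np.abs(np.fft.rfft(v.vz[:, 10, 17]))
        freqs = np.fft.rfftfreq(small_acq.n_timepoints, small_acq.delta_t)
        assert freqs[np.argmax(spec)] == pytest.approx(3000.0, abs=1 / (
            small_acq.n_timepoints * small_acq.delta_t))
        # single tone: spectral mass concentrated at the peak
        assert spec.max() > 10 * np.median(spec)

    def test_seeded_determinism(self, small_acq):
        phantom = ol.homogeneous_phantom(2.0, small_acq)
        sim = ol.SimSpec(rng_seed=42, noise_sd_velocity=1e-4)
        a = ol.simulate_reverberant_field(phantom, small_acq, sim)
        b = ol.simulate_reverberant_field(phantom, small_acq, sim)
        np.testing.assert_array_equal(a.vz, b.vz)

    def test_under_resolved_wavelength_rejected(self, small_acq):
        slow = ol.homogeneous_phantom(0.2, small_acq)  # λ = 67 µm << 4 px
        with pytest.raises(ValueError, match="under-resolved"):
            ol.simulate_reverberant_field(slow, small_acq, ol.SimSpec())

    def test_rms_matches_requested_amplitude(self, small_acq):
        phantom = ol.homogeneous_phantom(2.0, small_acq)
        v = ol.simulate_reverberant_field(phantom, small_acq, ol.SimSpec(rng_seed=2))
        assert np.sqrt(np.mean(v.vz**2)) == pytest.approx(1.0e-3, rel=0.15)


class TestPhaseEncoding:
    def test_zero_velocity_zero_phase(self, small_acq):
        v = ol.VelocityField(np.zeros((small_acq.n_timepoints, 4, 4)), small_acq)
        assert np.all(ph.field_to_phase_volume(v).dphi == 0)

    def test_wrap_boundary_velocity(self, small_acq):
        """vz = λ0/(4nΔt) sits exactly at the Δφ = π wrap boundary."""
        vz_pi = small_acq.lambda0 / (4 * small_acq.n_refractive * small_acq.delta_t)
        v = ol.VelocityField(
            np.full((small_acq.n_timepoints, 2, 2), vz_pi), small_acq
        )
        p = ph.field_to_phase_volume(v)
        assert np.allclose(p.dphi, np.pi)

    def test_round_trip_below_wrap_limit(self, small_acq, rng):
        vz = rng.uniform(-3.9e-3, 3.9e-3, (small_acq.n_timepoints, 5, 5))
        v = ol.VelocityField(vz, small_acq)
        back = ol.phase_to_velocity(ph.field_to_phase_volume(v))
        np.testing.assert_allclose(back.vz, vz, rtol=1e-12)


class TestBrillouinSimulator:
    CAL = ol.AffinePixelMap(slope=0.03, intercept=-7.68)

    def test_noiseless_argmax_maps_to_true_shift(self):
        spec = ol.simulate_brillouin_spectrum(5.0, 0.3, self.CAL)
        peak_px = int(np.argmax(spec.intensity))
        assert self.CAL.pixel_to_ghz(peak_px) == pytest.approx(5.0, abs=0.03)

    def test_deterministic_given_seed(self):
        a = ol.simulate_brillouin_spectrum(5.0, 0.3, self.CAL, noise_sd=20, seed=7)
        b = ol.simulate_brillouin_spectrum(5.0, 0.3, self.CAL, noise_sd=20, seed=7)
        np.testing.assert_array_equal(a.intensity, b.intensity)

    def test_out_of_range_shift_rejected(self):
        with pytest.raises(ValueError, match="spectrometer range"):
            ol.simulate_brillouin_spectrum(9.0, 0.3, self.CAL)


class TestOCTSimulator:
    def test_noiseless_threshold_recovers_truth(self):
        vol = ol.simulate_oct_volume(ol.OrganoidPhantom(), 2e-5, snr=np.inf)
        thr = (0.1 + 0.7) / 2
        assert np.array_equal(vol.intensity > thr, vol.truth_mask)

    def test_equivalent_diameter_recovered(self):
        sphere = ol.OrganoidPhantom(shell_outer_radius=0.5e-3, core_radius=0.3e-3)
        vol = ol.simulate_oct_volume(sphere, 1e-5, snr=np.inf)
        d_eq = (6 * vol.truth_mask.sum() / np.pi) ** (1 / 3) * 1e-5
        assert abs(d_eq - 1.0e-3) <= 2e-5  # within 2 voxels of 1 mm

    def test_background_only_volume_has_no_object(self):
        vol = ol.simulate_oct_volume(None, 2e-5, snr=5, seed=0, shape=(40, 40, 40))
        assert not vol.truth_mask.any()

    def test_shell_thickness_resolution_enforced(self):
        with pytest.raises(ValueError, match="resolve"):
            ol.simulate_oct_volume(ol.OrganoidPhantom(), 2e-4)


class TestCountSimulator:
    def test_null_effects_reproduce_baseline_means(self):
        """No effects, near-zero dispersion, equal libraries: sample means hit
        baseline_mu within 3 SE at 200 replicates."""
        rows = [
            {"sample": f"c{i}", "arm": "control", "timepoint": "day20", "replicate": i}
            for i in range(200)
        ]
        design = ol.GroupDesign(pd.DataFrame(rows))
        mu = pd.Series(
            np.full(11, 50.0), index=["FOLR1", *ol.NEURO_GENES, "GENE00000"]
        )
        counts = ol.simulate_counts(
            design, baseline_mu=mu, dispersion=0.0,
            effects=pd.DataFrame(index=[], columns=["DTG10"]),
            seed=3, library_size_range=1.0,
        )
        se = np.sqrt(50.0 / 200)
        assert np.all(np.abs(counts.mean(axis=1) - 50.0) < 3 * se)

    def test_folr1_induction_survives_fc_threshold(self):
        design = ol.default_design()
        counts = ol.simulate_counts(design, seed=0)
        nm = ol.cpm_normalize(counts)
        de = ol.fold_changes(nm, design)
        folr1 = de[de.gene == "FOLR1"]
        assert (folr1.fc > 15).all()  # 2^8 = 256 >> 15 in every exposure arm

    def test_negative_binomial_moments(self):
        rows = [
            {"sample": f"c{i}", "arm": "control", "timepoint": "day20", "replicate": i}
            for i in range(400)
        ]
        design = ol.GroupDesign(pd.DataFrame(rows))
        mu = pd.Series(
            np.full(11, 100.0), index=["FOLR1", *ol.NEURO_GENES, "GENE00000"]
        )
        counts = ol.simulate_counts(
            design, baseline_mu=mu, dispersion=0.1,
            effects=pd.DataFrame(index=[], columns=["DTG10"]),
            seed=5, library_size_range=1.0,
        )
        var = counts.var(axis=1)
        expected = 100.0 + 0.1 * 100.0**2  # mu + phi mu²
        assert np.median(var) == pytest.approx(expected, rel=0.25)

    def test_fixed_seed_identity(self):
        design = ol.default_design()
        a = ol.simulate_counts(design, n_genes=50, seed=9)
        b = ol.simulate_counts(design, n_genes=50, seed=9)
        assert a.equals(b)

    def test_absent_gene_in_effects_rejected(self):
        design = ol.default_design()
        eff = pd.DataFrame({"DTG10": [2.0]}, index=["NOT_A_GENE"])
        with pytest.raises(ValueError, match="absent"):
            ol.simulate_counts(design, effects=eff, seed=0)
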