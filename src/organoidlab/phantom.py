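"""Synthetic-data generators with known ground truth for every estimator.

Four families of inputs are produced:

* reverberant shear-wave velocity fields over two-compartment spherical
  organoid phantoms (stiff shell, softer core, agarose-like background),
  encoded to sequential-A-line phase differences;
* Brillouin spectra — Stokes/anti-Stokes Lorentzian pairs seen through an
  affine pixel-to-GHz spectrometer map — plus reference-liquid spectra for
  calibration;
* OCT intensity volumes with gamma-distributed speckle;
* negative-binomial RNA-seq count matrices for the five-arm, two-timepoint
  exposure design, with a large planted FOLR1 induction and moderate
  perturbations of a neurodevelopment gene set.

Heterogeneous reverberant fields are synthesised with locally varying
wavenumber: one isotropic plane-wave set per compartment, sharing directions,
polarizations and phases but using the compartment's wavenumber, blended over
a ~2-pixel transition band.  Exact elastodynamic scattering is out of scope;
the wavenumber estimator is local and windowed, so local-k synthesis is the
standard test harness for it.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import (
    ARMS,
    TIMEPOINTS,
    AcquisitionConfig,
    OrganoidPhantom,
    SimSpec,
    homogeneous_phantom,
    nominal_wavenumber,
)
from .revoce import PhaseVolume, VelocityField, velocity_to_phase_increment

#: Neurodevelopment genes that receive moderate planted perturbations.
NEURO_GENES = (
    "DVL3", "GATA2", "KIF22", "LHX2", "NEUROG1",
    "NKX2-2", "NTF3", "SEMA6B", "WNT8B",
)

__all__ = [
    "NEURO_GENES",
    "AffinePixelMap",
    "BrillouinSpectrum",
    "OCTVolume",
    "GroupDesign",
    "simulate_reverberant_field",
    "field_to_phase_volume",
    "simulate_brillouin_spectrum",
    "simulate_shift_map",
    "simulate_oct_volume",
    "simulate_counts",
    "default_design",
    "default_effects",
    "phantom_mask_on_grid",
]


# ---------------------------------------------------------------------------
# Reverberant field
# ---------------------------------------------------------------------------

def _random_directions_and_polarizations(
    n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Directions uniform on the sphere; transverse polarizations uniform in
    the plane perpendicular to each direction."""
    z = rng.uniform(-1.0, 1.0, n)
    az = rng.uniform(0.0, 2.0 * math.pi, n)
    s = np.sqrt(1.0 - z**2)
    nhat = np.stack([s * np.cos(az), s * np.sin(az), z], axis=1)
    # orthonormal basis (e1, e2) of each wave's transverse plane
    helper = np.zeros_like(nhat)
    helper[:, 0] = 1.0
    near_x = np.abs(nhat[:, 0]) > 0.9
    helper[near_x] = [0.0, 1.0, 0.0]
    e1 = np.cross(nhat, helper)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(nhat, e1)
    psi = rng.uniform(0.0, 2.0 * math.pi, n)
    phat = np.cos(psi)[:, None] * e1 + np.sin(psi)[:, None] * e2
    return nhat, phat


def _plane_wave_sum(
    k: float,
    nhat: np.ndarray,
    amp_z: np.ndarray,
    phases: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    z0: float,
) -> np.ndarray:
    """Complex axial-velocity amplitude of a plane-wave superposition.

    The phase of wave q at (x, y, z0) is k (n_q·r) + φ_q, which is separable
    in x and y, so the field reduces to a single (nx, Q) @ (Q, ny) product.
    """
    cz = amp_z * np.exp(1j * (k * nhat[:, 2] * z0 + phases))  # (Q,)
    ex = np.exp(1j * k * np.outer(x, nhat[:, 0]))  # (nx, Q)
    ey = np.exp(1j * k * np.outer(nhat[:, 1], y))  # (Q, ny)
    return (ex * cz[None, :]) @ ey


def _region_weights(
    phantom: OrganoidPhantom, x: np.ndarray, y: np.ndarray, dx: float
) -> dict[str, np.ndarray]:
    """Smooth compartment weights on the scan plane z = phantom centre z.

    Logistic ramps with a ~2-pixel transition band; weights sum to 1.
    """
    cx, cy, _ = phantom.center
    d = np.hypot(x[:, None] - cx, y[None, :] - cy)
    tau = 0.5 * dx

    def sig(u: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-u / tau))

    inside_core = sig(phantom.core_radius - d)
    inside_shell = sig(phantom.shell_outer_radius - d)
    return {
        "core": inside_core,
        "shell": np.clip(inside_shell - inside_core, 0.0, 1.0),
        "background": 1.0 - inside_shell,
    }


def simulate_reverberant_field(
    phantom: OrganoidPhantom, acq: AcquisitionConfig, sim: SimSpec
) -> VelocityField:
    """Synthesize the axial particle velocity of a reverberant shear field.

    ``n_plane_waves`` shear plane waves with directions uniform on the sphere
    and random transverse polarizations are superposed; the local wavenumber
    at each scan-plane point is 2πF/vs of the phantom compartment containing
    it.  All waves share the excitation frequency, so the time dependence
    factors and the full (t, x, y) record is the real part of a single
    complex spatial field rotated at ωt.  Additive Gaussian velocity noise is
    applied per sample.  Identical ``SimSpec`` seeds give identical fields.
    """
    dx, dy = acq.grid_spacing
    # resolvability: >= ~4 samples per wavelength in every compartment
    for name, vs in phantom.region_speeds.items():
        lam = vs / acq.excitation_freq
        if lam / max(dx, dy) < 4.0:
            raise ValueError(
                f"shear wavelength in region {name!r} ({lam * 1e3:.3f} mm) is "
                f"under-resolved on the grid (spacing {max(dx, dy) * 1e3:.3f} mm); "
                "need >= 4 samples per wavelength"
            )
    rng = np.random.default_rng(sim.rng_seed)
    nhat, phat = _random_directions_and_polarizations(sim.n_plane_waves, rng)
    phases = rng.uniform(0.0, 2.0 * math.pi, sim.n_plane_waves)
    if sim.amplitude_model == "rayleigh":
        amps = rng.rayleigh(1.0, sim.n_plane_waves)
        scale = math.sqrt(3.0)  # E[a²]=2, E[p_z²]=1/3 -> var = 1/3 per unit rms
    else:
        amps = np.ones(sim.n_plane_waves)
        scale = math.sqrt(6.0)  # var = 1/6 for unit constant amplitudes
    amps = amps * (scale * sim.rms_velocity / math.sqrt(sim.n_plane_waves))
    amp_z = amps * phat[:, 2]  # axial projection of the polarization

    nx, ny = acq.grid_points
    x = np.arange(nx) * dx
    y = np.arange(ny) * dy
    z0 = phantom.center[2]

    if phantom.is_homogeneous():
        k = nominal_wavenumber(phantom.vs_background, acq.excitation_freq)
        V = _plane_wave_sum(k, nhat, amp_z, phases, x, y, z0)
    else:
        weights = _region_weights(phantom, x, y, dx)
        V = np.zeros((nx, ny), dtype=complex)
        for name, vs in phantom.region_speeds.items():
            w = weights[name]
            if not np.any(w > 1e-6):
                continue
            k = nominal_wavenumber(vs, acq.excitation_freq)
            V += w * _plane_wave_sum(k, nhat, amp_z, phases, x, y, z0)

    omega = 2.0 * math.pi * acq.excitation_freq
    t = np.arange(acq.n_timepoints) * acq.delta_t
    vz = np.cos(omega * t)[:, None, None] * V.real[None] + np.sin(omega * t)[:, None, None] * V.imag[None]
    if sim.noise_sd_velocity > 0:
        vz = vz + rng.normal(0.0, sim.noise_sd_velocity, vz.shape)
    return VelocityField(vz=vz, acq=acq)


def field_to_phase_volume(v: VelocityField, acq: AcquisitionConfig | None = None) -> PhaseVolume:
    """Encode a velocity field as wrapped sequential-A-line phase differences.

    Δφ = 4πnΔt·vz/λ0 wrapped into (−π, π]; the exact inverse of the velocity
    scaling whenever no wrapping occurs.
    """
    if acq is None:
        acq = v.acq
    dphi = velocity_to_phase_increment(v)
    wrapped = np.mod(dphi + math.pi, 2.0 * math.pi) - math.pi  # [-π, π)
    wrapped[wrapped == -math.pi] = math.pi  # convention: (−π, π]
    return PhaseVolume(dphi=wrapped, acq=acq)


def empirical_autocorrelation_kernel(
    vs: float = 2.0,
    freq: float = 3000.0,
    n_realizations: int = 12,
    seed: int = 0,
    n_plane_waves: int = 2000,
    aperture_wavelengths: float = 4.8,
) -> tuple[np.ndarray, np.ndarray]:
    """Numerically estimated reverberant kernel from simulated fields.

    Simulates ``n_realizations`` independent homogeneous reverberant fields
    over an aperture of several wavelengths, pools their raw radial
    autocorrelation profiles, and returns ``(k * lag, profile)`` normalised to
    1 at zero lag, covering k*lag up to ~2π.  Serves as the independent
    oracle for the closed-form kernel used by the wavenumber fitter.
    """
    from .revoce import _raw_radial_profile, extract_harmonic

    lam = vs / freq
    dx = lam / 33.0
    n = int(round(aperture_wavelengths * lam / dx)) + 1
    acq = AcquisitionConfig(
        grid_points=(n, n),
        scan_extent=((n - 1) * dx, (n - 1) * dx),
        n_timepoints=50,
        excitation_freq=freq,
    )
    phantom = homogeneous_phantom(vs, acq)
    prof_sum = None
    for i in range(n_realizations):
        sim = SimSpec(rng_seed=seed + i, n_plane_waves=n_plane_waves)
        v = simulate_reverberant_field(phantom, acq, sim)
        h = extract_harmonic(v, window="boxcar")
        rbar, prof = _raw_radial_profile(h.amplitude, dx, lam * 1.02)
        prof_sum = prof if prof_sum is None else prof_sum + prof
    k = 2.0 * math.pi * freq / vs
    return k * rbar, prof_sum / prof_sum[0]


def phantom_mask_on_grid(
    phantom: OrganoidPhantom, x_centers: np.ndarray, y_centers: np.ndarray
) -> np.ndarray:
    """Boolean organoid mask (shell outer radius) on an (x, y) centre grid."""
    cx, cy, _ = phantom.center
    d = np.hypot(
        np.asarray(x_centers)[:, None] - cx, np.asarray(y_centers)[None, :] - cy
    )
    return d <= phantom.shell_outer_radius


# ---------------------------------------------------------------------------
# Brillouin spectra
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AffinePixelMap:
    """Affine spectrometer dispersion: frequency (GHz) = slope * pixel + intercept."""

    slope: float  # GHz per pixel
    intercept: float  # GHz

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("slope must be nonzero")

    def pixel_to_ghz(self, pixel: np.ndarray | float) -> np.ndarray | float:
        return self.slope * np.asarray(pixel, dtype=float) + self.intercept

    def ghz_to_pixel(self, ghz: np.ndarray | float) -> np.ndarray | float:
        return (np.asarray(ghz, dtype=float) - self.intercept) / self.slope


@dataclass
class BrillouinSpectrum:
    """Spectrometer intensity trace (counts vs pixel index)."""

    intensity: np.ndarray
    exposure_time: float = 0.2

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 1 or self.intensity.size < 32:
            raise ValueError("spectrum must be a 1D trace of >= 32 pixels")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")


def _lorentzian(x: np.ndarray, center: float, hwhm: float) -> np.ndarray:
    return hwhm**2 / ((x - center) ** 2 + hwhm**2)


def simulate_brillouin_spectrum(
    true_shift: float,
    linewidth: float,
    calib: AffinePixelMap,
    noise_sd: float = 0.0,
    seed: int | None = None,
    n_pixels: int = 512,
    amplitude: float = 1000.0,
    baseline: float = 20.0,
    exposure_time: float = 0.2,
) -> BrillouinSpectrum:
    """Synthetic Stokes/anti-Stokes Lorentzian pair seen through ``calib``.

    The two peaks sit at ±``true_shift`` GHz about the elastic line, mapped to
    pixels through the affine dispersion; ``linewidth`` is the FWHM in GHz.
    Gaussian read noise of SD ``noise_sd`` counts is added (clipped at zero).
    """
    p_plus = calib.ghz_to_pixel(true_shift)
    p_minus = calib.ghz_to_pixel(-true_shift)
    if not (0 <= min(p_plus, p_minus) and max(p_plus, p_minus) <= n_pixels - 1):
        raise ValueError(
            f"shift {true_shift} GHz maps outside the spectrometer range "
            f"(pixels {p_minus:.1f}, {p_plus:.1f} of {n_pixels})"
        )
    px = np.arange(n_pixels, dtype=float)
    hwhm_px = (linewidth / 2.0) / abs(calib.slope)
    trace = baseline + amplitude * (
        _lorentzian(px, p_plus, hwhm_px) + _lorentzian(px, p_minus, hwhm_px)
    )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        trace = np.clip(trace + rng.normal(0.0, noise_sd, n_pixels), 0.0, None)
    return BrillouinSpectrum(intensity=trace, exposure_time=exposure_time)


def simulate_shift_map(
    phantom: OrganoidPhantom,
    x_centers: np.ndarray,
    y_centers: np.ndarray,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> np.ndarray:
    """Per-point true Brillouin shifts (GHz) on a grid over the phantom plane.

    Points in the shell take ``brillouin_shift_shell``, core points the core
    shift, background NaN (no sample); optional Gaussian measurement noise.
    """
    cx, cy, _ = phantom.center
    d = np.hypot(
        np.asarray(x_centers)[:, None] - cx, np.asarray(y_centers)[None, :] - cy
    )
    out = np.full(d.shape, np.nan)
    out[d <= phantom.shell_outer_radius] = phantom.brillouin_shift_shell
    out[d <= phantom.core_radius] = phantom.brillouin_shift_core
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        out = out + rng.normal(0.0, noise_sd, out.shape)
    return out


# ---------------------------------------------------------------------------
# OCT volumes
# ---------------------------------------------------------------------------

@dataclass
class OCTVolume:
    """OCT intensity volume with the generating ground truth attached."""

    intensity: np.ndarray  # (x, y, z)
    voxel_size: float  # metres
    truth_mask: np.ndarray | None = None  # boolean organoid mask, same shape


def simulate_oct_volume(
    phantom: OrganoidPhantom | None,
    voxel_size: float,
    snr: float = 5.0,
    seed: int | None = None,
    shape: tuple[int, int, int] | None = None,
    mean_object: float = 1.0,
    mean_core: float = 0.7,
    mean_background: float = 0.1,
) -> OCTVolume:
    """Speckled OCT intensity volume of a spherical organoid phantom.

    Speckle is modelled as gamma-distributed multiplicative noise with shape
    ``snr**2`` (so mean/SD = snr); ``snr = inf`` gives the noiseless template.
    With ``phantom=None`` a background-only volume of ``shape`` voxels is
    produced (no object; ``truth_mask`` all False).
    """
    if phantom is None:
        if shape is None:
            raise ValueError("shape required for a background-only volume")
        template = np.full(shape, mean_background)
        truth = np.zeros(shape, dtype=bool)
    else:
        if (phantom.shell_outer_radius - phantom.core_radius) / voxel_size < 2.0:
            raise ValueError("voxel_size must resolve the shell thickness with >= 2 voxels")
        if shape is None:
            n = int(math.ceil(2.0 * phantom.shell_outer_radius * 1.4 / voxel_size)) | 1
            shape = (n, n, n)
        cx = (np.arange(shape[0]) - (shape[0] - 1) / 2.0) * voxel_size
        cy = (np.arange(shape[1]) - (shape[1] - 1) / 2.0) * voxel_size
        cz = (np.arange(shape[2]) - (shape[2] - 1) / 2.0) * voxel_size
        d = np.sqrt(
            cx[:, None, None] ** 2 + cy[None, :, None] ** 2 + cz[None, None, :] ** 2
        )
        truth = d <= phantom.shell_outer_radius
        template = np.full(shape, mean_background)
        template[truth] = mean_object
        template[d <= phantom.core_radius] = mean_core
    if np.isinf(snr):
        intensity = template.copy()
    else:
        rng = np.random.default_rng(seed)
        m = snr**2
        intensity = template * rng.gamma(m, 1.0 / m, size=template.shape)
    return OCTVolume(intensity=intensity, voxel_size=voxel_size, truth_mask=truth)


# ---------------------------------------------------------------------------
# RNA-seq counts
# ---------------------------------------------------------------------------

@dataclass
class GroupDesign:
    """Sample-to-(arm, timepoint, replicate) assignment for the 5-arm design."""

    table: pd.DataFrame  # columns: sample, arm, timepoint, replicate

    def __post_init__(self) -> None:
        required = {"sample", "arm", "timepoint", "replicate"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"design table must have columns {sorted(required)}")
        if self.table["sample"].duplicated().any():
            raise ValueError("duplicate sample IDs in design")
        bad = set(self.table["arm"]) - set(ARMS)
        if bad:
            raise ValueError(f"unknown arms in design: {sorted(bad)}")
        bad_tp = set(self.table["timepoint"]) - set(TIMEPOINTS)
        if bad_tp:
            raise ValueError(f"unknown timepoints in design: {sorted(bad_tp)}")

    @property
    def samples(self) -> list[str]:
        return list(self.table["sample"])

    def samples_in(self, arm: str, timepoint: str | None = None) -> list[str]:
        sel = self.table["arm"] == arm
        if timepoint is not None:
            sel &= self.table["timepoint"] == timepoint
        return list(self.table.loc[sel, "sample"])


def default_design(n_replicates: int = 3) -> GroupDesign:
    """Five arms x two timepoints x ``n_replicates`` pooled-organoid samples."""
    rows = [
        {
            "sample": f"{arm}_{tp}_r{r + 1}",
            "arm": arm,
            "timepoint": tp,
            "replicate": r + 1,
        }
        for arm in ARMS
        for tp in TIMEPOINTS
        for r in range(n_replicates)
    ]
    return GroupDesign(table=pd.DataFrame(rows))


def default_effects(folr1_log2fc: float = 8.0) -> pd.DataFrame:
    """Planted log2 fold changes (genes x exposure arms) vs control.

    FOLR1 receives a large positive induction in every exposure arm (the
    default 2^8 = 256-fold realises an induction spanning several orders of
    magnitude).  The neurodevelopment set receives mixed moderate effects,
    alternating in sign, slightly attenuated in the folate-rescue arms.
    """
    exposure_arms = [a for a in ARMS if a != "control"]
    eff = pd.DataFrame(0.0, index=["FOLR1", *NEURO_GENES], columns=exposure_arms)
    eff.loc["FOLR1"] = folr1_log2fc
    for i, g in enumerate(NEURO_GENES):
        base = 1.5 if i % 2 == 0 else -1.5
        eff.loc[g, "DTG10"] = base
        eff.loc[g, "DTG20"] = base * 1.3
        eff.loc[g, "DTG10_FA10"] = base * 0.6
        eff.loc[g, "DTG20_FA20"] = base * 0.8
    return eff


def simulate_counts(
    design: GroupDesign,
    n_genes: int = 2000,
    baseline_mu: pd.Series | None = None,
    dispersion: float | pd.Series = 0.1,
    effects: pd.DataFrame | None = None,
    seed: int = 0,
    library_size_range: float = 2.0,
) -> pd.DataFrame:
    """Negative-binomial gene x sample count matrix for the exposure design.

    Counts are NB with mean ``baseline_mu[g] * sizefactor[s] * 2**effect[g, arm(s)]``
    and variance ``mu + dispersion * mu**2``.  Per-sample library-size factors
    are drawn log-uniformly over a ``library_size_range``-fold range.  FOLR1
    and the neurodevelopment gene set are always present; ``effects`` rows
    must reference existing genes.  A fixed ``seed`` reproduces the matrix
    exactly.
    """
    rng = np.random.default_rng(seed)
    if baseline_mu is None:
        n_filler = n_genes - 1 - len(NEURO_GENES)
        if n_filler < 0:
            raise ValueError("n_genes too small for the named gene set")
        genes = ["FOLR1", *NEURO_GENES] + [f"GENE{i:05d}" for i in range(n_filler)]
        mu = np.exp(rng.normal(math.log(30.0), 1.5, len(genes)))
        baseline_mu = pd.Series(mu, index=genes)
        baseline_mu.loc["FOLR1"] = 20.0  # moderate control-level expression
        baseline_mu.loc[list(NEURO_GENES)] = np.exp(
            rng.normal(math.log(100.0), 0.5, len(NEURO_GENES))
        )
    genes = list(baseline_mu.index)
    if effects is None:
        effects = default_effects()
    missing = set(effects.index) - set(genes)
    if missing:
        raise ValueError(f"effect table references absent genes: {sorted(missing)}")
    if {"FOLR1", *NEURO_GENES} - set(genes):
        raise ValueError("FOLR1 and the neurodevelopment gene set must be present")

    samples = design.samples
    arms = design.table.set_index("sample")["arm"]
    half = math.log2(library_size_range) / 2.0
    size_factors = pd.Series(
        2.0 ** rng.uniform(-half, half, len(samples)), index=samples
    )
    log2fc = pd.DataFrame(0.0, index=genes, columns=list(design.table["arm"].unique()))
    for g in effects.index:
        for a in effects.columns:
            if a in log2fc.columns:
                log2fc.loc[g, a] = effects.loc[g, a]

    disp = (
        dispersion.reindex(genes).to_numpy()
        if isinstance(dispersion, pd.Series)
        else np.full(len(genes), float(dispersion))
    )
    mu0 = baseline_mu.to_numpy()
    counts = np.empty((len(genes), len(samples)), dtype=np.int64)
    for j, s in enumerate(samples):
        mu = mu0 * size_factors[s] * 2.0 ** log2fc[arms[s]].to_numpy()
        pois = disp <= 0
        col = np.empty(len(genes), dtype=np.int64)
        if pois.any():
            col[pois] = rng.poisson(mu[pois])
        if (~pois).any():
            r = 1.0 / disp[~pois]
            p = r / (r + mu[~pois])
            col[~pois] = rng.negative_binomial(r, p)
        counts[:, j] = col
    return pd.DataFrame(counts, index=genes, columns=samples)
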