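"""Reverberant optical coherence elastography (Rev-OCE) estimation pipeline.

Phase differences from sequential A-lines are scaled to axial particle
velocity, the excitation harmonic is extracted per pixel, an annular spatial
bandpass suppresses out-of-band noise, and local wavenumbers are estimated by
fitting the isotropic reverberant autocorrelation kernel to windowed 2D
autocorrelation profiles.  Shear-wave speed follows from vs = 2*pi*F / k.

The kernel
----------
For an ideal isotropic reverberant shear field (plane shear waves from all
directions, random transverse polarization), the normalised spatial
autocorrelation of the *axial* velocity component over a transverse lag
``Δr`` depends only on ``a = k Δr``:

    B(a) = (3/2) * [ j0(a) - j1(a)/a ],   B(0) = 1,

with spherical Bessel functions j0, j1.  Equivalently
B(a) = j0(a) - j2(a)/2.  This is obtained by averaging
(p̂·ẑ)² · exp(i k n̂·Δr) over uniformly distributed propagation directions n̂
and transverse polarizations p̂; the sin²θ polarization weight is what
distinguishes it from the scalar-field sinc kernel.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.optimize import minimize_scalar
from scipy.special import spherical_jn

from .config import AcquisitionConfig

__all__ = [
    "PhaseVolume",
    "VelocityField",
    "HarmonicField",
    "WavenumberMap",
    "SpeedMap",
    "Morphometry",
    "RegionSummary",
    "reverberant_kernel",
    "phase_to_velocity",
    "velocity_to_phase_increment",
    "extract_harmonic",
    "spatial_bandpass",
    "default_band",
    "estimate_wavenumber_map",
    "wavenumber_to_speed",
    "regionwise_speed_summary",
    "organoid_volume",
    "radial_autocorrelation",
]


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------

@dataclass
class PhaseVolume:
    """Sequential-A-line phase differences Δφ(t, x, y) in radians, wrapped to (-π, π]."""

    dphi: np.ndarray
    acq: AcquisitionConfig

    def __post_init__(self) -> None:
        self.dphi = np.asarray(self.dphi, dtype=float)
        if self.dphi.ndim != 3:
            raise ValueError("dphi must be a (t, x, y) array")
        if self.dphi.shape[0] != self.acq.n_timepoints:
            raise ValueError(
                f"time axis {self.dphi.shape[0]} != acq.n_timepoints {self.acq.n_timepoints}"
            )


@dataclass
class VelocityField:
    """Axial particle velocity vz(t, x, y) in m/s on the scan grid."""

    vz: np.ndarray
    acq: AcquisitionConfig

    def __post_init__(self) -> None:
        self.vz = np.asarray(self.vz, dtype=float)
        if self.vz.ndim != 3:
            raise ValueError("vz must be a (t, x, y) array")


@dataclass
class HarmonicField:
    """Complex amplitude of vz at the excitation frequency, per pixel."""

    amplitude: np.ndarray  # complex, (x, y)
    freq: float
    acq: AcquisitionConfig


@dataclass
class WavenumberMap:
    """Local wavenumber estimates on the window-centre grid.

    ``k`` is in rad/m; ``fit_quality`` is the R² of the kernel fit; windows
    with ``valid == False`` failed the quality threshold or hit the search
    bounds and must not be interpreted.
    """

    k: np.ndarray
    fit_quality: np.ndarray
    valid: np.ndarray
    x_centers: np.ndarray  # m
    y_centers: np.ndarray  # m
    window_size: float  # m
    diagnostics: list[str] = field(default_factory=list)


@dataclass
class SpeedMap:
    """Shear-wave speed vs = 2*pi*F/k on the window-centre grid (m/s)."""

    vs: np.ndarray
    valid: np.ndarray
    x_centers: np.ndarray
    y_centers: np.ndarray
    freq: float


@dataclass
class RegionSummary:
    """Surface- and core-region speed statistics for one organoid."""

    surface_mean: float
    surface_median: float
    surface_sd: float
    surface_n: int
    core_mean: float
    core_median: float
    core_sd: float
    core_n: int
    errors: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class Morphometry:
    """Sphericity-based organoid volumetry from two orthogonal diameters (mm).

    V = (4/3) π r³ with r = d_mean / 2 and d_mean the average of the
    horizontal and vertical diameters.
    """

    d_horizontal: float
    d_vertical: float

    def __post_init__(self) -> None:
        if self.d_horizontal <= 0 or self.d_vertical <= 0:
            raise ValueError("diameters must be positive")

    @property
    def d_mean(self) -> float:
        return (self.d_horizontal + self.d_vertical) / 2.0

    @property
    def r(self) -> float:
        return self.d_mean / 2.0

    @property
    def volume(self) -> float:
        """Volume in mm³ assuming sphericity."""
        return (4.0 / 3.0) * math.pi * self.r**3


# ---------------------------------------------------------------------------
# Kernel
# ---------------------------------------------------------------------------

def reverberant_kernel(a: np.ndarray | float) -> np.ndarray:
    """Normalised transverse-lag autocorrelation kernel B(a), a = k*Δr.

    B(a) = (3/2) [ j0(a) - j1(a)/a ], continuous at a=0 with B(0)=1.
    """
    a = np.asarray(a, dtype=float)
    out = np.empty_like(a)
    small = np.abs(a) < 1e-6
    # series: B(a) = 1 - a²/5 + O(a⁴)
    out[small] = 1.0 - a[small] ** 2 / 5.0
    ab = a[~small]
    out[~small] = 1.5 * (spherical_jn(0, ab) - spherical_jn(1, ab) / ab)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Phase <-> velocity
# ---------------------------------------------------------------------------

def phase_to_velocity(p: PhaseVolume, unwrap: bool = False) -> VelocityField:
    """Scale phase differences to axial particle velocity.

    vz = λ0 Δφ / (4 π n Δt).  With ``unwrap=True`` the phase record is first
    unwrapped along the time axis per pixel (needed only when velocities
    exceed the wrap amplitude λ0/(4 n Δt)).
    """
    if not np.all(np.isfinite(p.dphi)):
        raise ValueError("phase volume contains non-finite values")
    acq = p.acq
    dphi = np.unwrap(p.dphi, axis=0) if unwrap else p.dphi
    scale = acq.lambda0 / (4.0 * math.pi * acq.n_refractive * acq.delta_t)
    return VelocityField(vz=dphi * scale, acq=acq)


def velocity_to_phase_increment(v: VelocityField) -> np.ndarray:
    """Unwrapped phase increments 4 π n Δt vz / λ0 (inverse of the scaling)."""
    acq = v.acq
    return 4.0 * math.pi * acq.n_refractive * acq.delta_t * v.vz / acq.lambda0


# ---------------------------------------------------------------------------
# Temporal demodulation
# ---------------------------------------------------------------------------

def extract_harmonic(
    v: VelocityField, freq: float | None = None, window: str = "flattop"
) -> HarmonicField:
    """Complex amplitude of the excitation harmonic at each pixel.

    A windowed temporal DFT is evaluated and the bin nearest ``freq`` taken;
    the amplitude is normalised by the window's coherent gain so a pure
    bin-centred sinusoid of amplitude A returns |amplitude| = A exactly.  The
    flat-top default keeps the scalloping loss below 1% for off-bin tones.
    """
    acq = v.acq
    if freq is None:
        freq = acq.excitation_freq
    if not (0 < freq < acq.aline_rate / 2):
        raise ValueError(f"frequency {freq} Hz beyond Nyquist ({acq.aline_rate / 2} Hz)")
    nt = v.vz.shape[0]
    w = signal.get_window(window, nt, fftbins=True)
    spec = np.fft.rfft(v.vz * w[:, None, None], axis=0)
    freqs = np.fft.rfftfreq(nt, d=acq.delta_t)
    b = int(np.argmin(np.abs(freqs - freq)))
    amp = 2.0 * spec[b] / w.sum()
    return HarmonicField(amplitude=amp, freq=freq, acq=acq)


# ---------------------------------------------------------------------------
# Spatial bandpass
# ---------------------------------------------------------------------------

def spatial_bandpass(
    h: HarmonicField, k_lo: float, k_hi: float, taper: float = 0.15
) -> HarmonicField:
    """Annular 2D-FFT bandpass retaining spatial frequencies |k| in [k_lo, k_hi].

    The mask is 1 on the band, falls to 0 with raised-cosine ramps of relative
    width ``taper`` outside it, and is 0 beyond the ramps, so out-of-band
    plane waves are suppressed essentially completely while in-band content
    passes unchanged.  A low cutoff below ~2 k-space bins of the aperture is
    below the spectral resolution and is skipped: at long wavelengths the
    DC bin carries genuine leaked signal power, and removing it biases the
    downstream wavenumber fit.
    """
    dx, dy = h.acq.grid_spacing
    nx, ny = h.amplitude.shape
    k_nyq = math.pi / max(dx, dy)
    if not (0 < k_lo < k_hi):
        raise ValueError("need 0 < k_lo < k_hi")
    if k_hi >= k_nyq:
        raise ValueError(f"k_hi {k_hi:.1f} rad/m exceeds spatial Nyquist {k_nyq:.1f} rad/m")
    kx = 2.0 * math.pi * np.fft.fftfreq(nx, d=dx)
    ky = 2.0 * math.pi * np.fft.fftfreq(ny, d=dy)
    kr = np.hypot(kx[:, None], ky[None, :])
    dk = 2.0 * math.pi / min(nx * dx, ny * dy)

    w_lo = taper * k_lo
    w_hi = taper * k_hi
    mask = np.zeros_like(kr)
    low_cut = k_lo >= 2.0 * dk
    if not low_cut:
        k_lo, w_lo = 0.0, 0.0
    mask[(kr >= k_lo) & (kr <= k_hi)] = 1.0
    if low_cut:
        lo_ramp = (kr >= k_lo - w_lo) & (kr < k_lo)
        mask[lo_ramp] = 0.5 * (1 + np.cos(math.pi * (k_lo - kr[lo_ramp]) / w_lo))
    hi_ramp = (kr > k_hi) & (kr <= k_hi + w_hi)
    mask[hi_ramp] = 0.5 * (1 + np.cos(math.pi * (kr[hi_ramp] - k_hi) / w_hi))

    out = np.fft.ifft2(np.fft.fft2(h.amplitude) * mask)
    return HarmonicField(amplitude=out, freq=h.freq, acq=h.acq)


def default_band(k_nominal: float) -> tuple[float, float]:
    """Default bandpass cutoffs [0.25, 4] x the nominal wavenumber."""
    return 0.25 * k_nominal, 4.0 * k_nominal


# ---------------------------------------------------------------------------
# Windowed autocorrelation wavenumber estimation
# ---------------------------------------------------------------------------

def _autocorr2d_unbiased(a: np.ndarray) -> np.ndarray:
    """Unbiased 2D autocorrelation of a complex field, zero lag at centre.

    FFT-based with zero padding; each lag is divided by its overlap count so
    the taper of the biased estimator does not distort the kernel shape.
    """
    n0, n1 = a.shape
    f = np.fft.fft2(a, s=(2 * n0, 2 * n1))
    c = np.fft.fftshift(np.fft.ifft2(f * np.conj(f)))[1:, 1:]  # lags ±(n-1), centred
    lag0 = np.arange(-(n0 - 1), n0)
    lag1 = np.arange(-(n1 - 1), n1)
    ov = np.outer(n0 - np.abs(lag0), n1 - np.abs(lag1)).astype(float)
    return c / ov


def _raw_radial_profile(
    field2d: np.ndarray, dx: float, max_lag: float
) -> tuple[np.ndarray, np.ndarray]:
    """Radially binned real autocorrelation of a complex 2D patch, unnormalised.

    Returns (mean_radius_per_bin, profile).  Bin coordinates are the exact
    mean lag radius of the pixels in each annular bin, not the nominal bin
    centre — the difference is a systematic wavenumber bias at small windows.
    Unnormalised profiles from neighbouring patches can be averaged before
    normalisation; averaging *normalised* profiles weights low-power patches
    equally and biases the pooled estimate.
    """
    c = _autocorr2d_unbiased(np.asarray(field2d, dtype=complex))
    n0, n1 = field2d.shape
    lag0 = (np.arange(-(n0 - 1), n0) * dx)[:, None]
    lag1 = (np.arange(-(n1 - 1), n1) * dx)[None, :]
    r = np.hypot(lag0, lag1)
    nbins = int(max_lag / dx) + 1
    idx = np.round(r / dx).astype(int)
    sel = idx < nbins
    counts = np.maximum(np.bincount(idx[sel], minlength=nbins), 1)
    sums = np.bincount(idx[sel], weights=c.real[sel], minlength=nbins)
    rbar = np.bincount(idx[sel], weights=r[sel], minlength=nbins) / counts
    return rbar, sums / counts


def radial_autocorrelation(
    field2d: np.ndarray, dx: float, max_lag: float
) -> tuple[np.ndarray, np.ndarray]:
    """Radially averaged real autocorrelation profile of a complex 2D field.

    Returns (lag_r, profile) with the profile normalised to 1 at zero lag;
    lag bins are one grid spacing wide out to ``max_lag`` (metres), with the
    exact mean radius of each bin as its coordinate.  Assumes isotropic
    sampling (dx == dy).
    """
    lags, profile = _raw_radial_profile(field2d, dx, max_lag)
    if profile[0] <= 0:
        raise ValueError("degenerate field: zero power")
    return lags, profile / profile[0]


def _fit_kernel(
    lags: np.ndarray,
    data: np.ndarray,
    k_lo: float,
    k_hi: float,
    n_candidates: int = 80,
    fit_amplitude: bool = True,
) -> tuple[float, float, float]:
    """Least-squares fit of c*B(k*lag) to an autocorrelation profile.

    Returns (k, r_squared, c).  With ``fit_amplitude=True`` (default) the
    zero-lag point is included and the amplitude c is solved in closed form
    per candidate k — fitting the *unnormalised* profile this way avoids the
    ratio bias of normalise-then-fit on noisy profiles.  With
    ``fit_amplitude=False`` the profile is assumed normalised, c is pinned at
    1 and the zero-lag point is excluded.  Ties break toward smaller k
    (ascending candidate grid, strict improvement required).
    """
    if fit_amplitude:
        r_ = lags
        d = data
    else:
        pos = lags > 0
        r_ = lags[pos]
        d = data[pos]

    def sse(k: float) -> float:
        m = reverberant_kernel(k * r_)
        if fit_amplitude:
            denom = float(m @ m)
            if denom <= 0:
                return float(d @ d)
            c = float(m @ d) / denom
            resid = d - c * m
        else:
            resid = d - m
        return float(resid @ resid)

    ks = np.geomspace(k_lo, k_hi, n_candidates)
    errs = np.array([sse(k) for k in ks])
    i = int(np.argmin(errs))
    lo = ks[max(i - 1, 0)]
    hi = ks[min(i + 1, n_candidates - 1)]
    if hi > lo:
        res = minimize_scalar(sse, bounds=(lo, hi), method="bounded")
        k_best = float(res.x) if res.fun <= errs[i] else float(ks[i])
    else:
        k_best = float(ks[i])
    m = reverberant_kernel(k_best * r_)
    c = float(m @ d) / float(m @ m) if fit_amplitude else 1.0
    # fit quality over positive lags only: the zero-lag point is the patch
    # power and fits trivially, which would let structureless (white-noise)
    # profiles score high
    pos = r_ > 0
    resid = d[pos] - c * m[pos]
    sstot = float(np.sum((d[pos] - d[pos].mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / sstot if sstot > 0 else 0.0
    return k_best, r2, c


def estimate_wavenumber_map(
    h: HarmonicField,
    acq: AcquisitionConfig | None = None,
    stride: int | None = None,
    quality_threshold: float = 0.6,
    k_bounds: tuple[float, float] | None = None,
    neighborhood: int | str = "auto",
    fit_amplitude: bool = True,
) -> WavenumberMap:
    """Local wavenumber map from windowed 2D autocorrelation kernel fits.

    For each sliding square window (side ``acq.window_size``, default stride
    half a window) the complex harmonic field is autocorrelated and the real
    part radially binned over lags up to the window size.  Raw correlation
    profiles are averaged over a ``(2*neighborhood+1)²`` block of adjacent
    windows before normalisation — each window is a single coherent speckle
    patch, and pooling raw correlations from neighbours removes the
    normalisation bias and most of the realization noise while keeping the
    estimate local.  The reverberant kernel ``B(k Δr)`` is then fitted by
    least squares over k.  Windows whose fit R² falls below
    ``quality_threshold`` — or whose k lands on a search bound — are marked
    invalid.

    With ``neighborhood="auto"`` (default) a first pass at a 3x3 block sets
    the pooling scale: when the estimated median wavelength exceeds the
    window — the regime where each window sees a quasi-plane wave and the
    median local estimate converges to ~1.05 k rather than k — the block is
    widened until the pooled correlation support spans about one wavelength
    (at most 7x7), and the fits are repeated.
    """
    if acq is None:
        acq = h.acq
    dx, dy = acq.grid_spacing
    if abs(dx - dy) > 1e-12:
        raise ValueError("anisotropic grids are not supported")
    nx, ny = h.amplitude.shape
    w = int(round(acq.window_size / dx)) + 1
    if w < 3:
        raise ValueError(
            f"window of {w} samples is below the 3-sample minimum; "
            "increase window_size or grid density"
        )
    w = min(w, nx, ny)
    if stride is None:
        stride = max(1, w // 2)
    if k_bounds is None:
        k_lo = 2.0 * math.pi / (20.0 * acq.window_size)
        k_hi = math.pi / dx
    else:
        k_lo, k_hi = k_bounds
    max_lag = acq.window_size

    xs = list(range(0, nx - w + 1, stride))
    ys = list(range(0, ny - w + 1, stride))
    nbins = int(max_lag / dx) + 1
    raw = np.zeros((len(xs), len(ys), nbins))
    power = np.zeros((len(xs), len(ys)))
    lags = np.arange(nbins) * dx  # overwritten with exact bin radii below
    for i, x0 in enumerate(xs):
        for j, y0 in enumerate(ys):
            patch = h.amplitude[x0 : x0 + w, y0 : y0 + w]
            if not np.any(np.abs(patch) > 0):
                continue
            lags, prof = _raw_radial_profile(patch, dx, max_lag)
            raw[i, j] = prof
            power[i, j] = prof[0]

    def fit_all(nbh: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        K = np.full((len(xs), len(ys)), np.nan)
        Q = np.zeros((len(xs), len(ys)))
        V = np.zeros((len(xs), len(ys)), dtype=bool)
        for i in range(len(xs)):
            for j in range(len(ys)):
                if power[i, j] <= 0:
                    continue
                block = raw[
                    max(0, i - nbh) : i + nbh + 1, max(0, j - nbh) : j + nbh + 1
                ]
                prof = block.reshape(-1, nbins).mean(axis=0)
                if prof[0] <= 0:
                    continue
                if not fit_amplitude:
                    prof = prof / prof[0]
                k, r2, _ = _fit_kernel(
                    lags, prof, k_lo, k_hi, fit_amplitude=fit_amplitude
                )
                K[i, j] = k
                Q[i, j] = r2
                on_bound = k <= k_lo * 1.01 or k >= k_hi * 0.99
                V[i, j] = (r2 >= quality_threshold) and not on_bound
        return K, Q, V

    diags: list[str] = []
    if neighborhood == "auto":
        K, Q, V = fit_all(1)
        if V.any():
            lam_est = 2.0 * math.pi / float(np.median(K[V]))
            # pooled support is ~(1 + nbh) windows at the default stride
            nbh = int(np.ceil(lam_est / acq.window_size)) - 1
            nbh = int(np.clip(nbh, 1, 3))
            if nbh > 1:
                diags.append(
                    f"wavelength ~{lam_est * 1e3:.2f} mm exceeds the window; "
                    f"pooling widened to {2 * nbh + 1}x{2 * nbh + 1}"
                )
                K, Q, V = fit_all(nbh)
    else:
        K, Q, V = fit_all(int(neighborhood))
    if not V.any():
        diags.append("no window passed the fit-quality threshold")
        warnings.warn("wavenumber map contains no valid windows", stacklevel=2)
    x_centers = (np.array(xs) + (w - 1) / 2.0) * dx
    y_centers = (np.array(ys) + (w - 1) / 2.0) * dy
    return WavenumberMap(
        k=K,
        fit_quality=Q,
        valid=V,
        x_centers=x_centers,
        y_centers=y_centers,
        window_size=acq.window_size,
        diagnostics=diags,
    )


def wavenumber_to_speed(km: WavenumberMap, freq: float) -> SpeedMap:
    """vs = 2*pi*F / k pointwise; invalid windows propagate as invalid."""
    with np.errstate(divide="ignore", invalid="ignore"):
        vs = 2.0 * math.pi * freq / km.k
    return SpeedMap(
        vs=vs,
        valid=km.valid.copy(),
        x_centers=km.x_centers,
        y_centers=km.y_centers,
        freq=freq,
    )


# ---------------------------------------------------------------------------
# Region summaries and volumetry
# ---------------------------------------------------------------------------

def regionwise_speed_summary(
    sm: SpeedMap, mask: np.ndarray, shell_fraction: float = 0.2
) -> RegionSummary:
    """Mean/median/SD of vs over the surface and core regions of one organoid.

    ``mask`` is a boolean array on the window-centre grid marking the
    organoid.  The surface region is the outer ``shell_fraction`` of the
    radial extent measured from the mask centroid; everything inside is core.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != sm.vs.shape:
        raise ValueError("mask must align with the speed-map grid")
    errors: list[str] = []
    if not mask.any():
        return RegionSummary(
            *(float("nan"),) * 3, 0, *(float("nan"),) * 3, 0,
            errors=["surface region empty", "core region empty"],
        )
    xi, yi = np.nonzero(mask)
    x = sm.x_centers[xi]
    y = sm.y_centers[yi]
    cx, cy = x.mean(), y.mean()
    r = np.hypot(x - cx, y - cy)
    r_max = r.max()
    surface_sel = r >= (1.0 - shell_fraction) * r_max if r_max > 0 else np.zeros_like(r, bool)
    core_sel = ~surface_sel

    def stats(sel: np.ndarray, name: str) -> tuple[float, float, float, int]:
        vals = sm.vs[xi[sel], yi[sel]]
        ok = sm.valid[xi[sel], yi[sel]] & np.isfinite(vals)
        vals = vals[ok]
        if vals.size == 0:
            errors.append(f"{name} region empty")
            return float("nan"), float("nan"), float("nan"), 0
        return (
            float(vals.mean()),
            float(np.median(vals)),
            float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
            int(vals.size),
        )

    s = stats(surface_sel, "surface")
    c = stats(core_sel, "core")
    return RegionSummary(*s, *c, errors=errors)


def organoid_volume(
    d_horizontal: float | None = None,
    d_vertical: float | None = None,
    mask: np.ndarray | None = None,
    spacing_mm: float | None = None,
) -> Morphometry:
    """Organoid morphometry from two diameters or a 2D segmentation mask.

    With a mask, the horizontal and vertical diameters are the mask extents
    along the row and column passing through the centroid, in mm given
    ``spacing_mm`` per pixel.  Volume assumes sphericity:
    V = (4/3) π (d_mean/2)³.
    """
    if mask is not None:
        if spacing_mm is None:
            raise ValueError("spacing_mm required when measuring from a mask")
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError("empty mask: no organoid to measure")
        xi, yi = np.nonzero(mask)
        ci, cj = int(round(xi.mean())), int(round(yi.mean()))
        d_horizontal = float(mask[ci, :].sum()) * spacing_mm
        d_vertical = float(mask[:, cj].sum()) * spacing_mm
    if d_horizontal is None or d_vertical is None:
        raise ValueError("provide either both diameters or a mask")
    return Morphometry(d_horizontal=d_horizontal, d_vertical=d_vertical)
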