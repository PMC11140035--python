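"""Brillouin spectrometer calibration, shift fitting and OCT-guided surfaces.

The spectrometer disperses light onto camera pixels; an affine pixel-to-GHz
map is established before every session by fitting the Stokes/anti-Stokes
peak positions of reference liquids (ultrapure water, acetone, methanol) with
known shifts.  Sample spectra are then fitted with a symmetric Lorentzian
pair to read out the Brillouin frequency shift ν_B — the stiffness proxy —
and shifts are summarised over the organoid surface defined by OCT
segmentation.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import curve_fit
from skimage.filters import threshold_otsu

from .phantom import AffinePixelMap, BrillouinSpectrum, OCTVolume

#: Documented default reference shifts at 660 nm incident wavelength,
#: computed as ν = 2 n V / λ from standard acoustic-velocity and
#: refractive-index tables.  These are configuration inputs, not constants of
#: the method — any >= 2 liquids with distinct shifts calibrate the map.
DEFAULT_REFERENCE_SHIFTS = {"water": 6.00, "acetone": 4.83, "methanol": 4.42}

__all__ = [
    "DEFAULT_REFERENCE_SHIFTS",
    "CalibrationModel",
    "ShiftFit",
    "ShiftMap",
    "SegmentationMask",
    "calibrate_spectrometer",
    "fit_shift",
    "segment_organoid",
    "surfacewise_mean_shift",
    "SurfaceShiftSummary",
]


@dataclass(frozen=True)
class CalibrationModel:
    """Fitted affine pixel-to-GHz dispersion with its calibration residual."""

    pixel_map: AffinePixelMap
    residual_rms: float  # GHz
    references: dict[str, float] = field(default_factory=dict)

    @property
    def slope(self) -> float:
        return self.pixel_map.slope

    @property
    def intercept(self) -> float:
        return self.pixel_map.intercept


@dataclass(frozen=True)
class ShiftFit:
    """Result of a Stokes/anti-Stokes pair fit on one spectrum."""

    nu_B: float  # GHz
    linewidth: float  # GHz (FWHM)
    r_squared: float
    valid: bool
    diagnostic: str = ""


@dataclass
class ShiftMap:
    """Brillouin shifts (GHz) sampled on a grid registered to the OCT volume.

    ``values`` may contain NaN where no sample was measured; ``valid`` marks
    points whose fit passed quality control.
    """

    values: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != self.valid.shape:
            raise ValueError("values and valid must share a shape")


@dataclass
class SegmentationMask:
    """OCT segmentation: organoid mask plus its boundary shell."""

    mask: np.ndarray
    boundary: np.ndarray
    found: bool
    voxel_size: float

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class SurfaceShiftSummary:
    mean: float
    sd: float
    n: int
    errors: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# Peak fitting helpers
# ---------------------------------------------------------------------------

def _pair_model_pixels(px, p1, p2, hwhm, amp, base):
    return base + amp * (
        hwhm**2 / ((px - p1) ** 2 + hwhm**2) + hwhm**2 / ((px - p2) ** 2 + hwhm**2)
    )


def _noise_floor(trace: np.ndarray) -> tuple[float, float]:
    """(median, robust SD) of a trace via the MAD."""
    med = float(np.median(trace))
    mad = float(np.median(np.abs(trace - med)))
    return med, 1.4826 * mad


def _find_pair_pixels(trace: np.ndarray) -> tuple[float, float] | None:
    """Initial Stokes/anti-Stokes pixel positions, or None if no clear pair."""
    med, sd = _noise_floor(trace)
    if trace.max() - med < 5.0 * max(sd, 1e-12):
        return None
    n = trace.size
    half = n // 2
    p1 = int(np.argmax(trace[:half]))
    p2 = half + int(np.argmax(trace[half:]))
    if p2 - p1 < 2:
        return None
    return float(p1), float(p2)


def _fit_pair_pixels(trace: np.ndarray) -> tuple[float, float, float] | None:
    """Least-squares symmetric-pair fit in pixel space -> (p1, p2, hwhm_px)."""
    init = _find_pair_pixels(trace)
    if init is None:
        return None
    p1, p2 = init
    med, _ = _noise_floor(trace)
    px = np.arange(trace.size, dtype=float)
    amp0 = trace.max() - med
    try:
        popt, _ = curve_fit(
            _pair_model_pixels,
            px,
            trace,
            p0=[p1, p2, 3.0, amp0, med],
            maxfev=20_000,
        )
    except RuntimeError:
        return None
    p1f, p2f, hwhm, _, _ = popt
    if p1f > p2f:
        p1f, p2f = p2f, p1f
    return float(p1f), float(p2f), abs(float(hwhm))


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def calibrate_spectrometer(
    ref_spectra: dict[str, BrillouinSpectrum],
    ref_shifts: dict[str, float] | None = None,
) -> CalibrationModel:
    """Affine pixel-to-GHz calibration from reference-liquid spectra.

    For each liquid the Stokes (−ν) and anti-Stokes (+ν) peak pixels are
    fitted, giving two (pixel, frequency) points per reference; the affine
    map is the least-squares line through all points, with its residual RMS
    reported.  At least two liquids with distinct shifts are required.
    """
    if ref_shifts is None:
        ref_shifts = {k: DEFAULT_REFERENCE_SHIFTS[k] for k in ref_spectra}
    missing = set(ref_spectra) - set(ref_shifts)
    if missing:
        raise ValueError(f"no reference shift given for {sorted(missing)}")
    if len(ref_spectra) < 2:
        raise ValueError("need >= 2 reference liquids")
    if len({round(ref_shifts[k], 9) for k in ref_spectra}) < 2:
        raise ValueError("degenerate calibration: reference shifts are not distinct")

    pixels, ghz = [], []
    for liquid, spec in ref_spectra.items():
        fit = _fit_pair_pixels(spec.intensity)
        if fit is None:
            raise ValueError(f"no resolvable peak pair in reference spectrum {liquid!r}")
        p_minus, p_plus, _ = fit
        pixels += [p_minus, p_plus]
        ghz += [-ref_shifts[liquid], ref_shifts[liquid]]
    A = np.vstack([pixels, np.ones(len(pixels))]).T
    coef, *_ = np.linalg.lstsq(A, np.asarray(ghz), rcond=None)
    slope, intercept = float(coef[0]), float(coef[1])
    if abs(slope) < 1e-12:
        raise ValueError("degenerate calibration: zero dispersion slope")
    resid = np.asarray(ghz) - (A @ coef)
    return CalibrationModel(
        pixel_map=AffinePixelMap(slope=slope, intercept=intercept),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        references={k: ref_shifts[k] for k in ref_spectra},
    )


# ---------------------------------------------------------------------------
# Shift fitting
# ---------------------------------------------------------------------------

def fit_shift(s: BrillouinSpectrum, calib: CalibrationModel) -> ShiftFit:
    """Brillouin shift from a symmetric Lorentzian-pair fit in frequency space.

    The pixel axis is converted to GHz through the calibration; the model is
    a pair of Lorentzians of shared linewidth constrained to ±ν_B about the
    elastic line.  Spectra without a peak pair above the noise floor return
    an invalid result rather than a number.
    """
    trace = s.intensity
    init = _fit_pair_pixels(trace)
    if init is None:
        return ShiftFit(
            nu_B=float("nan"), linewidth=float("nan"), r_squared=0.0,
            valid=False, diagnostic="no peak pair above the noise floor",
        )
    p_minus, p_plus, hwhm_px = init
    nu = np.asarray(calib.pixel_map.pixel_to_ghz(np.arange(trace.size)))
    med, _ = _noise_floor(trace)
    nu0 = abs(calib.pixel_map.pixel_to_ghz(p_plus))
    gamma0 = max(hwhm_px * abs(calib.slope), 1e-3)

    def model(x, nu_b, hwhm, amp, base):
        return base + amp * (
            hwhm**2 / ((x - nu_b) ** 2 + hwhm**2)
            + hwhm**2 / ((x + nu_b) ** 2 + hwhm**2)
        )

    try:
        popt, _ = curve_fit(
            model, nu, trace, p0=[nu0, gamma0, trace.max() - med, med], maxfev=20_000
        )
    except RuntimeError:
        return ShiftFit(
            nu_B=float("nan"), linewidth=float("nan"), r_squared=0.0,
            valid=False, diagnostic="pair fit did not converge",
        )
    nu_b, hwhm, _, _ = popt
    pred = model(nu, *popt)
    sstot = float(np.sum((trace - trace.mean()) ** 2))
    r2 = 1.0 - float(np.sum((trace - pred) ** 2)) / sstot if sstot > 0 else 0.0
    return ShiftFit(
        nu_B=abs(float(nu_b)),
        linewidth=2.0 * abs(float(hwhm)),
        r_squared=r2,
        valid=r2 > 0.5,
        diagnostic="" if r2 > 0.5 else "poor fit quality",
    )


# ---------------------------------------------------------------------------
# OCT segmentation
# ---------------------------------------------------------------------------

def segment_organoid(
    oct_vol: OCTVolume,
    boundary_thickness: int = 3,
    min_voxels: int = 27,
    smoothing_sigma: float = 0.0,
) -> SegmentationMask:
    """Otsu threshold + largest connected component + hole filling.

    A bimodality guard (Otsu between-class separability >= 0.8) and a minimum
    component size prevent pure background speckle — which percolates into
    large components when thresholded — from segmenting as an object.  The
    boundary shell is the outer ``boundary_thickness`` voxels of the
    component.  Optional Gaussian pre-smoothing is available for very low
    contrast-to-noise volumes; it trades boundary accuracy for robustness.
    """
    img = oct_vol.intensity.astype(float)
    if smoothing_sigma > 0:
        img = ndimage.gaussian_filter(img, smoothing_sigma)
    empty = SegmentationMask(
        mask=np.zeros(img.shape, bool),
        boundary=np.zeros(img.shape, bool),
        found=False,
        voxel_size=oct_vol.voxel_size,
    )
    lo, hi = float(img.min()), float(img.max())
    if hi - lo < 1e-12:
        return empty
    thr = threshold_otsu(img)
    fg = img > thr
    if not fg.any() or fg.all():
        return empty
    # separability guard: between-class variance fraction of total variance
    mu1, mu0 = img[fg].mean(), img[~fg].mean()
    w1 = fg.mean()
    between = w1 * (1 - w1) * (mu1 - mu0) ** 2
    total = img.var()
    if total <= 0 or between / total < 0.8:
        return empty
    labels, n = ndimage.label(fg)
    if n == 0:
        return empty
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    biggest = int(np.argmax(sizes)) + 1
    if sizes[biggest - 1] < min_voxels:
        return empty
    mask = ndimage.binary_fill_holes(labels == biggest)
    eroded = ndimage.binary_erosion(mask, iterations=boundary_thickness)
    return SegmentationMask(
        mask=mask,
        boundary=mask & ~eroded,
        found=True,
        voxel_size=oct_vol.voxel_size,
    )


# ---------------------------------------------------------------------------
# Surface summaries
# ---------------------------------------------------------------------------

def surfacewise_mean_shift(
    shifts: ShiftMap, seg: SegmentationMask | None
) -> SurfaceShiftSummary:
    """Mean/SD of valid Brillouin shifts over the segmented boundary shell."""
    if seg is None or not seg.found:
        return SurfaceShiftSummary(
            mean=float("nan"), sd=float("nan"), n=0, errors=("no segmentation mask",)
        )
    if shifts.values.shape != seg.boundary.shape:
        raise ValueError("shift map is not registered to the OCT grid")
    sel = seg.boundary & shifts.valid & np.isfinite(shifts.values)
    vals = shifts.values[sel]
    if vals.size == 0:
        return SurfaceShiftSummary(
            mean=float("nan"), sd=float("nan"), n=0, errors=("no valid surface points",)
        )
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return SurfaceShiftSummary(mean=float(vals.mean()), sd=sd, n=int(vals.size))
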