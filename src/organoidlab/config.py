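"""Acquisition, phantom and simulation configuration types.

All geometric quantities are SI (metres, seconds, Hz) internally; morphometry
outputs are reported in mm/mm**3 where the field convention expects them.
"""
from __future__ import annotations

from dataclasses import dataclass, field
import math

#: Exposure arms of the study design: vehicle control, two dolutegravir doses,
#: and the two dolutegravir + folic-acid rescue arms.
ARMS = ("control", "DTG10", "DTG20", "DTG10_FA10", "DTG20_FA20")
#: Organoid maturation timepoints at which samples are collected.
TIMEPOINTS = ("day20", "day24")


@dataclass(frozen=True)
class AcquisitionConfig:
    """Phase-sensitive OCT acquisition geometry for reverberant elastography.

    Defaults follow a typical 840 nm spectral-domain system running M-C mode
    scans: 25 kHz A-line rate, a 3 kHz quasi-harmonic shear excitation, 500
    A-lines per lateral position on a 101 x 101 grid spanning 2 mm per axis,
    and 0.5 mm analysis windows.

    Parameters
    ----------
    lambda0 : float
        Source central wavelength in metres.
    n_refractive : float
        Refractive index of the sample (brain tissue ~ 1.34).
    aline_rate : float
        A-line acquisition rate in Hz; the phase-difference sampling rate.
    excitation_freq : float
        Shear-wave excitation frequency F in Hz.
    n_timepoints : int
        Number of sequential A-lines (time samples) per lateral position.
    grid_points : tuple of int
        Lateral grid size (nx, ny).
    scan_extent : tuple of float
        Physical scan extent per axis in metres.
    window_size : float
        Side length of the square wavenumber-analysis window in metres.
    """

    lambda0: float = 840e-9
    n_refractive: float = 1.34
    aline_rate: float = 25_000.0
    excitation_freq: float = 3_000.0
    n_timepoints: int = 500
    grid_points: tuple[int, int] = (101, 101)
    scan_extent: tuple[float, float] = (2.0e-3, 2.0e-3)
    window_size: float = 0.5e-3

    def __post_init__(self) -> None:
        if self.lambda0 <= 0 or self.n_refractive <= 0 or self.aline_rate <= 0:
            raise ValueError("lambda0, n_refractive and aline_rate must be positive")
        if not (0 < self.excitation_freq < self.aline_rate / 2):
            raise ValueError(
                f"excitation_freq {self.excitation_freq} Hz violates Nyquist for "
                f"A-line rate {self.aline_rate} Hz"
            )
        if self.n_timepoints < 2:
            raise ValueError("n_timepoints must be >= 2")
        if any(n < 3 for n in self.grid_points):
            raise ValueError("grid must be at least 3 x 3 points")
        if any(e <= 0 for e in self.scan_extent):
            raise ValueError("scan_extent must be positive")
        if not (0 < self.window_size <= min(self.scan_extent)):
            raise ValueError("window_size must be positive and <= min(scan_extent)")

    @property
    def delta_t(self) -> float:
        """Temporal resolution between sequential A-lines, 1/aline_rate (s)."""
        return 1.0 / self.aline_rate

    @property
    def grid_spacing(self) -> tuple[float, float]:
        """(dx, dy) in metres; extent / (points - 1)."""
        return (
            self.scan_extent[0] / (self.grid_points[0] - 1),
            self.scan_extent[1] / (self.grid_points[1] - 1),
        )


@dataclass(frozen=True)
class OrganoidPhantom:
    """Two-compartment spherical organoid phantom with known ground truth.

    The phantom is a stiff spherical shell around a softer core, embedded in
    an agarose-like background — the structure the elastography and Brillouin
    estimators are asked to recover.  Shear speeds parameterise the
    elastography contrast; per-compartment Brillouin shifts parameterise the
    stiffness proxy seen by the spectrometer.
    """

    center: tuple[float, float, float] = (1.0e-3, 1.0e-3, 0.0)
    shell_outer_radius: float = 0.8e-3
    core_radius: float = 0.5e-3
    vs_shell: float = 3.0
    vs_core: float = 1.5
    vs_background: float = 2.0
    brillouin_shift_shell: float = 5.2
    brillouin_shift_core: float = 5.0

    def __post_init__(self) -> None:
        if self.shell_outer_radius <= 0 or self.core_radius <= 0:
            raise ValueError("radii must be positive")
        if not self.core_radius < self.shell_outer_radius:
            raise ValueError("core must lie strictly inside the shell")
        if min(self.vs_shell, self.vs_core, self.vs_background) <= 0:
            raise ValueError("shear speeds must be positive")

    @property
    def region_speeds(self) -> dict[str, float]:
        return {
            "core": self.vs_core,
            "shell": self.vs_shell,
            "background": self.vs_background,
        }

    def is_homogeneous(self) -> bool:
        return self.vs_shell == self.vs_core == self.vs_background


def homogeneous_phantom(vs: float, acq: AcquisitionConfig | None = None) -> OrganoidPhantom:
    """Phantom with a single shear speed everywhere — the calibration case."""
    if acq is None:
        acq = AcquisitionConfig()
    cx = acq.scan_extent[0] / 2
    cy = acq.scan_extent[1] / 2
    return OrganoidPhantom(
        center=(cx, cy, 0.0),
        vs_shell=vs,
        vs_core=vs,
        vs_background=vs,
    )


@dataclass(frozen=True)
class SimSpec:
    """Controls for the reverberant plane-wave field synthesiser.

    A reverberant field is approximated by ``n_plane_waves`` shear plane waves
    with propagation directions drawn uniformly on the sphere, each carrying a
    random transverse polarization.  1000 waves is empirically sufficient for
    the field's 2D autocorrelation to be isotropic at the window scale.
    """

    n_plane_waves: int = 1000
    rng_seed: int = 0
    noise_sd_velocity: float = 0.0
    polarization_model: str = "transverse-random"
    amplitude_model: str = "constant"
    rms_velocity: float = 1.0e-3  # m/s; keeps Δφ below the wrap limit

    def __post_init__(self) -> None:
        if self.n_plane_waves < 1:
            raise ValueError("n_plane_waves must be >= 1")
        if self.noise_sd_velocity < 0:
            raise ValueError("noise_sd_velocity must be >= 0")
        if self.rms_velocity <= 0:
            raise ValueError("rms_velocity must be positive")
        if self.polarization_model != "transverse-random":
            raise ValueError(f"unknown polarization_model {self.polarization_model!r}")
        if self.amplitude_model not in ("constant", "rayleigh"):
            raise ValueError(f"unknown amplitude_model {self.amplitude_model!r}")


def nominal_wavenumber(vs: float, excitation_freq: float) -> float:
    """k = 2*pi*F / vs (rad/m) — the plane-wave dispersion relation."""
    return 2.0 * math.pi * excitation_freq / vs
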