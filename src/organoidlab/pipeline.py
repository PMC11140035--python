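"""End-to-end orchestration: simulate -> estimate -> summarise -> test.

A run is fully determined by one YAML config plus a seed.  The demo scenario
simulates the five-arm, two-timepoint, three-replicate organoid study with
arm-dependent phantom physics (softer cores, smaller radii and higher surface
Brillouin shifts in the exposure arms), runs the Rev-OCE and Brillouin-OCT
estimators on every organoid, simulates and summarises the RNA-seq counts,
and applies the group statistics — writing one summary CSV row per organoid
plus the transcriptomics and statistics tables and a checksummed manifest.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import brillouin as bl
from . import io as olio
from . import phantom as ph
from . import revoce as rv
from . import stats as st
from . import transcriptomics as tx
from .config import ARMS, TIMEPOINTS, AcquisitionConfig, OrganoidPhantom, SimSpec, nominal_wavenumber

__all__ = ["RunConfig", "RunManifest", "ConfigError", "validate_config", "run_pipeline"]

#: Demo arm physics: multiplicative factors on (core speed, shell speed,
#: radius) and an additive surface Brillouin-shift delta (GHz) vs control.
DEMO_ARM_PHYSICS: dict[str, tuple[float, float, float, float]] = {
    "control": (1.00, 1.00, 1.00, 0.00),
    "DTG10": (0.85, 0.95, 0.92, 0.08),
    "DTG20": (0.75, 0.95, 0.88, 0.10),
    "DTG10_FA10": (0.90, 1.00, 0.95, 0.15),
    "DTG20_FA20": (0.85, 1.00, 0.92, 0.18),
}

#: Tsepamo surveillance NTD counts used as the prevalence worked examples:
#: (label, cases, deliveries) for the 2018 signal and its two follow-ups.
TSEPAMO_COUNTS = (
    ("tsepamo_2018", 4, 426),
    ("tsepamo_2019", 5, 1683),
    ("tsepamo_2022", 10, 9460),
)


class ConfigError(ValueError):
    """Aggregated, human-readable configuration errors."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(errors))


@dataclass(frozen=True)
class Thresholds:
    fold_change: float = 15.0
    r_squared: float = 0.6
    shell_fraction: float = 0.2


@dataclass(frozen=True)
class RnaseqSpec:
    n_genes: int = 1000
    n_replicates: int = 3
    folr1_log2fc: float = 8.0
    dispersion: float = 0.1
    pseudocount: float = 1.0


@dataclass(frozen=True)
class BrillouinSpec:
    linewidth: float = 0.3  # GHz FWHM
    noise_sd: float = 10.0  # counts
    n_surface_points: int = 15
    slope: float = 0.03  # true dispersion, GHz/pixel
    intercept: float = -7.68  # GHz
    n_pixels: int = 512


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved, serialisable run configuration."""

    experiment: str = "demo"
    seed: int = 0
    output_dir: str = "organoidlab_run"
    acquisition: AcquisitionConfig = field(
        default_factory=lambda: AcquisitionConfig(
            grid_points=(41, 41), n_timepoints=250
        )
    )
    phantom: OrganoidPhantom = field(default_factory=OrganoidPhantom)
    simulation: SimSpec = field(
        default_factory=lambda: SimSpec(n_plane_waves=400, noise_sd_velocity=0.0)
    )
    thresholds: Thresholds = field(default_factory=Thresholds)
    rnaseq: RnaseqSpec = field(default_factory=RnaseqSpec)
    brillouin: BrillouinSpec = field(default_factory=BrillouinSpec)
    oct_voxel_size: float = 2.5e-5
    write_volumes: bool = False

    @property
    def delta_t(self) -> float:
        """Resolved temporal resolution, 1/aline_rate (s)."""
        return self.acquisition.delta_t

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["delta_t"] = self.delta_t
        return d


@dataclass
class RunManifest:
    """Per-stage outputs with checksums and wall times."""

    experiment: str
    seed: int
    stages: dict[str, float] = field(default_factory=dict)  # stage -> seconds
    files: dict[str, str] = field(default_factory=dict)  # path -> sha256

    def add_file(self, path: Path) -> None:
        self.files[str(path)] = hashlib.sha256(path.read_bytes()).hexdigest()

    def write(self, path: Path) -> None:
        path.write_text(
            json.dumps(
                {
                    "experiment": self.experiment,
                    "seed": self.seed,
                    "stages_seconds": self.stages,
                    "files_sha256": self.files,
                },
                indent=2,
            )
        )


# ---------------------------------------------------------------------------
# Config validation
# ---------------------------------------------------------------------------

_SECTION_TYPES = {
    "acquisition": AcquisitionConfig,
    "phantom": OrganoidPhantom,
    "simulation": SimSpec,
    "thresholds": Thresholds,
    "rnaseq": RnaseqSpec,
    "brillouin": BrillouinSpec,
}
_SCALAR_KEYS = {"experiment", "seed", "output_dir", "oct_voxel_size", "write_volumes"}


def validate_config(raw: dict | str | Path | None) -> RunConfig:
    """Build a typed, defaults-complete RunConfig from a raw mapping or YAML.

    All problems — unknown keys, type errors, constraint violations — are
    collected and raised together in a single :class:`ConfigError`.
    An empty document resolves to the complete demo configuration.
    """
    if raw is None:
        raw = {}
    if isinstance(raw, (str, Path)):
        text = Path(raw).read_text()
        raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ConfigError(["top-level config must be a mapping"])

    errors: list[str] = []
    unknown = set(raw) - _SCALAR_KEYS - set(_SECTION_TYPES)
    for k in sorted(unknown):
        errors.append(f"unknown key {k!r}")

    kwargs: dict = {}
    for k in _SCALAR_KEYS & set(raw):
        kwargs[k] = raw[k]
    for section, cls in _SECTION_TYPES.items():
        sub = raw.get(section)
        if sub is None:
            continue
        if not isinstance(sub, dict):
            errors.append(f"section {section!r} must be a mapping")
            continue
        valid_fields = {f.name for f in dataclasses.fields(cls)}
        bad = set(sub) - valid_fields
        for k in sorted(bad):
            errors.append(f"unknown key {section}.{k}")
        clean = {k: v for k, v in sub.items() if k in valid_fields}
        for tup_key in ("grid_points", "scan_extent", "center"):
            if tup_key in clean and isinstance(clean[tup_key], list):
                clean[tup_key] = tuple(clean[tup_key])
        try:
            kwargs[section] = cls(**clean)
        except (TypeError, ValueError) as e:
            errors.append(f"{section}: {e}")
    if errors:
        raise ConfigError(errors)
    try:
        return RunConfig(**kwargs)
    except (TypeError, ValueError) as e:  # cross-field constraint failures
        raise ConfigError([str(e)]) from e


# ---------------------------------------------------------------------------
# Stage helpers
# ---------------------------------------------------------------------------

def _arm_phantom(
    cfg: RunConfig, arm: str, timepoint: str, rng: np.random.Generator
) -> OrganoidPhantom:
    """Phantom for one organoid: arm/timepoint physics plus ~4% biological
    replicate-to-replicate variability in size, stiffness and surface shift."""
    core_f, shell_f, rad_f, shift_d = DEMO_ARM_PHYSICS[arm]
    growth = 1.0 if timepoint == "day20" else 1.1
    size_j = float(np.exp(rng.normal(0.0, 0.04)))
    speed_j = float(np.exp(rng.normal(0.0, 0.04)))
    shift_j = float(rng.normal(0.0, 0.02))
    base = cfg.phantom
    return OrganoidPhantom(
        center=base.center,
        shell_outer_radius=base.shell_outer_radius * rad_f * growth * size_j,
        core_radius=base.core_radius * rad_f * growth * size_j,
        vs_shell=base.vs_shell * shell_f * speed_j,
        vs_core=base.vs_core * core_f * speed_j,
        vs_background=base.vs_background,
        brillouin_shift_shell=base.brillouin_shift_shell + shift_d + shift_j,
        brillouin_shift_core=base.brillouin_shift_core,
    )


def process_organoid(
    phantom: OrganoidPhantom,
    acq: AcquisitionConfig,
    sim: SimSpec,
    thresholds: Thresholds,
    bandpass: bool | None = None,
) -> tuple[rv.RegionSummary, rv.SpeedMap]:
    """Full Rev-OCE chain on one phantom: field -> phase -> speed summary.

    The spatial bandpass is a noise-management step: by default it is applied
    only when the simulation carries velocity noise (on clean data the band
    edges can only distort the autocorrelation of a small aperture).
    """
    vfield = ph.simulate_reverberant_field(phantom, acq, sim)
    pvol = ph.field_to_phase_volume(vfield)
    v = rv.phase_to_velocity(pvol)
    h = rv.extract_harmonic(v)
    if bandpass is None:
        bandpass = sim.noise_sd_velocity > 0
    if bandpass:
        k_nom = nominal_wavenumber(phantom.vs_core, acq.excitation_freq)
        k_lo, k_hi = rv.default_band(k_nom)
        k_hi = min(k_hi, 0.95 * np.pi / max(acq.grid_spacing))
        h = rv.spatial_bandpass(h, k_lo, k_hi)
    km = rv.estimate_wavenumber_map(h, acq, quality_threshold=thresholds.r_squared)
    sm = rv.wavenumber_to_speed(km, acq.excitation_freq)
    mask = ph.phantom_mask_on_grid(phantom, km.x_centers, km.y_centers)
    summary = rv.regionwise_speed_summary(sm, mask, thresholds.shell_fraction)
    return summary, sm


def speed_recovery_study(
    speeds: tuple[float, ...] = (1.0, 2.0, 3.0, 5.0),
    noise_sd: float = 0.0,
    n_acquisitions: int = 12,
    seed: int = 0,
    acq: AcquisitionConfig | None = None,
) -> dict[float, float]:
    """Homogeneous-phantom calibration: recovered median speed per true speed.

    For each true shear speed, ``n_acquisitions`` independent reverberant
    acquisitions are simulated, pushed through the full phase-encode ->
    velocity -> harmonic -> wavenumber -> speed chain, and the per-acquisition
    medians over valid windows averaged.  A single 2-2.8 mm aperture holds
    only a couple of speckle cells at the longest wavelengths, so replicate
    acquisitions (the study scans three organoids per group) are what make
    the median a stable calibration readout.
    """
    from .config import homogeneous_phantom

    if acq is None:
        acq = AcquisitionConfig()
    out: dict[float, float] = {}
    for i, vs in enumerate(speeds):
        phantom = homogeneous_phantom(vs, acq)
        meds = []
        for j in range(n_acquisitions):
            sim = SimSpec(
                rng_seed=seed + 1000 * i + j, noise_sd_velocity=noise_sd
            )
            summary_sim = ph.simulate_reverberant_field(phantom, acq, sim)
            pvol = ph.field_to_phase_volume(summary_sim)
            v = rv.phase_to_velocity(pvol)
            h = rv.extract_harmonic(v)
            if noise_sd > 0:
                k_nom = nominal_wavenumber(vs, acq.excitation_freq)
                k_lo, k_hi = rv.default_band(k_nom)
                k_hi = min(k_hi, 0.95 * np.pi / max(acq.grid_spacing))
                h = rv.spatial_bandpass(h, k_lo, k_hi)
            km = rv.estimate_wavenumber_map(h, acq)
            sm = rv.wavenumber_to_speed(km, acq.excitation_freq)
            vals = sm.vs[sm.valid]
            if vals.size:
                meds.append(float(np.median(vals)))
        out[vs] = float(np.mean(meds)) if meds else float("nan")
    return out


def _brillouin_calibration(cfg: RunConfig, rng: np.random.Generator) -> bl.CalibrationModel:
    true_map = ph.AffinePixelMap(cfg.brillouin.slope, cfg.brillouin.intercept)
    refs = {
        liquid: ph.simulate_brillouin_spectrum(
            shift,
            cfg.brillouin.linewidth,
            true_map,
            noise_sd=cfg.brillouin.noise_sd,
            seed=int(rng.integers(2**31)),
            n_pixels=cfg.brillouin.n_pixels,
        )
        for liquid, shift in bl.DEFAULT_REFERENCE_SHIFTS.items()
    }
    return bl.calibrate_spectrometer(refs, bl.DEFAULT_REFERENCE_SHIFTS)


def _surface_shift(
    cfg: RunConfig,
    phantom: OrganoidPhantom,
    calib: bl.CalibrationModel,
    rng: np.random.Generator,
) -> tuple[float, int]:
    """Fit spectra at surface sampling points; return (mean shift, n valid)."""
    true_map = ph.AffinePixelMap(cfg.brillouin.slope, cfg.brillouin.intercept)
    vals = []
    for _ in range(cfg.brillouin.n_surface_points):
        spec = ph.simulate_brillouin_spectrum(
            phantom.brillouin_shift_shell,
            cfg.brillouin.linewidth,
            true_map,
            noise_sd=cfg.brillouin.noise_sd,
            seed=int(rng.integers(2**31)),
            n_pixels=cfg.brillouin.n_pixels,
        )
        fit = bl.fit_shift(spec, calib)
        if fit.valid:
            vals.append(fit.nu_B)
    return (float(np.mean(vals)) if vals else float("nan")), len(vals)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def run_pipeline(cfg: RunConfig) -> RunManifest:
    """Execute all stages in dependency order; abort naming a failing stage."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(experiment=cfg.experiment, seed=cfg.seed)
    master = np.random.default_rng(cfg.seed)

    stage = "elastography"
    try:
        t0 = time.perf_counter()
        calib = _brillouin_calibration(cfg, np.random.default_rng(cfg.seed + 1))
        rows = []
        for arm in ARMS:
            for tp in TIMEPOINTS:
                for rep in range(1, cfg.rnaseq.n_replicates + 1):
                    organoid_seed = int(master.integers(2**31))
                    phantom = _arm_phantom(
                        cfg, arm, tp, np.random.default_rng(organoid_seed + 13)
                    )
                    sim = dataclasses.replace(cfg.simulation, rng_seed=organoid_seed)
                    summary, _ = process_organoid(
                        phantom, cfg.acquisition, sim, cfg.thresholds
                    )
                    oct_vol = ph.simulate_oct_volume(
                        phantom, cfg.oct_voxel_size, snr=5.0, seed=organoid_seed
                    )
                    seg = bl.segment_organoid(oct_vol)
                    mid = seg.mask[:, :, seg.mask.shape[2] // 2]
                    morph = rv.organoid_volume(
                        mask=mid, spacing_mm=cfg.oct_voxel_size * 1e3
                    )
                    shift_rng = np.random.default_rng(organoid_seed + 7)
                    shift_mean, shift_n = _surface_shift(cfg, phantom, calib, shift_rng)
                    rows.append(
                        {
                            "organoid_id": f"{arm}_{tp}_r{rep}",
                            "arm": arm,
                            "day": tp,
                            "surface_mean_vs": summary.surface_mean,
                            "core_mean_vs": summary.core_mean,
                            "d_mean_mm": morph.d_mean,
                            "volume_mm3": morph.volume,
                            "surface_mean_shift_GHz": shift_mean,
                            "n_shift_points": shift_n,
                        }
                    )
        summary_df = pd.DataFrame(rows)
        summary_path = out / "organoid_summary.csv"
        summary_df.to_csv(summary_path, index=False)
        manifest.add_file(summary_path)
        manifest.stages[stage] = time.perf_counter() - t0

        stage = "rnaseq"
        t0 = time.perf_counter()
        design = ph.default_design(cfg.rnaseq.n_replicates)
        counts = ph.simulate_counts(
            design,
            n_genes=cfg.rnaseq.n_genes,
            dispersion=cfg.rnaseq.dispersion,
            effects=ph.default_effects(cfg.rnaseq.folr1_log2fc),
            seed=cfg.seed + 2,
        )
        olio.save_counts_tsv(out / "counts.tsv", counts)
        olio.save_design_tsv(out / "design.tsv", design)
        nm = tx.cpm_normalize(counts, pseudocount=cfg.rnaseq.pseudocount)
        de = tx.fold_changes(nm, design)
        de.to_csv(out / "de_results.tsv", sep="\t", index=False)
        lists = tx.threshold_gene_lists(de, cfg.thresholds.fold_change)
        venn = tx.venn_partition({a: set(lists[a]["up"]) for a in lists})
        venn_df = pd.DataFrame(
            {
                "region": ["&".join(k) for k in venn.region_counts],
                "count": list(venn.region_counts.values()),
                "genes": [
                    ";".join(sorted(venn.region_members[k])) for k in venn.region_counts
                ],
            }
        )
        venn_df.to_csv(out / "venn_regions.tsv", sep="\t", index=False)
        pca = tx.run_pca(nm, design)
        scores = pca.scores.copy()
        scores.insert(0, "sample", scores.index)
        scores.to_csv(out / "pca_scores.tsv", sep="\t", index=False)
        for name in ("counts.tsv", "design.tsv", "de_results.tsv", "venn_regions.tsv", "pca_scores.tsv"):
            manifest.add_file(out / name)
        manifest.stages[stage] = time.perf_counter() - t0

        stage = "stats"
        t0 = time.perf_counter()
        stat_rows = []
        for metric in ("surface_mean_vs", "core_mean_vs", "volume_mm3", "surface_mean_shift_GHz"):
            for tp in TIMEPOINTS:
                tab = summary_df.loc[summary_df["day"] == tp].rename(
                    columns={metric: "value"}
                )[["arm", "value"]].dropna()
                if tab.groupby("arm").size().min() < 2 or tab["arm"].nunique() < 2:
                    continue
                res = st.one_way_anova(tab)
                stat_rows.append(
                    {
                        "test": "one_way_anova",
                        "metric": metric,
                        "day": tp,
                        "groups": ";".join(res.group_means),
                        "statistic": res.f_statistic,
                        "p_raw": res.p_value,
                        "p_adjusted": res.p_value,
                        "stars": st.significance_stars(res.p_value),
                    }
                )
                for pw in st.bonferroni_pairwise(tab):
                    stat_rows.append(
                        {
                            "test": "bonferroni_t",
                            "metric": metric,
                            "day": tp,
                            "groups": f"{pw.group_a};{pw.group_b}",
                            "statistic": pw.t_statistic,
                            "p_raw": pw.p_raw,
                            "p_adjusted": pw.p_adjusted,
                            "stars": pw.stars,
                        }
                    )
        pd.DataFrame(stat_rows).to_csv(out / "stats_report.tsv", sep="\t", index=False)
        prev_rows = []
        for label, k, n in TSEPAMO_COUNTS:
            pr = st.prevalence(k, n)
            prev_rows.append(
                {
                    "study": label,
                    "cases": k,
                    "denominator": n,
                    "percent": pr.percent,
                    "ci_low": pr.ci_low,
                    "ci_high": pr.ci_high,
                }
            )
        pd.DataFrame(prev_rows).to_csv(out / "prevalence.tsv", sep="\t", index=False)
        manifest.add_file(out / "stats_report.tsv")
        manifest.add_file(out / "prevalence.tsv")
        manifest.stages[stage] = time.perf_counter() - t0
    except Exception as e:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e

    manifest.write(out / "manifest.json")
    return manifest
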