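"""File formats shared across the pipeline: HDF5 volumes, TSV tables."""
from __future__ import annotations

import dataclasses
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .config import AcquisitionConfig
from .phantom import GroupDesign
from .revoce import PhaseVolume, SpeedMap, VelocityField, WavenumberMap


def _write_acq(group: h5py.Group, acq: AcquisitionConfig) -> None:
    for f in dataclasses.fields(acq):
        group.attrs[f.name] = getattr(acq, f.name)


def _read_acq(group: h5py.Group) -> AcquisitionConfig:
    kwargs = {}
    for f in dataclasses.fields(AcquisitionConfig):
        v = group.attrs[f.name]
        if f.name in ("grid_points",):
            kwargs[f.name] = tuple(int(x) for x in v)
        elif f.name in ("scan_extent",):
            kwargs[f.name] = tuple(float(x) for x in v)
        elif f.name == "n_timepoints":
            kwargs[f.name] = int(v)
        else:
            kwargs[f.name] = float(v)
    return AcquisitionConfig(**kwargs)


def save_phase_volume(path: str | Path, p: PhaseVolume, vz: VelocityField | None = None) -> None:
    """HDF5 layout: /dphi [t,x,y], optional /vz, acquisition attrs on root."""
    with h5py.File(path, "w") as f:
        f.create_dataset("dphi", data=p.dphi, compression="gzip")
        if vz is not None:
            f.create_dataset("vz", data=vz.vz, compression="gzip")
        _write_acq(f, p.acq)


def load_phase_volume(path: str | Path) -> PhaseVolume:
    with h5py.File(path, "r") as f:
        acq = _read_acq(f)
        return PhaseVolume(dphi=f["dphi"][...], acq=acq)


def save_maps(path: str | Path, km: WavenumberMap, sm: SpeedMap) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("wavenumber")
        g.create_dataset("k", data=km.k)
        g.create_dataset("fit_quality", data=km.fit_quality)
        g.create_dataset("valid", data=km.valid)
        g.create_dataset("x_centers", data=km.x_centers)
        g.create_dataset("y_centers", data=km.y_centers)
        g.attrs["window_size"] = km.window_size
        s = f.create_group("speed")
        s.create_dataset("vs", data=sm.vs)
        s.create_dataset("valid", data=sm.valid)
        s.attrs["freq"] = sm.freq


def save_counts_tsv(path: str | Path, counts: pd.DataFrame) -> None:
    """Genes x samples TSV with a header row of sample IDs."""
    counts.to_csv(path, sep="\t", index_label="gene")


def load_counts_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def save_design_tsv(path: str | Path, design: GroupDesign) -> None:
    design.table.to_csv(path, sep="\t", index=False)


def load_design_tsv(path: str | Path) -> GroupDesign:
    return GroupDesign(table=pd.read_csv(path, sep="\t"))


def save_counts_mtx(path: str | Path, counts: pd.DataFrame) -> None:
    """Optional MatrixMarket export (gene/sample labels as sidecar files)."""
    from scipy.io import mmwrite
    from scipy.sparse import csr_matrix

    path = Path(path)
    mmwrite(path, csr_matrix(counts.to_numpy()))
    path.with_suffix(".genes.txt").write_text("\n".join(counts.index) + "\n")
    path.with_suffix(".samples.txt").write_text("\n".join(counts.columns) + "\n")


def save_oct_volume(path: str | Path, intensity: np.ndarray, voxel_size: float) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("oct", data=intensity, compression="gzip")
        f.attrs["voxel_size"] = voxel_size
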