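"""Dataset layout, readers/writers, run configuration and the full pipeline.

A scan lives in a plain directory for inspectability:

    scan_dir/
      frames.tiff   multi-page TIFF, one page per angle (32-bit float counts)
      flats.tiff    empty-beam frames
      darks.tiff    dark frames
      gain.tiff     per-pixel gain map
      angles.txt    one angle (degrees) per line
      config.yaml   geometry, seed, photon count, arc

Volumes are written as multi-page 32-bit float TIFF with a JSON provenance
sidecar (optionally a single HDF5 container).  ``run_pipeline`` binds the
stages together: simulate (optional) -> retrieve -> reconstruct -> render /
segment, with every seed and parameter recorded in the resolved config that
is written next to the outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .geometry import AcquisitionGeometry
from .histology import n_slices_for_thickness, render_hne, slab, threshold_label
from .recon import ReconVolume, reconstruct_scan
from .retrieval import RegularizationParams, retrieve_stack
from .simulate import ProjectionSet, build_phantom, simulate_scan

logger = logging.getLogger(__name__)

CONFIG_NAME = "config.yaml"


@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    # simulation (optional stage)
    preset: str = "cortex_layers"
    size: int = 64
    n_angles: int = 200
    arc: float = 180.0
    photon_count: float = 1e4
    ring_sigma: float = 0.02
    noise: bool = True
    n_cells: int = 50
    # geometry
    geometry: AcquisitionGeometry = field(default_factory=AcquisitionGeometry)
    # retrieval
    alpha: float = 1e-3
    gamma: float = 1.0
    pad_fraction: float = 0.25
    # reconstruction
    ring: str = "wavelet"
    binning: int = 1
    pad_width: int = 0
    # rendering / segmentation
    section_thickness_um: float = 30.0
    gray_range: tuple[float, float] | None = None
    min_voxels: int = 27
    # bookkeeping
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["geometry"] = self.geometry.to_dict()
        if self.gray_range is not None:
            d["gray_range"] = list(self.gray_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        missing = {"alpha", "gamma", "seed"} - set(d)
        if missing:
            raise KeyError(f"config missing required keys: {sorted(missing)}")
        if "geometry" in d:
            d["geometry"] = AcquisitionGeometry.from_dict(d["geometry"])
        if d.get("gray_range") is not None:
            d["gray_range"] = tuple(d["gray_range"])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValueError(f"unparseable config file {path}")
        return cls.from_dict(data)


# ---------------------------------------------------------------------------
# Scan I/O
# ---------------------------------------------------------------------------

def write_scan(scan: ProjectionSet, path: str | Path) -> Path:
    """Write a ProjectionSet as TIFF stacks + angles.txt + config.yaml."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path / "frames.tiff", scan.frames.astype(np.float32))
    tifffile.imwrite(path / "flats.tiff", scan.flats.astype(np.float32))
    tifffile.imwrite(path / "darks.tiff", scan.darks.astype(np.float32))
    tifffile.imwrite(path / "gain.tiff", scan.gain_map.astype(np.float32))
    np.savetxt(path / "angles.txt", scan.angles, fmt="%.8f")
    meta = {
        "geometry": scan.geometry.to_dict(),
        "seed": int(scan.seed),
        "arc": float(scan.arc),
        "photon_count": float(scan.photon_count),
    }
    (path / CONFIG_NAME).write_text(yaml.safe_dump(meta, sort_keys=True))
    return path


def read_scan(path: str | Path) -> ProjectionSet:
    """Read a scan directory back into a ProjectionSet (dtype-preserving)."""
    path = Path(path)
    for name in ("frames.tiff", "flats.tiff", "darks.tiff", CONFIG_NAME, "angles.txt"):
        if not (path / name).exists():
            raise FileNotFoundError(f"scan directory {path} is missing {name}")
    meta = yaml.safe_load((path / CONFIG_NAME).read_text())
    frames = tifffile.imread(path / "frames.tiff").astype(np.float64)
    flats = tifffile.imread(path / "flats.tiff").astype(np.float64)
    darks = tifffile.imread(path / "darks.tiff").astype(np.float64)
    if flats.ndim == 2:
        flats = flats[None]
    if darks.ndim == 2:
        darks = darks[None]
    gain_file = path / "gain.tiff"
    gain = (
        tifffile.imread(gain_file).astype(np.float64)
        if gain_file.exists()
        else np.ones(frames.shape[1:])
    )
    return ProjectionSet(
        angles=np.loadtxt(path / "angles.txt", ndmin=1),
        frames=frames,
        flats=flats,
        darks=darks,
        gain_map=gain,
        seed=int(meta["seed"]),
        geometry=AcquisitionGeometry.from_dict(meta["geometry"]),
        arc=float(meta["arc"]),
        photon_count=float(meta["photon_count"]),
    )


# ---------------------------------------------------------------------------
# Volume I/O
# ---------------------------------------------------------------------------

def write_volume(volume: ReconVolume, path: str | Path, hdf5: bool = False) -> Path:
    """Multi-page float32 TIFF plus a JSON provenance sidecar (or HDF5)."""
    path = Path(path)
    if hdf5:
        import h5py

        with h5py.File(path, "w") as f:
            ds = f.create_dataset("volume", data=volume.values.astype(np.float32))
            ds.attrs["voxel_size"] = volume.voxel_size
            ds.attrs["provenance"] = json.dumps(volume.provenance)
        return path
    tifffile.imwrite(path, volume.values.astype(np.float32))
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps({"voxel_size": volume.voxel_size, "provenance": volume.provenance}, indent=2)
    )
    return path


def read_volume(path: str | Path) -> ReconVolume:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "r") as f:
            ds = f["volume"]
            return ReconVolume(
                values=ds[...].astype(np.float64),
                voxel_size=float(ds.attrs["voxel_size"]),
                provenance=json.loads(ds.attrs.get("provenance", "{}")),
            )
    values = tifffile.imread(path).astype(np.float64)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return ReconVolume(
        values=values,
        voxel_size=float(meta.get("voxel_size", 1.0)),
        provenance=meta.get("provenance", {}),
    )


def checksum(array: np.ndarray) -> str:
    """SHA-256 of the raw array bytes (determinism checks)."""
    return hashlib.sha256(np.ascontiguousarray(array).tobytes()).hexdigest()


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig, out_dir: str | Path, scan_dir: str | Path | None = None) -> dict:
    """simulate? -> retrieve -> reconstruct -> render + segment.

    If ``scan_dir`` is given that scan is processed; otherwise a scan is
    simulated from the config's phantom preset.  Writes the contrast stack
    QC table, the volume, a MIP section (grayscale + H&E render), the label
    map summary and the resolved config; returns a result summary dict
    (checksums, counts, paths).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    phantom = None
    if scan_dir is None:
        phantom = build_phantom(
            config.preset, config.size, seed=config.seed,
            voxel_size=config.geometry.effective_pixel, n_cells=config.n_cells,
        )
        scan = simulate_scan(
            phantom, config.geometry, config.n_angles, arc=config.arc,
            photon_count=config.photon_count, ring_sigma=config.ring_sigma,
            seed=config.seed, noise=config.noise, pad_fraction=config.pad_fraction,
        )
        write_scan(scan, out / "scan")
    else:
        scan = read_scan(scan_dir)

    params = RegularizationParams(alpha=config.alpha, gamma=config.gamma, pad_fraction=config.pad_fraction)
    stack, qc = retrieve_stack(scan, params)
    qc.to_csv(out / "retrieval_qc.csv", index=False)
    tifffile.imwrite(out / "contrast.tiff", stack.astype(np.float32))

    volume = reconstruct_scan(
        stack, scan.angles, scan.geometry,
        ring=config.ring, binning=config.binning, pad_width=config.pad_width,
        force_parallel=True,
    )
    write_volume(volume, out / "volume.tiff")

    n_mip = n_slices_for_thickness(config.section_thickness_um, volume.voxel_size)
    n_mip = min(n_mip, volume.values.shape[0])
    start = (volume.values.shape[0] - n_mip) // 2
    section = slab(volume, plane="axial", start=start, n_slices=n_mip, mode="max")
    tifffile.imwrite(out / "mip.tiff", section.image.astype(np.float32))
    tifffile.imwrite(out / "mip_hne.tiff", render_hne(section.image))

    if config.gray_range is not None:
        gray_range = config.gray_range
    else:
        lo = float(np.percentile(volume.values, 50) + 0.5 * (np.percentile(volume.values, 99.9) - np.percentile(volume.values, 50)))
        gray_range = (lo, float(volume.values.max()) + 1.0)
    label_map = threshold_label(volume, None, gray_range, min_voxels=config.min_voxels)
    label_map.table.to_csv(out / "cells.csv", index=False)
    tifffile.imwrite(out / "labels.tiff", label_map.labels.astype(np.uint16))

    config.save(out / "run_config.yaml")
    result = {
        "n_angles": int(scan.n_angles),
        "volume_checksum": checksum(volume.values),
        "contrast_checksum": checksum(stack),
        "n_cells_detected": label_map.n_cells,
        "n_cells_truth": len([o for o in (phantom.component_truth if phantom else []) if o.kind == "cell"]),
        "gray_range": [float(g) for g in gray_range],
        "mip_n_slices": int(n_mip),
        "out_dir": str(out),
    }
    (out / "summary.json").write_text(json.dumps(result, indent=2))
    logger.info("pipeline complete: %s", result)
    return result
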