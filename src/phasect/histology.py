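"""Virtual histology: slabs, H&E-like rendering and cell segmentation.

A reconstructed tomogram can be resliced in any orientation without physical
sectioning.  To emulate the contrast of a real histological section of
finite thickness, a maximum intensity projection (MIP) over the matching
number of slices is used for cytoarchitecture; a minimum intensity
projection highlights the (low-density) vascular lumina instead.  Cell
segmentation mirrors a threshold-based brush: inside a user-supplied seed
mask, voxels within a gray range become labels via 3D connected components.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .recon import ReconVolume

logger = logging.getLogger(__name__)

MODES = ("single", "max", "min", "mean")
PLANES = {"axial": 0, "coronal": 1, "sagittal": 2, "z": 0, "y": 1, "x": 2}


@dataclass
class VirtualSection:
    """One histology-like section with physical-thickness bookkeeping."""

    image: np.ndarray
    mode: str
    plane: str
    n_slices: int
    voxel_size: float

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.mode == "single" and self.n_slices != 1:
            raise ValueError("mode='single' implies n_slices=1")

    @property
    def physical_thickness(self) -> float:
        """Section thickness in um: exactly n_slices x voxel_size."""
        return self.n_slices * self.voxel_size


@dataclass
class LabelMap:
    """Segmented cells: 3D labels (0 = background) plus a per-label table."""

    labels: np.ndarray
    table: pd.DataFrame
    gray_range: tuple[float, float]
    voxel_size: float
    parameters: dict = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return int(self.labels.max())


def n_slices_for_thickness(thickness: float, voxel: float) -> int:
    """Largest n with n * voxel <= thickness (e.g. 30 um at 0.95 um -> 31)."""
    if thickness <= 0 or voxel <= 0:
        raise ValueError("thickness and voxel must be > 0")
    return max(int(math.floor(thickness / voxel + 1e-9)), 1)


def slab(
    volume: ReconVolume | np.ndarray,
    plane: str = "axial",
    start: int = 0,
    n_slices: int = 1,
    mode: str = "max",
    voxel_size: float | None = None,
    normal: np.ndarray | None = None,
    point: np.ndarray | None = None,
) -> VirtualSection:
    """Project ``n_slices`` consecutive planes into one section.

    Axis-aligned planes (``plane`` in axial/coronal/sagittal or z/y/x) are
    extracted exactly; an oblique orientation may be given instead as a unit
    ``normal`` and a ``point`` on the first plane, in which case planes are
    resampled trilinearly.  ``mode``: max (MIP, cytoarchitecture), min
    (MinIP, vasculature), mean, or single.
    """
    if isinstance(volume, ReconVolume):
        data, voxel = volume.values, volume.voxel_size
    else:
        data = np.asarray(volume)
        voxel = voxel_size if voxel_size is not None else 1.0
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    n = 1 if mode == "single" else n_slices

    if normal is not None:
        planes = _oblique_planes(data, np.asarray(normal, float), np.asarray(point, float), n)
        plane_name = "oblique"
    else:
        axis = PLANES.get(plane)
        if axis is None:
            raise ValueError(f"unknown plane {plane!r}")
        if start < 0 or start + n > data.shape[axis]:
            raise ValueError(
                f"slab [{start}, {start + n}) exceeds axis {axis} of size {data.shape[axis]}"
            )
        planes = np.moveaxis(data, axis, 0)[start : start + n]
        plane_name = plane
    if mode == "max":
        image = planes.max(axis=0)
    elif mode == "min":
        image = planes.min(axis=0)
    else:  # mean or single
        image = planes.mean(axis=0)
    return VirtualSection(image=image, mode=mode, plane=plane_name, n_slices=n, voxel_size=voxel)


def _oblique_planes(data: np.ndarray, normal: np.ndarray, point: np.ndarray, n: int) -> np.ndarray:
    normal = normal / np.linalg.norm(normal)
    # build an orthonormal in-plane basis
    helper = np.array([1.0, 0.0, 0.0]) if abs(normal[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(normal, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    extent = int(np.ceil(np.linalg.norm(data.shape)))
    grid = np.arange(extent) - extent / 2
    uu, vv = np.meshgrid(grid, grid, indexing="ij")
    planes = []
    for i in range(n):
        origin = point + i * normal
        coords = (
            origin[:, None, None]
            + e1[:, None, None] * uu[None]
            + e2[:, None, None] * vv[None]
        )
        planes.append(ndimage.map_coordinates(data, coords, order=1, mode="constant", cval=np.nan))
    return np.asarray(planes)


def threshold_label(
    volume: ReconVolume | np.ndarray,
    seed_mask: np.ndarray | None,
    gray_range: tuple[float, float],
    connectivity: int = 26,
    min_voxels: int = 27,
    voxel_size: float | None = None,
) -> LabelMap:
    """Threshold-brush segmentation: gray-range selection inside a seed mask.

    Voxels of the seed mask whose intensity falls in ``gray_range`` are kept;
    3D connected components (26-connectivity by default) become cell labels;
    components below ``min_voxels`` are discarded (logged).  An empty result
    is a warning, not an error.
    """
    if isinstance(volume, ReconVolume):
        data, voxel = volume.values, volume.voxel_size
    else:
        data = np.asarray(volume)
        voxel = voxel_size if voxel_size is not None else 1.0
    lo, hi = gray_range
    if not lo < hi:
        raise ValueError("gray_range must satisfy lo < hi")
    mask = (data >= lo) & (data <= hi)
    if seed_mask is not None:
        seed_mask = np.asarray(seed_mask, bool)
        if seed_mask.shape != data.shape:
            raise ValueError("seed_mask shape must match the volume")
        mask &= seed_mask
    structure = _structure(connectivity)
    labels, n = ndimage.label(mask, structure=structure)
    if n:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        keep = np.flatnonzero(sizes >= min_voxels) + 1
        dropped = n - len(keep)
        if dropped:
            logger.info("threshold_label: discarded %d components < %d voxels", dropped, min_voxels)
        remap = np.zeros(n + 1, dtype=np.int32)
        remap[keep] = np.arange(1, len(keep) + 1)
        labels = remap[labels]
        n = len(keep)
    if n == 0:
        logger.warning("threshold_label: no components in gray range %s", gray_range)
    table = _label_table(labels, data, n, voxel)
    return LabelMap(
        labels=labels,
        table=table,
        gray_range=(float(lo), float(hi)),
        voxel_size=voxel,
        parameters={"connectivity": connectivity, "min_voxels": min_voxels},
    )


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return np.ones((3, 3, 3), dtype=bool)
    if connectivity == 18:
        return ndimage.generate_binary_structure(3, 2)
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    raise ValueError("connectivity must be 6, 18 or 26")


def _label_table(labels: np.ndarray, data: np.ndarray, n: int, voxel: float) -> pd.DataFrame:
    if n == 0:
        return pd.DataFrame(
            columns=["label", "z_um", "y_um", "x_um", "voxels", "mean_intensity"]
        ).astype({"label": int, "voxels": int})
    idx = np.arange(1, n + 1)
    centroids = np.asarray(ndimage.center_of_mass(np.ones_like(data), labels, index=idx))
    sizes = ndimage.sum_labels(np.ones_like(data), labels, index=idx)
    means = ndimage.mean(data, labels, index=idx)
    return pd.DataFrame(
        {
            "label": idx,
            "z_um": centroids[:, 0] * voxel,
            "y_um": centroids[:, 1] * voxel,
            "x_um": centroids[:, 2] * voxel,
            "voxels": sizes.astype(int),
            "mean_intensity": means,
        }
    )


def cell_statistics(
    label_map: LabelMap, layer_mask: np.ndarray | None = None
) -> pd.DataFrame:
    """Per-cell morphometrics: centroid (um), equivalent-sphere diameter, layer.

    ``layer_mask`` (integer volume) assigns each cell the layer of its
    centroid voxel, enabling per-layer counts of the 3D cell distribution.
    """
    table = label_map.table.copy()
    if table.empty:
        table["equiv_diameter_um"] = pd.Series(dtype=float)
        if layer_mask is not None:
            table["layer"] = pd.Series(dtype=int)
        return table
    volume_um3 = table["voxels"] * label_map.voxel_size**3
    table["equiv_diameter_um"] = (6.0 * volume_um3 / math.pi) ** (1.0 / 3.0)
    if layer_mask is not None:
        layer_mask = np.asarray(layer_mask)
        zi = np.clip((table["z_um"] / label_map.voxel_size).round().astype(int), 0, layer_mask.shape[0] - 1)
        yi = np.clip((table["y_um"] / label_map.voxel_size).round().astype(int), 0, layer_mask.shape[1] - 1)
        xi = np.clip((table["x_um"] / label_map.voxel_size).round().astype(int), 0, layer_mask.shape[2] - 1)
        table["layer"] = layer_mask[zi, yi, xi]
    return table


def render_hne(image: np.ndarray, clip_percentiles: tuple[float, float] = (1.0, 99.0)) -> np.ndarray:
    """Map a scalar section to a white-to-pink-to-magenta ramp (uint8 RGB).

    A purely cosmetic monotone colormap chosen so virtual sections resemble
    hematoxylin-and-eosin staining: dense (bright) structures render dark
    magenta, background renders near-white.  Contrast is percentile-clipped.
    """
    image = np.asarray(image, dtype=np.float64)
    lo, hi = np.percentile(image, clip_percentiles)
    if hi <= lo:
        t = np.zeros_like(image)
    else:
        t = np.clip((image - lo) / (hi - lo), 0.0, 1.0)
    # anchors: white -> pale pink -> eosin pink -> hematoxylin magenta/purple
    anchors = np.array(
        [
            [1.00, 1.00, 1.00],
            [0.99, 0.88, 0.92],
            [0.91, 0.54, 0.70],
            [0.55, 0.09, 0.45],
        ]
    )
    positions = np.array([0.0, 0.35, 0.7, 1.0])
    rgb = np.stack([np.interp(t, positions, anchors[:, c]) for c in range(3)], axis=-1)
    return np.clip(np.round(rgb * 255), 0, 255).astype(np.uint8)
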