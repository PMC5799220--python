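"""4D BOLD volumes, masks and label maps on a regular voxel grid.

NIfTI-1 reading/writing goes through nibabel. The spatial conventions
used everywhere else in the package live here:

* voxel indices are 0-based ``(x, y, z)`` triples;
* connectivity is the full 26-neighbourhood (faces, edges and corners),
  for seeding, cluster growth and border layers alike;
* label maps are int32 images sharing the input grid, 0 = background.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import GeometryError, ParameterError

Voxel = tuple[int, int, int]

#: 3x3x3 structuring element for 26-connectivity
STRUCT26 = np.ones((3, 3, 3), dtype=bool)

#: default mask rule: temporal-mean intensity above this fraction of the
#: grand maximum counts as in-brain
DEFAULT_MASK_FRACTION = 0.10


@dataclass(frozen=True)
class GridGeometry:
    """Voxel grid: dimensions, voxel size in mm, TR in s, time points."""

    dims: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    tr: float
    n_timepoints: int

    def __post_init__(self) -> None:
        if len(self.dims) != 3 or any(d < 1 for d in self.dims):
            raise GeometryError(f"invalid dims {self.dims}")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise GeometryError(f"invalid voxel size {self.voxel_size}")
        if self.tr <= 0:
            raise GeometryError("tr must be positive")
        if self.n_timepoints < 3:
            raise GeometryError("need at least 3 time points")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))

    @property
    def nyquist_hz(self) -> float:
        return 0.5 / self.tr

    def mm_coords(self, voxel: Voxel) -> tuple[float, float, float]:
        return tuple(i * s for i, s in zip(voxel, self.voxel_size))


@dataclass
class BoldVolume:
    """A 4D signal array indexed (x, y, z, t) plus geometry and brain mask."""

    geometry: GridGeometry
    data: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 4:
            raise GeometryError("data must be 4-D (x, y, z, t)")
        if self.data.shape[:3] != self.geometry.dims:
            raise GeometryError(
                f"data spatial shape {self.data.shape[:3]} != dims {self.geometry.dims}")
        if self.data.shape[3] != self.geometry.n_timepoints:
            raise GeometryError("temporal length does not match geometry")
        if self.mask.shape != self.geometry.dims:
            raise GeometryError(
                f"mask shape {self.mask.shape} != dims {self.geometry.dims}")

    def courses(self, voxels: Sequence[Voxel]) -> np.ndarray:
        """Stack the time courses of the given voxels, shape (N, T)."""
        idx = np.asarray(sorted(voxels), dtype=int)
        return self.data[idx[:, 0], idx[:, 1], idx[:, 2], :]


@dataclass
class LabelMap:
    """Integer parcellation image: 0 = background, k > 0 = region id k."""

    geometry: GridGeometry
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int32)
        if self.labels.shape != self.geometry.dims:
            raise GeometryError("label shape does not match geometry")

    @property
    def n_labels(self) -> int:
        return int(self.labels.max(initial=0))

    def voxels_of(self, label: int) -> set[Voxel]:
        return {tuple(v) for v in np.argwhere(self.labels == label)}


def _affine(voxel_size: Sequence[float]) -> np.ndarray:
    return np.diag([voxel_size[0], voxel_size[1], voxel_size[2], 1.0])


def default_mask(data: np.ndarray, fraction: float = DEFAULT_MASK_FRACTION) -> np.ndarray:
    """Liberal intensity mask: temporal-mean above ``fraction`` of its maximum."""
    mean = data.mean(axis=3)
    top = mean.max()
    if top <= 0:
        return np.ones(data.shape[:3], dtype=bool)
    return mean > fraction * top


def load_bold(path: str | Path, mask_path: Optional[str | Path] = None,
              tr: Optional[float] = None) -> BoldVolume:
    """Load a 4D NIfTI-1 image (and optional 3D mask) into a BoldVolume.

    The TR is taken from the NIfTI header's fourth zoom unless overridden.
    Without a mask, a simple intensity mask is derived (voxels whose
    temporal-mean intensity exceeds 10% of the grand maximum).
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise GeometryError(f"expected a 4-D image, got shape {data.shape}")
    if data.shape[3] < 3:
        raise GeometryError("need at least 3 time points")
    zooms = img.header.get_zooms()
    voxel_size = tuple(float(z) for z in zooms[:3])
    if tr is None:
        tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    geometry = GridGeometry(dims=data.shape[:3], voxel_size=voxel_size,
                            tr=tr, n_timepoints=data.shape[3])
    if mask_path is not None:
        mimg = nib.load(str(mask_path))
        mask = np.asarray(mimg.dataobj) > 0
        if mask.shape != data.shape[:3]:
            raise GeometryError(
                f"mask shape {mask.shape} does not match data grid {data.shape[:3]}")
    else:
        mask = default_mask(data)
    return BoldVolume(geometry=geometry, data=data, mask=mask)


def save_bold(volume: BoldVolume, path: str | Path) -> None:
    """Write a BoldVolume as NIfTI-1, recording voxel size and TR in the header."""
    img = nib.Nifti1Image(volume.data, _affine(volume.geometry.voxel_size))
    img.header.set_zooms((*volume.geometry.voxel_size, volume.geometry.tr))
    nib.save(img, str(path))


def save_mask(mask: np.ndarray, geometry: GridGeometry, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.astype(np.uint8), _affine(geometry.voxel_size))
    nib.save(img, str(path))


def save_labelmap(labelmap: LabelMap, path: str | Path) -> None:
    img = nib.Nifti1Image(labelmap.labels.astype(np.int32),
                          _affine(labelmap.geometry.voxel_size))
    nib.save(img, str(path))


def load_labelmap(path: str | Path, geometry: Optional[GridGeometry] = None) -> LabelMap:
    img = nib.load(str(path))
    labels = np.asarray(img.dataobj, dtype=np.int32)
    if geometry is None:
        zooms = img.header.get_zooms()
        geometry = GridGeometry(dims=labels.shape,
                                voxel_size=tuple(float(z) for z in zooms[:3]),
                                tr=1.0, n_timepoints=3)
    return LabelMap(geometry=geometry, labels=labels)


def neighbors26(voxel: Voxel, geometry: GridGeometry | tuple[int, int, int]) -> set[Voxel]:
    """The up-to-26 in-grid voxels differing by at most 1 on each axis."""
    dims = geometry.dims if isinstance(geometry, GridGeometry) else tuple(geometry)
    x, y, z = voxel
    if not (0 <= x < dims[0] and 0 <= y < dims[1] and 0 <= z < dims[2]):
        raise IndexError(f"voxel {voxel} outside grid {dims}")
    out: set[Voxel] = set()
    for dx in (-1, 0, 1):
        nx = x + dx
        if not 0 <= nx < dims[0]:
            continue
        for dy in (-1, 0, 1):
            ny = y + dy
            if not 0 <= ny < dims[1]:
                continue
            for dz in (-1, 0, 1):
                if dx == dy == dz == 0:
                    continue
                nz = z + dz
                if 0 <= nz < dims[2]:
                    out.add((nx, ny, nz))
    return out


def connected_components(voxels: Iterable[Voxel]) -> list[set[Voxel]]:
    """Partition a voxel set into maximal 26-connected components.

    Sorted by size descending; ties broken by the lexicographically
    smallest member, so the result is independent of input order.
    """
    vox = [tuple(int(c) for c in v) for v in voxels]
    if not vox:
        return []
    arr = np.asarray(vox, dtype=int)
    lo = arr.min(axis=0)
    shape = arr.max(axis=0) - lo + 1
    grid = np.zeros(shape, dtype=bool)
    grid[arr[:, 0] - lo[0], arr[:, 1] - lo[1], arr[:, 2] - lo[2]] = True
    labels, n = ndimage.label(grid, structure=STRUCT26)
    comps: list[set[Voxel]] = []
    for k in range(1, n + 1):
        members = np.argwhere(labels == k) + lo
        comps.append({tuple(int(c) for c in m) for m in members})
    comps.sort(key=lambda s: (-len(s), min(s)))
    return comps


def border_layer(voxels: Iterable[Voxel], mask: np.ndarray) -> set[Voxel]:
    """One-voxel-wide layer of in-mask voxels 26-adjacent to, but outside, the set."""
    mask = np.asarray(mask, dtype=bool)
    ind = np.zeros(mask.shape, dtype=bool)
    vox = list(voxels)
    if not vox:
        return set()
    arr = np.asarray(vox, dtype=int)
    ind[arr[:, 0], arr[:, 1], arr[:, 2]] = True
    dil = ndimage.binary_dilation(ind, structure=STRUCT26)
    border = dil & ~ind & mask
    return {tuple(int(c) for c in v) for v in np.argwhere(border)}
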