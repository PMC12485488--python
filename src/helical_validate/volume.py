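"""MRC2014/CCP4 volume I/O and axis normalization.

Deposited EM maps declare, in header words 17–19 (MAPC/MAPR/MAPS), which
physical axis (1 = X, 2 = Y, 3 = Z) varies fastest/medium/slowest in the
file.  Most maps use the standard order (X fastest, Z slowest) but a
minority do not, and downstream helical analysis assumes the helical axis
is the slowest storage axis.  This module reads maps preserving the file
storage order, records the declared axis correspondence, and provides the
transpositions that bring a map to the canonical layout.

Conventions: voxel centers at 0-based indices; physical position =
origin + index × voxel_size; the helical axis passes through the grid
center (N/2 in each transverse axis).  Data are indexed ``[slow, mid,
fast]`` — ``[z, y, x]`` once standard.  NaN marks invalid voxels and is
zero-filled on write.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import gemmi
import numpy as np

__all__ = [
    "DensityMap",
    "MapFormatError",
    "read_map",
    "write_map",
    "normalize_axes",
    "orient_helical_axis",
]

_AXIS_LETTERS = ("X", "Y", "Z")
STANDARD_AXES_ORDER = ("X", "Y", "Z")  # fastest -> slowest


class MapFormatError(ValueError):
    """Raised for malformed or unsupported MRC/CCP4 files."""


@dataclass
class DensityMap:
    """A 3D density grid with physical metadata.

    Parameters
    ----------
    data:
        3D float array indexed ``[slow, mid, fast]`` in storage order.
    voxel_size:
        Isotropic sampling in Å per voxel.
    origin:
        Physical origin in Å, (x, y, z).  Informational; the helical axis
        is taken through the grid center, not the origin.
    axes_order:
        Physical axis letters in fastest → slowest storage order, e.g.
        ``("X", "Y", "Z")`` for a standard map.
    """

    data: np.ndarray
    voxel_size: float
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axes_order: tuple[str, str, str] = STANDARD_AXES_ORDER

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D grid, got ndim={self.data.ndim}")
        if min(self.data.shape) < 8:
            raise ValueError(f"all grid dimensions must be >= 8, got {self.data.shape}")
        if not self.voxel_size > 0:
            raise ValueError(f"voxel_size must be > 0 Å, got {self.voxel_size}")
        self.axes_order = tuple(str(a).upper() for a in self.axes_order)
        if sorted(self.axes_order) != sorted(_AXIS_LETTERS):
            raise ValueError(f"axes_order must permute X,Y,Z, got {self.axes_order}")

    @property
    def is_standard_order(self) -> bool:
        return self.axes_order == STANDARD_AXES_ORDER

    @property
    def axial_extent(self) -> float:
        """Physical length (Å) of the slowest (helical) axis."""
        return self.data.shape[0] * self.voxel_size

    def with_data(self, data: np.ndarray) -> "DensityMap":
        """Copy of this map with the grid replaced (same geometry)."""
        return replace(self, data=data)


def read_map(path: str | Path) -> DensityMap:
    """Read an MRC2014/CCP4 map (optionally gzip-compressed).

    The grid is returned in *file storage order* (slowest axis first) with
    ``axes_order`` populated from the MAPC/MAPR/MAPS header words; call
    :func:`normalize_axes` to obtain the canonical layout.  Only mode 0/1/2
    (integer and float32) data are supported; values are promoted to
    float32.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        ccp4 = gemmi.read_ccp4_map(str(path), setup=False)
    except (RuntimeError, ValueError) as exc:
        raise MapFormatError(f"not a valid MRC/CCP4 map: {path} ({exc})") from exc

    mode = ccp4.header_i32(4)
    if mode not in (0, 1, 2):
        raise MapFormatError(f"unsupported MRC data mode {mode} (only 0/1/2)")

    mapc, mapr, maps_ = (ccp4.header_i32(w) for w in (17, 18, 19))
    if sorted((mapc, mapr, maps_)) != [1, 2, 3]:
        raise MapFormatError(
            f"invalid axis correspondence MAPC/MAPR/MAPS = {(mapc, mapr, maps_)}"
        )
    axes_order = tuple(_AXIS_LETTERS[i - 1] for i in (mapc, mapr, maps_))

    # gemmi exposes the raw grid with the fastest (column) axis first;
    # transpose to storage order (slowest first).
    raw = np.asarray(ccp4.grid.array)
    data = np.ascontiguousarray(raw.transpose(2, 1, 0)).astype(np.float32, copy=False)

    # voxel size from the cell dimensions over the sampling counts (words
    # 8-10 MX/MY/MZ, words 11-13 CELLA); per-file axis i of the cell is
    # physical, independent of storage order.
    m_counts = [ccp4.header_i32(w) for w in (8, 9, 10)]
    cella = [ccp4.header_float(w) for w in (11, 12, 13)]
    spacings = [c / m for c, m in zip(cella, m_counts) if m > 0]
    if not spacings:
        raise MapFormatError("header declares zero sampling counts")
    if max(spacings) - min(spacings) > 1e-3 * max(spacings):
        raise MapFormatError(
            f"anisotropic voxel size {spacings} Å not supported; "
            "helical validation assumes one isotropic Å-per-voxel scale"
        )
    voxel = float(spacings[0])

    origin = tuple(float(ccp4.header_float(w)) for w in (50, 51, 52))
    return DensityMap(data=data, voxel_size=voxel, origin=origin, axes_order=axes_order)


def write_map(density_map: DensityMap, path: str | Path) -> None:
    """Write a map to a standard-conformant MRC2014 file (mode 2, float32).

    The map must be in standard axis order.  Invalid (NaN) voxels are
    written as zero.
    """
    if not density_map.is_standard_order:
        raise ValueError("write_map requires standard axis order; call normalize_axes")
    data = np.nan_to_num(density_map.data, nan=0.0).astype(np.float32)
    nz, ny, nx = data.shape
    grid = gemmi.FloatGrid(nx, ny, nz)
    # gemmi's grid buffer is fastest-axis-first
    grid.array[:] = np.ascontiguousarray(data.transpose(2, 1, 0))
    apix = density_map.voxel_size
    grid.set_unit_cell(gemmi.UnitCell(nx * apix, ny * apix, nz * apix, 90, 90, 90))
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = grid
    ccp4.update_ccp4_header()
    for w, v in zip((50, 51, 52), density_map.origin):
        ccp4.set_header_float(w, float(v))
    ccp4.write_ccp4_map(str(path))


def normalize_axes(density_map: DensityMap) -> DensityMap:
    """Transpose the grid to the standard storage order (X fastest, Z slowest).

    Voxel values and their physical positions are preserved; only the
    memory layout changes.  Identity when already standard.
    """
    if density_map.is_standard_order:
        return density_map
    # data axes are (slow, mid, fast); find where each target letter lives
    current = tuple(reversed(density_map.axes_order))  # letters of data axes 0,1,2
    perm = tuple(current.index(ax) for ax in ("Z", "Y", "X"))
    data = np.ascontiguousarray(np.transpose(density_map.data, perm))
    return replace(density_map, data=data, axes_order=STANDARD_AXES_ORDER)


def orient_helical_axis(density_map: DensityMap, axis: str) -> DensityMap:
    """Permute the grid so the named physical axis becomes the slowest axis.

    ``axis`` refers to the physical axis letter (X/Y/Z) as recorded in
    ``axes_order``.  After the call the helical axis is storage-slowest and
    ``axes_order`` tracks the relabelling, so repeating the call is a
    no-op.  Downstream code treats the slowest axis as the helical (z)
    axis regardless of its physical letter.
    """
    axis = str(axis).upper()
    if axis not in _AXIS_LETTERS:
        raise ValueError(f"axis must be one of X, Y, Z, got {axis!r}")
    labels = list(reversed(density_map.axes_order))  # letters of data axes 0,1,2
    pos = labels.index(axis)
    if pos == 0:
        return density_map
    perm = list(range(3))
    perm[0], perm[pos] = perm[pos], perm[0]
    data = np.ascontiguousarray(np.transpose(density_map.data, perm))
    new_labels = [labels[p] for p in perm]
    return replace(
        density_map, data=data, axes_order=tuple(reversed(new_labels))
    )
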