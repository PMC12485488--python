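"""The algebra of helical symmetry.

A helical assembly is generated from one asymmetric unit by a screw
operation — a rotation (*twist*, degrees) about the helical axis combined
with a translation (*rise*, Å) along it — optionally composed with an
n-fold rotational symmetry Cn about the same axis.

Sign convention
---------------
Positive twist means a right-handed helix when the helical axis points
toward increasing slice index: the i-th symmetry mate sits at azimuth
``i * twist`` (counterclockwise viewed from +z) and height ``i * rise``.
The convention is arbitrary but used consistently by the synthetic-map
generator, the symmetrizer and the indexer; only consistency matters for
validation, since map handedness itself is not adjudicated here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
from scipy import ndimage

if TYPE_CHECKING:  # pragma: no cover
    from .volume import DensityMap

__all__ = [
    "HelicalParams",
    "SymmetryTransform",
    "wrap_twist",
    "symmetry_transforms",
    "apply_transform",
    "n_fold",
    "swap",
    "flip_sign",
]


def wrap_twist(angle: float) -> float:
    """Wrap an angle in degrees into the interval (−180, 180].

    The result is congruent to ``angle`` modulo 360.  −180 maps to +180
    (the boundary belongs to the positive side).
    """
    if not math.isfinite(angle):
        raise ValueError(f"twist angle must be finite, got {angle}")
    w = math.fmod(angle, 360.0)
    if w > 180.0:
        w -= 360.0
    elif w <= -180.0:
        w += 360.0
    # fmod of exact multiples can yield -0.0; normalize for readability
    return w + 0.0


@dataclass(frozen=True)
class HelicalParams:
    """Helical symmetry parameters: twist (deg), rise (Å), axial Cn order.

    Twist is stored wrapped into (−180, 180].  Rise must be positive and
    csym a positive integer.
    """

    twist: float
    rise: float
    csym: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "twist", wrap_twist(float(self.twist)))
        object.__setattr__(self, "rise", float(self.rise))
        if self.rise <= 0:
            raise ValueError(f"rise must be > 0 Å, got {self.rise}")
        if int(self.csym) != self.csym or self.csym < 1:
            raise ValueError(f"csym must be an integer >= 1, got {self.csym}")
        object.__setattr__(self, "csym", int(self.csym))


@dataclass(frozen=True)
class SymmetryTransform:
    """One rigid symmetry operation: rotation about + translation along the axis."""

    rotation_deg: float
    translation: float  # Å

    def compose(self, other: "SymmetryTransform") -> "SymmetryTransform":
        return SymmetryTransform(
            math.fmod(self.rotation_deg + other.rotation_deg, 360.0),
            self.translation + other.translation,
        )


def symmetry_transforms(
    params: HelicalParams, axial_extent: float
) -> list[SymmetryTransform]:
    """Enumerate the screw-group elements whose translation fits a window.

    Returns transforms ``(i*twist + k*360/csym, i*rise)`` for all integer
    screw steps i (both signs) with ``|i*rise| <= axial_extent/2`` and
    k = 0..csym−1.  The identity is always included.
    """
    if axial_extent <= 0:
        raise ValueError("axial_extent must be positive")
    i_max = int(math.floor((axial_extent / 2.0) / params.rise))
    out = []
    for i in range(-i_max, i_max + 1):
        for k in range(params.csym):
            out.append(
                SymmetryTransform(
                    math.fmod(i * params.twist + k * (360.0 / params.csym), 360.0),
                    i * params.rise,
                )
            )
    return out


def apply_transform(density_map: "DensityMap", t: SymmetryTransform) -> "DensityMap":
    """Resample a map under one symmetry transform (trilinear interpolation).

    The map must be axis-canonical (helical axis = slowest storage axis,
    data indexed ``[z, y, x]``).  The rotation axis passes through the grid
    center ``(Nx/2, Ny/2)`` in voxel coordinates.  Voxels whose source
    location falls outside the grid become NaN (invalid) and are excluded
    from downstream averages; NaNs already present propagate.
    """
    data = density_map.data
    nz, ny, nx = data.shape
    apix = density_map.voxel_size

    if t.rotation_deg == 0.0 and t.translation == 0.0:
        return density_map.with_data(data.copy())

    theta = math.radians(t.rotation_deg)
    cos_t, sin_t = math.cos(theta), math.sin(theta)
    cy, cx = ny / 2.0, nx / 2.0
    dz = t.translation / apix

    z = np.arange(nz, dtype=np.float64)
    y = np.arange(ny, dtype=np.float64) - cy
    x = np.arange(nx, dtype=np.float64) - cx
    yy, xx = np.meshgrid(y, x, indexing="ij")
    # inverse rotation of the transverse coordinates
    src_x = cos_t * xx + sin_t * yy + cx
    src_y = -sin_t * xx + cos_t * yy + cy
    src_z = z - dz

    coords = np.empty((3, nz, ny, nx), dtype=np.float64)
    coords[0] = src_z[:, None, None]
    coords[1] = src_y[None, :, :]
    coords[2] = src_x[None, :, :]
    out = ndimage.map_coordinates(
        data.astype(np.float64, copy=False),
        coords.reshape(3, -1),
        order=1,
        mode="constant",
        cval=np.nan,
    ).reshape(data.shape)
    return density_map.with_data(out)


def n_fold(params: HelicalParams, n: int) -> HelicalParams:
    """The n-th power of the screw operation: (n·twist mod 360, n·rise).

    A reconstruction using (n·twist, n·rise) averages every n-th
    asymmetric unit only — a correct but *partial* use of the symmetry.
    """
    if int(n) != n or n < 1:
        raise ValueError(f"n must be an integer >= 1, got {n}")
    return HelicalParams(wrap_twist(n * params.twist), n * params.rise, params.csym)


def swap(params: HelicalParams) -> HelicalParams:
    """Exchange the numeric twist and rise values (models a deposition typo)."""
    if params.twist <= 0:
        raise ValueError(
            f"cannot swap: twist {params.twist} deg is not interpretable as a rise in Å"
        )
    return HelicalParams(params.rise, params.twist, params.csym)


def flip_sign(params: HelicalParams) -> HelicalParams:
    """Negate the twist sign (models the most common deposition error)."""
    return HelicalParams(wrap_twist(-params.twist), params.rise, params.csym)
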