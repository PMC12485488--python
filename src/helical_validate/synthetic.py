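"""Synthetic helical density maps with exactly known symmetry.

Real deposited maps cannot be bundled, so every stage of the validation
pipeline is exercised on maps built here: a small pseudo-atomic asymmetric
unit (a handful of 3D Gaussians given in cylindrical coordinates) is
replicated under an exact helical screw operation plus Cn symmetry, and
optionally split into a noisy half-map pair.

These fixtures reproduce the geometry of helical reconstructions — a
centered axis, a known lattice, tunable SNR — but not microscope physics
(no CTF, no solvent, no B-factor envelope); conclusions drawn from them
concern the symmetry analysis, not image formation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import HelicalParams, wrap_twist
from .volume import DensityMap

__all__ = [
    "PseudoAtom",
    "PseudoAtomModel",
    "default_model",
    "make_helical_map",
    "make_half_maps",
    "make_lattice_points",
    "amyloid_model",
]


@dataclass(frozen=True)
class PseudoAtom:
    """One Gaussian blob of the asymmetric unit, in cylindrical coordinates."""

    radius: float  # Å from the helical axis
    azimuth: float  # degrees
    height: float  # Å along the axis, relative to the unit's reference plane
    amplitude: float = 1.0
    sigma: float = 3.0  # Å, Gaussian width


@dataclass(frozen=True)
class PseudoAtomModel:
    """An asymmetric unit plus the grid it is rendered on."""

    atoms: tuple[PseudoAtom, ...]
    box_size: int = 64  # voxels per axis (cubic)
    voxel_size: float = 2.0  # Å

    def __post_init__(self) -> None:
        object.__setattr__(self, "atoms", tuple(self.atoms))
        half_width = self.box_size * self.voxel_size / 2.0
        for a in self.atoms:
            if a.radius >= half_width:
                raise ValueError(
                    f"atom radius {a.radius} Å exceeds box half-width {half_width} Å"
                )
            if a.sigma < self.voxel_size:
                raise ValueError(
                    f"gaussian sigma {a.sigma} Å below voxel size "
                    f"{self.voxel_size} Å would alias"
                )


def default_model(box_size: int = 64, voxel_size: float = 2.0) -> PseudoAtomModel:
    """Desk-scale fixture: three atoms at distinct radii/azimuths/heights.

    Distinct radii break spurious rotational symmetries of the asymmetric
    unit itself, so detected symmetry reflects the imposed helical lattice
    only.
    """
    scale = box_size * voxel_size / 128.0  # keep proportions across box sizes
    atoms = (
        PseudoAtom(radius=16.0 * scale, azimuth=0.0, height=0.0, amplitude=1.0, sigma=2.6),
        PseudoAtom(radius=22.0 * scale, azimuth=35.0, height=1.2, amplitude=0.8, sigma=3.0),
        PseudoAtom(radius=10.0 * scale, azimuth=150.0, height=-1.0, amplitude=0.9, sigma=2.6),
    )
    return PseudoAtomModel(atoms=atoms, box_size=box_size, voxel_size=voxel_size)


def amyloid_model(box_size: int = 64, voxel_size: float = 1.25) -> PseudoAtomModel:
    """Fixture emulating an amyloid fibril cross-section.

    Amyloid maps resolve the ~4.8 Å cross-β strand repeat, so the blobs
    must be sharp relative to the rise; the default fixture's wider
    Gaussians would smear consecutive rungs into continuous ridges.  A
    finer grid (1.25 Å/voxel) with tight σ ≈ 1.4 Å keeps the axial repeat
    visible, as in real sub-4 Å fibril reconstructions.
    """
    scale = box_size * voxel_size / 80.0
    atoms = (
        PseudoAtom(radius=26.0 * scale, azimuth=0.0, height=0.0, amplitude=1.0, sigma=1.4),
        PseudoAtom(radius=30.0 * scale, azimuth=12.0, height=0.6, amplitude=0.8, sigma=1.5),
        PseudoAtom(radius=20.0 * scale, azimuth=-20.0, height=-0.5, amplitude=0.9, sigma=1.4),
    )
    return PseudoAtomModel(atoms=atoms, box_size=box_size, voxel_size=voxel_size)


_TRUNCATE_SIGMAS = 4.0  # Gaussian support cutoff; <0.1% amplitude beyond


def make_helical_map(model: PseudoAtomModel, params: HelicalParams) -> DensityMap:
    """Render the full helical assembly implied by ``params``.

    Density is the sum of Gaussians at every helical-symmetry image of the
    asymmetric unit whose center falls inside (or within 4σ of) the box.
    The result is exactly invariant under the generating screw transform,
    up to interpolation/truncation error.
    """
    apix = model.voxel_size
    if params.rise < apix / 2.0:
        raise ValueError(
            f"rise {params.rise} Å below half the voxel size {apix} Å: "
            "the lattice cannot be resolved on this grid"
        )
    n = model.box_size
    grid = np.zeros((n, n, n), dtype=np.float64)
    center = n / 2.0  # voxel coords of the axis and of the axial midplane

    half_height = n * apix / 2.0
    margin = _TRUNCATE_SIGMAS * max(a.sigma for a in model.atoms)
    i_max = int(math.ceil((half_height + margin) / params.rise))

    zs = np.arange(n, dtype=np.float64)
    for i in range(-i_max, i_max + 1):
        for k in range(params.csym):
            phi_off = i * params.twist + k * 360.0 / params.csym
            z_off = i * params.rise
            for atom in model.atoms:
                phi = math.radians(atom.azimuth + phi_off)
                cx = center + atom.radius * math.cos(phi) / apix
                cy = center + atom.radius * math.sin(phi) / apix
                cz = center + (atom.height + z_off) / apix
                _add_gaussian(grid, cz, cy, cx, atom.amplitude, atom.sigma / apix)
    return DensityMap(
        data=grid.astype(np.float32), voxel_size=apix, axes_order=("X", "Y", "Z")
    )


def _add_gaussian(
    grid: np.ndarray, cz: float, cy: float, cx: float, amp: float, sigma_vox: float
) -> None:
    """Accumulate one truncated Gaussian into the grid in place."""
    n0, n1, n2 = grid.shape
    r = _TRUNCATE_SIGMAS * sigma_vox
    z0, z1 = max(0, int(cz - r)), min(n0, int(cz + r) + 2)
    y0, y1 = max(0, int(cy - r)), min(n1, int(cy + r) + 2)
    x0, x1 = max(0, int(cx - r)), min(n2, int(cx + r) + 2)
    if z0 >= z1 or y0 >= y1 or x0 >= x1:
        return
    dz = (np.arange(z0, z1) - cz) ** 2
    dy = (np.arange(y0, y1) - cy) ** 2
    dx = (np.arange(x0, x1) - cx) ** 2
    d2 = dz[:, None, None] + dy[None, :, None] + dx[None, None, :]
    grid[z0:z1, y0:y1, x0:x1] += amp * np.exp(-d2 / (2.0 * sigma_vox**2))


def make_half_maps(
    density_map: DensityMap, noise_sigma: float, seed: int
) -> tuple[DensityMap, DensityMap]:
    """Split a map into two half-maps with independent Gaussian noise.

    ``noise_sigma`` is expressed as a fraction of the map RMS (standard
    deviation about the mean), so SNR is comparable across fixtures.
    Deterministic given ``seed``; no global RNG state is touched.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    rng = np.random.default_rng(seed)
    data = density_map.data.astype(np.float64)
    scale = noise_sigma * float(np.nanstd(data))
    halves = []
    for _ in range(2):
        noise = rng.standard_normal(data.shape) * scale if scale > 0 else 0.0
        halves.append(density_map.with_data((data + noise).astype(np.float32)))
    return halves[0], halves[1]


def make_lattice_points(
    params: HelicalParams, radius: float, length: float
) -> list[tuple[float, float]]:
    """The 2D (azimuth, height) lattice obtained by unwrapping the helix.

    All symmetry images of a seed point at azimuth 0, height 0 with
    ``|height| <= length/2``: csym points per rise level, levels spaced by
    the rise.  ``radius`` fixes the cylinder being unwrapped (it does not
    change the angular coordinates; it is retained for arc-length
    conversions by callers).
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    i_max = int(math.floor((length / 2.0) / params.rise))
    points = []
    for i in range(-i_max, i_max + 1):
        for k in range(params.csym):
            points.append(
                (wrap_twist(i * params.twist + k * 360.0 / params.csym), i * params.rise)
            )
    return points
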