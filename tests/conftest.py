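"""Shared fixtures and an independent raw-MRC oracle for I/O cross-checks."""

from __future__ import annotations

import struct

import numpy as np
import pytest

from helical_validate import (
    HelicalParams,
    default_model,
    make_helical_map,
)

# ---------------------------------------------------------------------------
# Independent MRC2014 writer/reader built directly on struct/numpy, used to
# cross-check the gemmi-backed volume module.  Deliberately minimal and
# separate from the package code path.


def write_raw_mrc(
    path,
    data: np.ndarray,
    voxel_size: float = 1.0,
    mapc: int = 1,
    mapr: int = 2,
    maps: int = 3,
    mode: int = 2,
    cella: tuple[float, float, float] | None = None,
) -> None:
    """Write a minimal MRC2014 file; ``data`` is indexed [sections, rows, cols].

    ``mapc/mapr/maps`` declare which physical axis (1=X, 2=Y, 3=Z) the
    columns/rows/sections correspond to.
    """
    ns, nr, nc = data.shape
    dims_by_axis = {mapc: nc, mapr: nr, maps: ns}
    # tolerate deliberately invalid axis triples (for malformed-file tests)
    mx = dims_by_axis.get(1, nc)
    my = dims_by_axis.get(2, nr)
    mz = dims_by_axis.get(3, ns)
    if cella is None:
        cella = (mx * voxel_size, my * voxel_size, mz * voxel_size)
    header = bytearray(1024)
    struct.pack_into("<3i", header, 0, nc, nr, ns)
    struct.pack_into("<i", header, 12, mode)
    struct.pack_into("<3i", header, 16, 0, 0, 0)  # nstart
    struct.pack_into("<3i", header, 28, mx, my, mz)
    struct.pack_into("<3f", header, 40, *cella)
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)
    struct.pack_into("<3i", header, 64, mapc, mapr, maps)
    arr = np.ascontiguousarray(data, dtype=np.float32)
    struct.pack_into("<3f", header, 76, float(arr.min()), float(arr.max()), float(arr.mean()))
    struct.pack_into("<i", header, 88, 1)  # ISPG
    header[208:212] = b"MAP "
    header[212:216] = b"\x44\x44\x00\x00"  # little-endian machine stamp
    struct.pack_into("<f", header, 216, float(arr.std()))
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(arr.tobytes())


def read_raw_mrc(path) -> tuple[np.ndarray, float, tuple[int, int, int]]:
    """Parse an MRC file independently; returns (data[s,r,c], voxel, axes)."""
    with open(path, "rb") as fh:
        header = fh.read(1024)
        nc, nr, ns = struct.unpack_from("<3i", header, 0)
        (mode,) = struct.unpack_from("<i", header, 12)
        mx, my, mz = struct.unpack_from("<3i", header, 28)
        cella = struct.unpack_from("<3f", header, 40)
        mapc, mapr, maps = struct.unpack_from("<3i", header, 64)
        assert mode == 2, f"oracle only reads mode 2, got {mode}"
        data = np.frombuffer(fh.read(4 * nc * nr * ns), dtype="<f4").reshape(ns, nr, nc)
    return data, cella[0] / mx, (mapc, mapr, maps)


# ---------------------------------------------------------------------------
# Session-scoped synthetic maps (noiseless; reused read-only by many tests).


@pytest.fixture(scope="session")
def params_c1() -> HelicalParams:
    return HelicalParams(57.0, 12.0, 1)


@pytest.fixture(scope="session")
def helix_c1(params_c1):
    """Noiseless 64-cube C1 helix, twist 57 deg / rise 12 A."""
    return make_helical_map(default_model(), params_c1)


@pytest.fixture(scope="session")
def params_c3() -> HelicalParams:
    return HelicalParams(57.0, 12.0, 3)


@pytest.fixture(scope="session")
def helix_c3(params_c3):
    return make_helical_map(default_model(), params_c3)
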