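"""MRC/CCP4 density-map I/O with canonical axis ordering.

A cryo-EM map file stores a 3D array of density values in a box, but the
storage order of the three axes is a header choice (MAPC/MAPR/MAPS words).
``read_map`` always hands back a grid indexed ``[ix, iy, iz]`` along the
cell X/Y/Z axes regardless of file order, so every downstream metric can
ignore the permutation. MRC headers carry no resolution value; the reported
("map-side") resolution is supplied through a small JSON sidecar standing in
for repository-level metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

import gemmi

from .errors import NonsensicalBoxError, ParseFailureError

Cell = tuple[float, float, float, float, float, float]


@dataclass
class DensityMap:
    """Canonicalized density grid: ``grid[ix, iy, iz]`` runs along cell X/Y/Z."""

    grid: np.ndarray
    cell: Cell
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    axis_order_original: tuple[int, int, int] = (1, 2, 3)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float32)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.grid.ndim != 3:
            raise ValueError("density grid must be 3-dimensional")
        if any(c <= 0 for c in self.cell[:3]) or any(s <= 0 for s in self.grid.shape):
            raise NonsensicalBoxError(f"non-positive cell/grid: {self.cell} {self.grid.shape}")

    @property
    def n(self) -> tuple[int, int, int]:
        return self.grid.shape

    @property
    def voxel_size(self) -> np.ndarray:
        return np.array([self.cell[i] / self.grid.shape[i] for i in range(3)])

    @property
    def origin_grid(self) -> np.ndarray:
        """Origin expressed as (rounded) integer grid offsets."""
        return np.rint(self.origin / self.voxel_size).astype(int)

    def copy(self) -> "DensityMap":
        return DensityMap(self.grid.copy(), self.cell, self.origin.copy(), self.axis_order_original)

    def same_geometry(self, other: "DensityMap", cell_tol: float = 0.01) -> bool:
        return self.grid.shape == other.grid.shape and all(
            abs(a - b) <= cell_tol for a, b in zip(self.cell, other.cell)
        )


@dataclass
class MapMetadata:
    reported_resolutions: list[float] = field(default_factory=list)
    source: str = ""

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.reported_resolutions):
            raise ValueError("reported resolutions must be positive")


def read_sidecar(source: str | Path | dict | None) -> MapMetadata:
    """Load reported-resolution metadata from a JSON sidecar (or a dict)."""
    if source is None:
        return MapMetadata([], "none")
    if isinstance(source, dict):
        data, label = source, "dict"
    else:
        path = Path(source)
        with open(path) as fh:
            data = json.load(fh)
        label = str(path)
    values = data.get("reported_resolutions", [])
    if isinstance(values, (int, float)):
        values = [values]
    return MapMetadata([float(v) for v in values], label)


def write_sidecar(metadata: MapMetadata, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({"reported_resolutions": metadata.reported_resolutions}, fh, indent=1)


# -- reading -----------------------------------------------------------------


def read_map(
    path: str | Path, sidecar: str | Path | dict | None = None
) -> tuple[DensityMap, MapMetadata]:
    """Read an MRC/CCP4 map, canonicalize its axis order and attach metadata.

    The origin is taken from the ORIGIN header record; when that is all-zero
    the start indices (NC/NR/NS START) times the voxel size are used instead.
    Non-positive box dimensions raise :class:`NonsensicalBoxError`; a
    truncated or non-MRC file raises :class:`ParseFailureError`.
    """
    path = Path(path)
    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ParseFailureError(f"cannot parse map {path}: {exc}") from exc

    axis_order = tuple(m.header_i32(w) for w in (17, 18, 19))
    if sorted(axis_order) != [1, 2, 3]:
        raise ParseFailureError(f"{path}: invalid axis-order words {axis_order}")
    file_dims = [m.header_i32(w) for w in (1, 2, 3)]
    cell_lengths = [m.header_float(w) for w in (11, 12, 13)]
    if any(d <= 0 for d in file_dims) or any(c <= 0 for c in cell_lengths):
        raise NonsensicalBoxError(f"{path}: dimensions {file_dims}, cell {cell_lengths}")
    nstart_file = [m.header_i32(w) for w in (5, 6, 7)]
    origin_rec = np.array([m.header_float(w) for w in (50, 51, 52)])

    m.setup(0.0, gemmi.MapSetup.ReorderOnly)
    grid = np.array(m.grid, copy=True)
    uc = m.grid.unit_cell
    cell = (uc.a, uc.b, uc.c, uc.alpha, uc.beta, uc.gamma)

    voxel = np.array([cell[i] / grid.shape[i] for i in range(3)])
    if np.any(origin_rec != 0.0):
        origin = origin_rec
    else:
        # start indices are stored in file axis order; permute to X,Y,Z
        nstart_xyz = np.empty(3)
        for file_axis, cell_axis in enumerate(axis_order):
            nstart_xyz[cell_axis - 1] = nstart_file[file_axis]
        origin = nstart_xyz * voxel

    dmap = DensityMap(grid, cell, origin, tuple(axis_order))
    return dmap, read_sidecar(sidecar)


# -- writing -----------------------------------------------------------------


def write_map(
    dmap: DensityMap, path: str | Path, axis_order: tuple[int, int, int] = (1, 2, 3)
) -> None:
    """Write a map in MRC2014 format.

    ``axis_order`` gives the (1-based) cell axes stored fast/medium/slow,
    allowing permuted-order files to be produced for interoperability tests;
    the default writes X fastest.
    """
    if sorted(axis_order) != [1, 2, 3]:
        raise ValueError(f"axis_order must be a permutation of (1,2,3), got {axis_order}")
    perm = tuple(a - 1 for a in axis_order)
    data = np.ascontiguousarray(dmap.grid.transpose(perm))

    grid = gemmi.FloatGrid(*data.shape)
    np.array(grid, copy=False)[...] = data
    grid.set_unit_cell(gemmi.UnitCell(*dmap.cell))
    m = gemmi.Ccp4Map()
    m.grid = grid
    m.update_ccp4_header()
    # update_ccp4_header assumes canonical order; fix the permuted words
    for w, val in zip((17, 18, 19), axis_order):
        m.set_header_i32(w, val)
    for i in range(3):  # MX,MY,MZ and CELLA are in cell-axis order
        m.set_header_i32(8 + i, dmap.grid.shape[i])
        m.set_header_float(11 + i, dmap.cell[i])
        m.set_header_float(14 + i, dmap.cell[3 + i])
        m.set_header_float(50 + i, dmap.origin[i])
    m.write_ccp4_map(str(path))
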