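"""Subvolume lattice geometry for compartmentalised reaction-diffusion.

The simulation box (edge L, thickness h) is divided into cubic chambers of
edge l; molecules are well-mixed within a chamber and hop between
von-Neumann neighbours at rate D/l^2 per neighbour.  The standard
configuration is a single chamber layer (h = l) representing the interface
between plasma membrane and cytosol, where membrane and cytosolic species
co-reside and are distinguished only by their diffusion coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np


class Boundary(str, Enum):
    REFLECTING = "reflecting"
    PERIODIC = "periodic"


class GeometryError(ValueError):
    """Raised for non-commensurate or otherwise invalid lattice geometry."""


def _commensurate(total: float, unit: float) -> int:
    """Return total/unit as an integer, or raise if it is not one."""
    n = total / unit
    n_int = round(n)
    if n_int < 1 or abs(n - n_int) > 1e-6 * max(1.0, abs(n)):
        raise GeometryError(
            f"length {total} is not a positive integer multiple of chamber edge {unit}"
        )
    return n_int


@dataclass(frozen=True)
class LatticeGeometry:
    """Box and chamber dimensions, all in micrometres."""

    box_edge_um: float = 2.0
    box_thickness_um: float = 0.02
    chamber_edge_um: float = 0.02
    boundary: Boundary = Boundary.REFLECTING

    def __post_init__(self):
        if self.chamber_edge_um <= 0:
            raise GeometryError(f"chamber edge must be positive: {self.chamber_edge_um}")
        _commensurate(self.box_edge_um, self.chamber_edge_um)
        _commensurate(self.box_thickness_um, self.chamber_edge_um)

    @property
    def n_lateral(self) -> int:
        return _commensurate(self.box_edge_um, self.chamber_edge_um)

    @property
    def n_layers(self) -> int:
        return _commensurate(self.box_thickness_um, self.chamber_edge_um)

    @property
    def n_chambers(self) -> int:
        return self.n_lateral * self.n_lateral * self.n_layers


@dataclass
class Lattice:
    """Indexed chambers plus neighbour lists.

    Chamber ``(i, j, k)`` maps to flat index ``(i * ny + j) * nz + k``.
    ``neighbors`` is padded with -1; ``n_neighbors[c]`` gives the number of
    valid entries for chamber ``c``.
    """

    geometry: LatticeGeometry
    neighbors: np.ndarray = field(repr=False)  # (C, 6) int32, -1 padded
    n_neighbors: np.ndarray = field(repr=False)  # (C,) int32

    @property
    def n_chambers(self) -> int:
        return self.geometry.n_chambers

    @property
    def shape(self) -> tuple[int, int, int]:
        g = self.geometry
        return (g.n_lateral, g.n_lateral, g.n_layers)

    def flat_index(self, i: int, j: int, k: int = 0) -> int:
        nx, ny, nz = self.shape
        if not (0 <= i < nx and 0 <= j < ny and 0 <= k < nz):
            raise IndexError(f"chamber ({i}, {j}, {k}) outside lattice {self.shape}")
        return (i * ny + j) * nz + k

    def coords(self, c: int) -> tuple[int, int, int]:
        nx, ny, nz = self.shape
        k = c % nz
        j = (c // nz) % ny
        i = c // (nz * ny)
        return (i, j, k)


def diffusion_hop_rate(D_um2_s: float, chamber_edge_um: float) -> float:
    """Per-neighbour hop rate D/l^2 (1/s) for diffusion treated as a reaction."""
    if D_um2_s < 0:
        raise ValueError(f"negative diffusion coefficient: {D_um2_s}")
    if chamber_edge_um <= 0:
        raise ValueError(f"non-positive chamber edge: {chamber_edge_um}")
    return D_um2_s / chamber_edge_um**2


def build_lattice(geometry: LatticeGeometry) -> Lattice:
    """Construct the chamber index and neighbour lists for ``geometry``.

    Neighbour topology is von Neumann: 4 lateral neighbours per chamber
    plus the 2 vertical ones when the box is more than one layer thick.
    Reflecting boundaries simply omit the missing neighbour; periodic
    boundaries wrap around laterally (and vertically for thick boxes).
    """
    nx = geometry.n_lateral
    ny = geometry.n_lateral
    nz = geometry.n_layers
    C = nx * ny * nz
    periodic = geometry.boundary == Boundary.PERIODIC

    neighbors = np.full((C, 6), -1, dtype=np.int32)
    n_neighbors = np.zeros(C, dtype=np.int32)

    steps = [(-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0)]
    if nz > 1:
        steps += [(0, 0, -1), (0, 0, 1)]

    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                c = (i * ny + j) * nz + k
                m = 0
                for di, dj, dk in steps:
                    ii, jj, kk = i + di, j + dj, k + dk
                    if periodic:
                        ii, jj, kk = ii % nx, jj % ny, kk % nz
                    elif not (0 <= ii < nx and 0 <= jj < ny and 0 <= kk < nz):
                        continue
                    neighbors[c, m] = (ii * ny + jj) * nz + kk
                    m += 1
                n_neighbors[c] = m

    return Lattice(geometry=geometry, neighbors=neighbors, n_neighbors=n_neighbors)


def region_chambers(lattice: Lattice, edge_um: float, center_um: tuple[float, float] | None = None) -> np.ndarray:
    """Flat indices of the square chamber set of side ``edge_um`` at ``center_um``.

    The region's lower-left corner sits at floor((center - edge/2)/l)
    chambers, which is the documented deterministic tie-break when
    edge/l and box/l have opposite parity.  The region must be
    commensurate with the chamber edge and fit inside the box.
    """
    g = lattice.geometry
    l = g.chamber_edge_um
    n_edge = _commensurate(edge_um, l)
    nx, ny, nz = lattice.shape
    if center_um is None:
        center_um = (g.box_edge_um / 2.0, g.box_edge_um / 2.0)
    i0 = int(np.floor((center_um[0] - edge_um / 2.0) / l + 1e-9))
    j0 = int(np.floor((center_um[1] - edge_um / 2.0) / l + 1e-9))
    if i0 < 0 or j0 < 0 or i0 + n_edge > nx or j0 + n_edge > ny:
        raise GeometryError(
            f"region of edge {edge_um} um at center {center_um} exceeds the box"
        )
    out = []
    for i in range(i0, i0 + n_edge):
        for j in range(j0, j0 + n_edge):
            for k in range(nz):
                out.append((i * ny + j) * nz + k)
    return np.asarray(sorted(out), dtype=np.int64)
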