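"""Structured finite-volume grids: 3-D Cartesian, axisymmetric (r,z), and 1-D.

All grids are uniform and cell-centered.  Each grid exposes the geometric
quantities the finite-volume discretization needs: per-cell volumes, per-axis
interior-face transmissibility factors ``area / distance`` (so that a face
conductance is ``k_face * factor``), cell-center coordinate axes, and boundary
face factors for Dirichlet walls.

The Cartesian grid is the production geometry; the axisymmetric grid is an
exact (r,z) reduction for a single on-axis probe, and the 1-D grid exists for
planar-front verification against the Stefan similarity solution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SimulationGrid", "AxisymmetricGrid", "Grid1D"]


@dataclass(frozen=True)
class SimulationGrid:
    """Uniform cell-centered Cartesian grid (x, y, z), SI meters.

    ``origin`` is the minimum corner of the domain; cell centers sit at
    ``origin + (i + 1/2) * spacing``.
    """

    spacing: float
    shape: tuple[int, int, int]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if not self.spacing > 0:
            raise ValueError("spacing must be positive")
        if len(self.shape) != 3 or any(n < 3 for n in self.shape):
            raise ValueError("shape must have three axes with at least 3 cells each")

    @property
    def ndim(self) -> int:
        return 3

    @property
    def n_cells(self) -> int:
        return int(np.prod(self.shape))

    def axis_coords(self) -> list[np.ndarray]:
        """Cell-center coordinates along each axis."""
        return [
            self.origin[a] + (np.arange(self.shape[a]) + 0.5) * self.spacing
            for a in range(3)
        ]

    def cell_centers(self) -> np.ndarray:
        """(nx, ny, nz, 3) array of cell-center positions."""
        x, y, z = self.axis_coords()
        X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
        return np.stack([X, Y, Z], axis=-1)

    def cell_volumes(self) -> np.ndarray:
        return np.full(self.shape, self.spacing**3)

    def face_factor(self, axis: int) -> np.ndarray:
        """area/distance for interior faces normal to ``axis``."""
        fshape = list(self.shape)
        fshape[axis] -= 1
        return np.full(fshape, self.spacing)  # h^2 / h

    def boundary_face_factor(self, axis: int, side: int) -> np.ndarray:
        """area/(distance to wall) for the boundary faces on one side (half cell)."""
        fshape = list(self.shape)
        fshape[axis] = 1
        return np.full(fshape, 2.0 * self.spacing)  # h^2 / (h/2)

    def to_dict(self) -> dict:
        return {"kind": "cartesian", "spacing": self.spacing,
                "shape": list(self.shape), "origin": list(self.origin)}

    @staticmethod
    def centered(extent: tuple[float, float, float], spacing: float,
                 z_top: float = 0.0) -> "SimulationGrid":
        """Grid spanning ``extent`` (m) laterally centered on x=y=0, top at ``z_top``.

        Uses an odd cell count laterally so a cell center sits exactly on the
        array axis; probe lattices whose spacing is a multiple of the grid
        spacing then fall on cell centers, preserving discrete symmetry.
        """
        nx = int(round(extent[0] / spacing))
        ny = int(round(extent[1] / spacing))
        nz = int(round(extent[2] / spacing))
        nx += (nx + 1) % 2  # force odd
        ny += (ny + 1) % 2
        origin = (-nx * spacing / 2.0, -ny * spacing / 2.0, z_top - nz * spacing)
        return SimulationGrid(spacing=spacing, shape=(nx, ny, nz), origin=origin)


@dataclass(frozen=True)
class AxisymmetricGrid:
    """Uniform (r, z) grid for a rotationally symmetric single-probe problem.

    Axis 0 is radius (first cell center at ``spacing/2``), axis 1 is z with
    the domain top at ``z_top`` (the specimen surface).  Volumes and face
    areas carry the full 2*pi revolution, so energies are true 3-D energies.
    """

    spacing: float
    shape: tuple[int, int]  # (nr, nz)
    z_top: float = 0.0

    def __post_init__(self) -> None:
        if not self.spacing > 0:
            raise ValueError("spacing must be positive")
        if len(self.shape) != 2 or any(n < 3 for n in self.shape):
            raise ValueError("shape must be (nr, nz) with at least 3 cells each")

    @property
    def ndim(self) -> int:
        return 2

    @property
    def n_cells(self) -> int:
        return int(np.prod(self.shape))

    @property
    def origin(self) -> tuple[float, float]:
        return (0.0, self.z_top - self.shape[1] * self.spacing)

    def axis_coords(self) -> list[np.ndarray]:
        r = (np.arange(self.shape[0]) + 0.5) * self.spacing
        z = self.origin[1] + (np.arange(self.shape[1]) + 0.5) * self.spacing
        return [r, z]

    def cell_volumes(self) -> np.ndarray:
        r, _ = self.axis_coords()
        vol_r = 2.0 * np.pi * r * self.spacing**2
        return np.broadcast_to(vol_r[:, None], self.shape).copy()

    def face_factor(self, axis: int) -> np.ndarray:
        h = self.spacing
        nr, nz = self.shape
        if axis == 0:  # radial faces at r = i*h, i = 1..nr-1
            r_face = np.arange(1, nr) * h
            area = 2.0 * np.pi * r_face * h
            return np.broadcast_to((area / h)[:, None], (nr - 1, nz)).copy()
        r, _ = self.axis_coords()
        area = 2.0 * np.pi * r * h
        return np.broadcast_to((area / h)[:, None], (nr, nz - 1)).copy()

    def boundary_face_factor(self, axis: int, side: int) -> np.ndarray:
        h = self.spacing
        nr, nz = self.shape
        if axis == 0:
            r_face = 0.0 if side == 0 else nr * h
            area = 2.0 * np.pi * r_face * h
            return np.full((1, nz), area / (h / 2.0))
        r, _ = self.axis_coords()
        area = 2.0 * np.pi * r * h
        return (area / (h / 2.0))[:, None].copy()

    def to_dict(self) -> dict:
        return {"kind": "axisymmetric", "spacing": self.spacing,
                "shape": list(self.shape), "z_top": self.z_top}


@dataclass(frozen=True)
class Grid1D:
    """Uniform 1-D grid with unit cross-section, for planar-front verification."""

    spacing: float
    n: int
    origin: float = 0.0

    def __post_init__(self) -> None:
        if not self.spacing > 0:
            raise ValueError("spacing must be positive")
        if self.n < 3:
            raise ValueError("need at least 3 cells")

    @property
    def ndim(self) -> int:
        return 1

    @property
    def shape(self) -> tuple[int]:
        return (self.n,)

    @property
    def n_cells(self) -> int:
        return self.n

    def axis_coords(self) -> list[np.ndarray]:
        return [self.origin + (np.arange(self.n) + 0.5) * self.spacing]

    def cell_volumes(self) -> np.ndarray:
        return np.full(self.n, self.spacing)

    def face_factor(self, axis: int) -> np.ndarray:
        return np.full(self.n - 1, 1.0 / self.spacing)

    def boundary_face_factor(self, axis: int, side: int) -> np.ndarray:
        return np.full(1, 2.0 / self.spacing)

    def to_dict(self) -> dict:
        return {"kind": "1d", "spacing": self.spacing, "n": self.n, "origin": self.origin}
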