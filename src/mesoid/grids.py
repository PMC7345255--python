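"""Structured grids and grid-sampled fields.

A :class:`StructuredGrid` is a regular quadrilateral (2D) or hexahedral (3D)
mesh with lower-corner origin and lexicographic node numbering (x fastest).
Displacement fields live at nodes; strain and elasticity fields are
piecewise constant per element, strains stored as Kelvin vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["StructuredGrid", "DisplacementField", "StrainField"]


@dataclass(frozen=True)
class StructuredGrid:
    """Regular Q4/H8 grid.

    Parameters
    ----------
    n_elems : tuple of int
        Number of elements along each axis (length 2 or 3).
    h : tuple of float
        Element size along each axis, meters.
    origin : tuple of float
        Coordinates of the lower corner, meters.
    """

    n_elems: tuple[int, ...]
    h: tuple[float, ...]
    origin: tuple[float, ...] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        object.__setattr__(self, "n_elems", tuple(int(n) for n in self.n_elems))
        object.__setattr__(self, "h", tuple(float(x) for x in self.h))
        if self.origin is None:
            object.__setattr__(self, "origin", (0.0,) * len(self.n_elems))
        else:
            object.__setattr__(self, "origin", tuple(float(x) for x in self.origin))
        if len(self.h) != self.dim or len(self.origin) != self.dim:
            raise ValueError("n_elems, h and origin must have equal length")
        if any(n < 1 for n in self.n_elems) or any(x <= 0 for x in self.h):
            raise ValueError("grid must have >=1 element and positive spacing")

    @property
    def dim(self) -> int:
        return len(self.n_elems)

    @property
    def n_nodes_axis(self) -> tuple[int, ...]:
        return tuple(n + 1 for n in self.n_elems)

    @property
    def n_nodes(self) -> int:
        return int(np.prod(self.n_nodes_axis))

    @property
    def n_cells(self) -> int:
        return int(np.prod(self.n_elems))

    @property
    def extent(self) -> tuple[float, ...]:
        return tuple(n * hx for n, hx in zip(self.n_elems, self.h))

    @property
    def cell_volume(self) -> float:
        return float(np.prod(self.h))

    def node_coords(self) -> np.ndarray:
        """(n_nodes, dim) array of node coordinates, x fastest."""
        axes = [self.origin[a] + self.h[a] * np.arange(self.n_nodes_axis[a])
                for a in range(self.dim)]
        mesh = np.meshgrid(*axes, indexing="ij")
        # lexicographic with x fastest == Fortran order over (ix, iy, iz)
        return np.stack([m.ravel(order="F") for m in mesh], axis=1)

    def cell_centroids(self) -> np.ndarray:
        axes = [self.origin[a] + self.h[a] * (np.arange(self.n_elems[a]) + 0.5)
                for a in range(self.dim)]
        mesh = np.meshgrid(*axes, indexing="ij")
        return np.stack([m.ravel(order="F") for m in mesh], axis=1)

    def node_index(self, ijk: np.ndarray) -> np.ndarray:
        """Multi-index (..., dim) -> flat node id."""
        ijk = np.asarray(ijk)
        nn = self.n_nodes_axis
        idx = ijk[..., 0]
        stride = 1
        for a in range(1, self.dim):
            stride *= nn[a - 1]
            idx = idx + stride * ijk[..., a]
        return idx

    def boundary_node_ids(self) -> np.ndarray:
        """Flat ids of all nodes on the grid boundary."""
        nn = self.n_nodes_axis
        grids = np.meshgrid(*[np.arange(n) for n in nn], indexing="ij")
        ijk = np.stack([g.ravel(order="F") for g in grids], axis=1)
        on_bnd = np.zeros(len(ijk), dtype=bool)
        for a in range(self.dim):
            on_bnd |= (ijk[:, a] == 0) | (ijk[:, a] == nn[a] - 1)
        return np.nonzero(on_bnd)[0]

    def face_node_ids(self, axis: int, side: int) -> np.ndarray:
        """Node ids on the face normal to ``axis`` (0-based) at ``side``
        (0 = low, 1 = high)."""
        nn = self.n_nodes_axis
        sel = [np.arange(n) for n in nn]
        sel[axis] = np.array([0 if side == 0 else nn[axis] - 1])
        grids = np.meshgrid(*sel, indexing="ij")
        ijk = np.stack([g.ravel(order="F") for g in grids], axis=1)
        return self.node_index(ijk)

    def element_nodes(self) -> np.ndarray:
        """(n_cells, 4 or 8) connectivity, standard counterclockwise local
        ordering."""
        ne = self.n_elems
        nn = self.n_nodes_axis
        if self.dim == 2:
            i, j = np.meshgrid(np.arange(ne[0]), np.arange(ne[1]), indexing="ij")
            i = i.ravel(order="F")
            j = j.ravel(order="F")
            n0 = i + nn[0] * j
            return np.stack([n0, n0 + 1, n0 + 1 + nn[0], n0 + nn[0]], axis=1)
        i, j, k = np.meshgrid(*[np.arange(n) for n in ne], indexing="ij")
        i = i.ravel(order="F")
        j = j.ravel(order="F")
        k = k.ravel(order="F")
        n0 = i + nn[0] * (j + nn[1] * k)
        dz = nn[0] * nn[1]
        bot = [n0, n0 + 1, n0 + 1 + nn[0], n0 + nn[0]]
        return np.stack(bot + [b + dz for b in bot], axis=1)


@dataclass
class DisplacementField:
    """Nodal displacement vectors, shape (n_nodes, dim), meters."""

    grid: StructuredGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_nodes, self.grid.dim):
            raise ValueError(
                f"displacement shape {self.values.shape} does not match grid "
                f"({self.grid.n_nodes} nodes x {self.grid.dim})"
            )

    def flat(self) -> np.ndarray:
        return self.values.ravel()


@dataclass
class StrainField:
    """Element-centroid strains as Kelvin vectors, shape (n_cells, n_strain)
    with n_strain = 3 (2D) or 6 (3D), dimensionless."""

    grid: StructuredGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        nstr = 3 if self.grid.dim == 2 else 6
        if self.values.shape != (self.grid.n_cells, nstr):
            raise ValueError(
                f"strain shape {self.values.shape} does not match grid "
                f"({self.grid.n_cells} cells x {nstr})"
            )

    def spatial_mean(self) -> np.ndarray:
        """Cell-measure-weighted spatial average (uniform cells: plain mean)."""
        return self.values.mean(axis=0)
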