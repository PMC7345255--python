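"""Displacement-based FEM on structured Q4/H8 grids.

Solves the deterministic macroscale boundary value problem (clamped face +
traction face, homogeneous elasticity) and the per-realization mesoscale
Dirichlet problem (displacement prescribed on the whole boundary,
heterogeneous piecewise-constant elasticity).  Bilinear/trilinear elements
with full Gauss-Legendre quadrature; strains are evaluated at element
centroids, which for rectangular elements coincide with the element average
of the strain field and make the indicator quadratures exact for
piecewise-constant strains.

All constitutive matrices are Kelvin-form (see :mod:`mesoid.elasticity`), so
strain vectors carry a sqrt(2) factor on the shear components.  Stiffness is
passed in GPa (the package-wide modulus unit) and converted to Pa
internally, so tractions in N/m^2 and lengths in meters yield displacements
in meters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .grids import DisplacementField, StrainField, StructuredGrid

__all__ = [
    "LoadCase",
    "solve_macro",
    "solve_meso",
    "strain_from_displacement",
    "assemble_stiffness",
    "compression_load",
]

_SQRT2 = np.sqrt(2.0)

GPA = 1e9  # moduli are carried in GPa; assembly converts to Pa


@dataclass
class LoadCase:
    """Boundary conditions of a macroscale solve.

    ``neumann`` maps (axis, side) faces to a constant traction vector [N/m^2];
    ``dirichlet_nodes`` / ``dirichlet_values`` prescribe displacements
    (values broadcastable to (n_nodes_fixed, dim)).
    """

    neumann: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)
    dirichlet_nodes: np.ndarray = None  # type: ignore[assignment]
    dirichlet_values: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.dirichlet_nodes is None or len(self.dirichlet_nodes) == 0:
            raise ValueError("macro load case needs a non-empty Dirichlet set")
        self.dirichlet_nodes = np.asarray(self.dirichlet_nodes, dtype=int)


def compression_load(grid: StructuredGrid, traction: float) -> LoadCase:
    """Uniaxial compression test: bottom face clamped, uniform traction of
    magnitude ``traction`` [N/m^2] pushing down on the top face (loading along
    -x2 in 2D, -x3 in 3D)."""
    axis = grid.dim - 1
    t = np.zeros(grid.dim)
    t[axis] = -abs(traction)
    clamped = grid.face_node_ids(axis, 0)
    return LoadCase(
        neumann={(axis, 1): t},
        dirichlet_nodes=clamped,
        dirichlet_values=np.zeros((len(clamped), grid.dim)),
    )


# ---------------------------------------------------------------------------
# element matrices


def _gauss_1d() -> tuple[np.ndarray, np.ndarray]:
    g = 1.0 / np.sqrt(3.0)
    return np.array([-g, g]), np.array([1.0, 1.0])


def _local_corners(dim: int) -> np.ndarray:
    if dim == 2:
        return np.array([[-1, -1], [1, -1], [1, 1], [-1, 1]], dtype=float)
    bot = np.array([[-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1]], dtype=float)
    top = bot.copy()
    top[:, 2] = 1
    return np.vstack([bot, top])


def shape_gradients(dim: int, xi: np.ndarray, h: tuple[float, ...]) -> np.ndarray:
    """Physical gradients dN_a/dx_b at a local point ``xi``; (n_en, dim)."""
    corners = _local_corners(dim)
    n_en = len(corners)
    grad = np.empty((n_en, dim))
    for a in range(n_en):
        for b in range(dim):
            val = corners[a, b] / 2.0 ** dim
            for c in range(dim):
                if c != b:
                    val *= 1.0 + corners[a, c] * xi[c]
            grad[a, b] = val * 2.0 / h[b]  # d(xi)/dx = 2/h
    return grad


def _b_matrix(dim: int, grad: np.ndarray) -> np.ndarray:
    """Kelvin strain-displacement matrix (n_strain, n_en*dim)."""
    n_en = grad.shape[0]
    if dim == 2:
        b = np.zeros((3, 2 * n_en))
        for a in range(n_en):
            b[0, 2 * a] = grad[a, 0]
            b[1, 2 * a + 1] = grad[a, 1]
            b[2, 2 * a] = grad[a, 1] / _SQRT2
            b[2, 2 * a + 1] = grad[a, 0] / _SQRT2
        return b
    b = np.zeros((6, 3 * n_en))
    for a in range(n_en):
        ax = 3 * a
        b[0, ax] = grad[a, 0]
        b[1, ax + 1] = grad[a, 1]
        b[2, ax + 2] = grad[a, 2]
        b[3, ax + 1] = grad[a, 2] / _SQRT2  # sqrt(2)*eps23
        b[3, ax + 2] = grad[a, 1] / _SQRT2
        b[4, ax] = grad[a, 2] / _SQRT2  # sqrt(2)*eps13
        b[4, ax + 2] = grad[a, 0] / _SQRT2
        b[5, ax] = grad[a, 1] / _SQRT2  # sqrt(2)*eps12
        b[5, ax + 1] = grad[a, 0] / _SQRT2
    return b


def _gauss_b_matrices(grid: StructuredGrid) -> tuple[list[np.ndarray], float]:
    """B matrices at the full Gauss rule and the per-point measure w*|J|."""
    dim = grid.dim
    pts, _ = _gauss_1d()
    coords = np.meshgrid(*([pts] * dim), indexing="ij")
    gauss = np.stack([c.ravel() for c in coords], axis=1)
    det_j_w = grid.cell_volume / 2.0 ** dim  # |J| * unit weight
    return [_b_matrix(dim, shape_gradients(dim, xi, grid.h)) for xi in gauss], det_j_w


def centroid_b_matrix(grid: StructuredGrid) -> np.ndarray:
    return _b_matrix(grid.dim, shape_gradients(grid.dim, np.zeros(grid.dim), grid.h))


def element_dof_map(grid: StructuredGrid) -> np.ndarray:
    """(n_cells, n_en*dim) global dof indices per element."""
    conn = grid.element_nodes()
    dim = grid.dim
    dofs = (conn[:, :, None] * dim + np.arange(dim)[None, None, :])
    return dofs.reshape(conn.shape[0], -1)


def assemble_stiffness(grid: StructuredGrid, c_cells: np.ndarray) -> sp.csr_matrix:
    """Global stiffness for per-element Kelvin matrices ``c_cells`` [GPa] of
    shape (n_cells, n_strain, n_strain) or a single (n_strain, n_strain)
    matrix."""
    b_mats, djw = _gauss_b_matrices(grid)
    c_cells = np.asarray(c_cells, dtype=float) * GPA
    homogeneous = c_cells.ndim == 2
    if homogeneous:
        ke = djw * sum(b.T @ c_cells @ b for b in b_mats)
        ke_all = np.broadcast_to(ke, (grid.n_cells, *ke.shape))
    else:
        if c_cells.shape[0] != grid.n_cells:
            raise ValueError("one constitutive matrix per cell required")
        ke_all = np.zeros((grid.n_cells, b_mats[0].shape[1], b_mats[0].shape[1]))
        for b in b_mats:
            ke_all += djw * np.einsum("sa,est,tb->eab", b, c_cells, b,
                                      optimize=True)
    dofs = element_dof_map(grid)
    nde = dofs.shape[1]
    rows = np.repeat(dofs, nde, axis=1).ravel()
    cols = np.tile(dofs, (1, nde)).ravel()
    ndof = grid.n_nodes * grid.dim
    k = sp.coo_matrix((ke_all.ravel(), (rows, cols)), shape=(ndof, ndof))
    return k.tocsr()


def neumann_load_vector(grid: StructuredGrid,
                        neumann: dict[tuple[int, int], np.ndarray]) -> np.ndarray:
    """Consistent nodal forces for constant tractions on grid faces.

    For bilinear faces and a uniform traction the consistent load is the
    tributary-area rule: interior face nodes carry t*A_face-share; edge and
    corner nodes carry half/quarter shares.
    """
    dim = grid.dim
    f = np.zeros((grid.n_nodes, dim))
    for (axis, side), t in neumann.items():
        t = np.asarray(t, dtype=float)
        other = [a for a in range(dim) if a != axis]
        # tributary weights along each in-face axis: (1/2, 1, ..., 1, 1/2)*h
        weights = []
        for a in other:
            w = np.full(grid.n_nodes_axis[a], grid.h[a])
            w[0] *= 0.5
            w[-1] *= 0.5
            weights.append(w)
        if dim == 2:
            area = weights[0]
        else:
            area = np.outer(weights[0], weights[1]).ravel(order="F")
        nodes = grid.face_node_ids(axis, side)
        f[nodes] += area[:, None] * t[None, :]
    return f.ravel()


class ConstrainedSystem:
    """Reduced linear system for a fixed Dirichlet dof set; the sparse
    factorization is computed once and reused across right-hand sides."""

    def __init__(self, k: sp.csr_matrix, fixed_dofs: np.ndarray):
        ndof = k.shape[0]
        self.fixed = np.asarray(fixed_dofs, dtype=int)
        self.free = np.setdiff1d(np.arange(ndof), self.fixed)
        self.k_fc = k[self.free][:, self.fixed]
        self.k_ff = k[self.free][:, self.free].tocsc()
        try:
            self._lu = spla.splu(self.k_ff)
        except RuntimeError as exc:  # singular factorization
            raise RuntimeError(
                "singular stiffness system: the Dirichlet set does not "
                "remove all rigid modes (factorization failed)"
            ) from exc
        self.ndof = ndof

    def solve(self, f: np.ndarray, fixed_vals: np.ndarray) -> np.ndarray:
        u = np.zeros(self.ndof)
        u[self.fixed] = fixed_vals
        rhs = f[self.free] - self.k_fc @ fixed_vals
        x = self._lu.solve(rhs)
        # a rank-deficient matrix can slip through the factorization with a
        # tiny pivot; a residual check catches the remaining rigid mode
        res = np.linalg.norm(self.k_ff @ x - rhs)
        ref = np.linalg.norm(rhs)
        if not np.all(np.isfinite(x)) or (ref > 0 and res > 1e-6 * ref):
            raise RuntimeError(
                "singular stiffness system: the Dirichlet set does not "
                "remove all rigid modes (translation/rotation unconstrained)")
        u[self.free] = x
        return u


def _solve_constrained(k: sp.csr_matrix, f: np.ndarray,
                       fixed_dofs: np.ndarray,
                       fixed_vals: np.ndarray) -> np.ndarray:
    return ConstrainedSystem(k, fixed_dofs).solve(f, fixed_vals)


def _dirichlet_dofs(grid: StructuredGrid, nodes: np.ndarray,
                    values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    dim = grid.dim
    values = np.broadcast_to(np.asarray(values, dtype=float),
                             (len(nodes), dim))
    dofs = (nodes[:, None] * dim + np.arange(dim)[None, :]).ravel()
    return dofs, values.ravel()


def solve_macro(grid: StructuredGrid, c: "np.ndarray | object",
                load: LoadCase) -> tuple[DisplacementField, StrainField]:
    """Solve the homogeneous macroscale problem; returns nodal displacements
    and centroid strains.  ``c`` is a Kelvin stiffness matrix (3x3 plane
    stress or 6x6) or an :class:`~mesoid.elasticity.ElasticTensor`."""
    c_mat = getattr(c, "kelvin", c)
    k = assemble_stiffness(grid, c_mat)
    f = neumann_load_vector(grid, load.neumann)
    fixed, vals = _dirichlet_dofs(grid, load.dirichlet_nodes,
                                  load.dirichlet_values)
    u = _solve_constrained(k, f, fixed, vals)
    disp = DisplacementField(grid, u.reshape(-1, grid.dim))
    return disp, strain_from_displacement(grid, disp)


def solve_meso(grid: StructuredGrid, c_cells: np.ndarray,
               u_boundary: DisplacementField) -> StrainField:
    """Solve the mesoscale Dirichlet problem for one realization.

    ``c_cells``: per-element Kelvin *stiffness* matrices (compliance-stored
    fields are inverted by the caller).  ``u_boundary`` supplies the
    prescribed displacement on every boundary node (interior values of the
    field, if any, are ignored).
    """
    k = assemble_stiffness(grid, c_cells)
    bnd = grid.boundary_node_ids()
    vals = u_boundary.values[bnd]
    if not np.all(np.isfinite(vals)):
        raise ValueError("boundary displacement contains non-finite values")
    fixed, fvals = _dirichlet_dofs(grid, bnd, vals)
    u = _solve_constrained(k, np.zeros(k.shape[0]), fixed, fvals)
    return strain_from_displacement(grid, DisplacementField(grid, u.reshape(-1, grid.dim)))


def strain_from_displacement(grid: StructuredGrid,
                             u: DisplacementField) -> StrainField:
    """Element-centroid symmetric gradient (Kelvin vector per cell)."""
    b_c = centroid_b_matrix(grid)
    dofs = element_dof_map(grid)
    ue = u.flat()[dofs]  # (n_cells, nde)
    return StrainField(grid, ue @ b_c.T)
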