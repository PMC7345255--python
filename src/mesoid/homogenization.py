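"""Stochastic homogenization with static uniform boundary conditions (SUBC).

The effective compliance of a field realization over an RVE is obtained by
applying the traction boundary condition sigma.n = sigma0.n on the RVE
boundary for each Kelvin unit macroscopic stress state sigma0, averaging the
strain, and reading off <eps> = S_eff : sigma0.  Rigid modes of the pure
traction problem are removed by a minimal pinning set; the volume-average
strain is invariant to that choice.  The Monte-Carlo mean E{C_eff} is the
mean of per-realization stiffness inverses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .elasticity import ElasticTensor
from .fem import GPA, assemble_stiffness, neumann_load_vector, \
    strain_from_displacement
from .grids import DisplacementField, StructuredGrid
from .random_field import FieldRealization, FieldSpec, SfePlusSampler, \
    empirical_dispersion

__all__ = ["RveConfig", "EffectiveStats", "effective_compliance_subc",
           "mc_effective_mean", "stiffness_cells", "rve_grid"]

_SQRT2 = np.sqrt(2.0)


@dataclass
class RveConfig:
    """RVE sizing rule: side length = ``multiplier`` x correlation length,
    meshed with ``cells_per_ell`` elements per correlation length."""

    multiplier: float = 20.0
    cells_per_ell: int = 4

    def __post_init__(self) -> None:
        if self.multiplier <= 0 or self.cells_per_ell < 2:
            raise ValueError("RVE needs positive size and >=2 cells per ell")


def rve_grid(ell: float, dim: int, cfg: RveConfig) -> StructuredGrid:
    h = ell / cfg.cells_per_ell
    n = max(int(round(cfg.multiplier * cfg.cells_per_ell)), 2)
    return StructuredGrid((n,) * dim, (h,) * dim)


def stiffness_cells(realization: FieldRealization, dim: int) -> np.ndarray:
    """Per-element Kelvin stiffness matrices for a BVP of dimension ``dim``.

    A 6x6 compliance field on a 2D grid is reduced to its in-plane 3x3
    sub-block before inversion (plane-stress pipeline); stiffness fields are
    used as stored.
    """
    vals = realization.values
    n = vals.shape[-1]
    if realization.kind == "compliance":
        if dim == 2 and n == 6:
            from .elasticity import reduce_kelvin_matrices

            vals = reduce_kelvin_matrices(vals)
        return np.linalg.inv(vals)
    if dim == 2 and n == 6:
        raise ValueError("cannot reduce a 3D stiffness field to plane stress; "
                         "store compliance instead")
    return vals


def _kelvin_unit_stress(dim: int, k: int) -> np.ndarray:
    """k-th Kelvin basis stress state as a dim x dim tensor."""
    if dim == 2:
        pairs = [(0, 0), (1, 1), (0, 1)]
    else:
        pairs = [(0, 0), (1, 1), (2, 2), (1, 2), (0, 2), (0, 1)]
    i, j = pairs[k]
    s = np.zeros((dim, dim))
    if i == j:
        s[i, i] = 1.0
    else:
        s[i, j] = s[j, i] = 1.0 / _SQRT2
    return s


def _pin_dofs(grid: StructuredGrid) -> np.ndarray:
    """Minimal rigid-mode pinning for pure traction problems."""
    dim = grid.dim
    nn = grid.n_nodes_axis
    if dim == 2:
        n_a = 0
        n_b = nn[0] - 1  # (nx, 0)
        return np.array([n_a * 2, n_a * 2 + 1, n_b * 2 + 1])
    n_a = 0
    n_b = nn[0] - 1                      # (nx, 0, 0)
    n_c = nn[0] * (nn[1] - 1)            # (0, ny, 0)
    return np.array([n_a * 3, n_a * 3 + 1, n_a * 3 + 2,
                     n_b * 3 + 1, n_b * 3 + 2, n_c * 3 + 2])


def effective_compliance_subc(realization: FieldRealization) -> ElasticTensor:
    """SUBC effective compliance of one realization (Kelvin form, plane2d for
    2D grids, full3d for 3D grids)."""
    grid = realization.grid
    dim = grid.dim
    nstr = 3 if dim == 2 else 6
    c_cells = stiffness_cells(realization, dim)
    k = assemble_stiffness(grid, c_cells)
    pins = _pin_dofs(grid)
    from .fem import ConstrainedSystem

    system = ConstrainedSystem(k, pins)
    s_eff = np.empty((nstr, nstr))
    zeros = np.zeros(len(pins))
    for col in range(nstr):
        sig = _kelvin_unit_stress(dim, col)
        neumann = {}
        for axis in range(dim):
            for side, sgn in ((0, -1.0), (1, 1.0)):
                neumann[(axis, side)] = sgn * sig[:, axis]
        f = neumann_load_vector(grid, neumann)
        u = system.solve(f, zeros)
        eps = strain_from_displacement(
            grid, DisplacementField(grid, u.reshape(-1, dim)))
        s_eff[:, col] = eps.spatial_mean()
    s_eff = 0.5 * (s_eff + s_eff.T) * GPA  # unit tractions in Pa -> 1/GPa
    if np.linalg.eigvalsh(s_eff).min() <= 0:
        raise ValueError("effective compliance is not SPD: field is likely "
                         "under-resolved on the RVE grid")
    form = "plane2d" if dim == 2 else "full3d"
    return ElasticTensor(s_eff, kind="compliance", form=form, _validate=False)


@dataclass
class EffectiveStats:
    """Monte-Carlo summary of the effective stiffness."""

    mean: ElasticTensor
    dispersion: float
    stderr: float
    ns: int


def mc_effective_mean(spec: FieldSpec, rve: "RveConfig | StructuredGrid",
                      ns: int, dim: int = None,  # type: ignore[assignment]
                      base_seed: "int | None" = None) -> EffectiveStats:
    """Monte-Carlo mean of C_eff = inverse(S_eff) over ``ns`` realizations,
    with the empirical dispersion coefficient of C_eff and the standard error
    of the mean (Frobenius-relative)."""
    if ns < 1:
        raise ValueError("ns >= 1 required")
    if isinstance(rve, StructuredGrid):
        grid = rve
    else:
        if dim is None:
            raise ValueError("dim required when passing an RveConfig")
        finite = [l for l in spec.ell if np.isfinite(l)]
        grid = rve_grid(min(finite), dim, rve)
    sampler = SfePlusSampler(spec, grid, warn=False)
    c_effs = np.empty((ns, *((3, 3) if grid.dim == 2 else (6, 6))))
    for r in range(ns):
        real = sampler.sample(r, base_seed=base_seed)
        c_effs[r] = effective_compliance_subc(real).inverse().kelvin
    mean = c_effs.mean(axis=0)
    form = "plane2d" if grid.dim == 2 else "full3d"
    if ns > 1:
        disp = empirical_dispersion(c_effs, mean)
        stderr = disp / np.sqrt(ns)
    else:
        disp, stderr = 0.0, np.inf
    return EffectiveStats(
        mean=ElasticTensor(mean, kind="stiffness", form=form, _validate=False),
        dispersion=float(disp), stderr=float(stderr), ns=ns)
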