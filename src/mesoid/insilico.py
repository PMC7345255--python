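"""In-silico multiscale "experimental" data generator.

Emulates the validation protocol: sample ONE realization of the prior
random elasticity (compliance) field over the whole macroscopic domain at a
known hyperparameter vector b* = (delta*, ell*, kappa_bar*, mu_bar*), solve
the clamped-bottom / uniformly-loaded-top compression problem on a fine grid
resolving the heterogeneities, and extract (i) the displacement restricted
to a coarser macroscale observation grid and (ii) the fine-resolution
displacement over Q non-overlapping mesoscale observation windows.  Also
provides the Gaussian pre-smoothing applied to optically measured
displacement images.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .elasticity import IsotropicModuli, isotropic_compliance, \
    isotropic_stiffness
from .fem import assemble_stiffness, compression_load, \
    _solve_constrained, _dirichlet_dofs
from .grids import DisplacementField, StructuredGrid
from .homogenization import stiffness_cells
from .identification import HyperPoint
from .random_field import FieldSpec, SfePlusSampler

__all__ = ["ExperimentConfig", "SpecimenData", "generate_specimen",
           "gaussian_smooth", "reduced_validation_config",
           "paper_scale_config"]


@dataclass
class ExperimentConfig:
    """Geometry, loading and ground truth of one synthetic experiment.

    ``windows`` is a list of (origin_cells, size_cells) pairs on the fine
    grid; ``macro_subsample`` is the integer node-subsampling factor from the
    fine grid to the macroscale observation grid.
    """

    domain_size: float              # side length, m
    traction: float                 # |f| on the top face, N/m^2
    b_true: HyperPoint              # (delta, ell [m], kappa [GPa], mu [GPa])
    cells_per_ell: int = 4
    macro_subsample: int = 4
    windows: list = field(default_factory=list)
    dim: int = 2
    kernel: str = "squared_exponential"
    seed: int = 0
    store: str = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.b_true = HyperPoint(*self.b_true)
        if self.store is None:
            self.store = "compliance" if self.dim == 2 else "stiffness"
        n_fine = self.n_fine_cells
        if n_fine % self.macro_subsample:
            raise ValueError("macro_subsample must divide the fine grid size")
        if self.cells_per_ell < 4:
            raise ValueError("fine grid must resolve ell with >= 4 cells")
        for origin, size in self.windows:
            for a in range(self.dim):
                if origin[a] < 0 or origin[a] + size[a] > n_fine:
                    raise ValueError("mesoscale window outside the domain")

    @property
    def fine_h(self) -> float:
        return self.b_true.ell / self.cells_per_ell

    @property
    def n_fine_cells(self) -> int:
        n = self.domain_size / self.fine_h
        if abs(n - round(n)) > 1e-9:
            raise ValueError("domain size must be a whole number of fine cells")
        return int(round(n))

    def fine_grid(self) -> StructuredGrid:
        n = self.n_fine_cells
        return StructuredGrid((n,) * self.dim, (self.fine_h,) * self.dim)

    def macro_grid(self) -> StructuredGrid:
        n = self.n_fine_cells // self.macro_subsample
        return StructuredGrid((n,) * self.dim,
                              (self.fine_h * self.macro_subsample,) * self.dim)


@dataclass
class SpecimenData:
    """Synthetic multiscale observations plus the generating truth."""

    config: ExperimentConfig
    u_macro: DisplacementField
    windows: list[DisplacementField]
    u_fine: DisplacementField


def _field_spec(cfg: ExperimentConfig) -> FieldSpec:
    b = cfg.b_true
    m = IsotropicModuli(b.kappa, b.mu)
    mean = (isotropic_compliance(m, form="full3d") if cfg.store == "compliance"
            else isotropic_stiffness(m, form="full3d"))
    return FieldSpec(mean=mean, delta=b.delta, ell=(b.ell,) * cfg.dim,
                     kernel=cfg.kernel, seed=cfg.seed)


def generate_specimen(cfg: ExperimentConfig) -> SpecimenData:
    """Generate one synthetic multiscale experiment (deterministic in
    ``cfg.seed``)."""
    grid = cfg.fine_grid()
    spec = _field_spec(cfg)
    sampler = SfePlusSampler(spec, grid, warn=False)
    realization = sampler.sample(0)
    c_cells = stiffness_cells(realization, cfg.dim)
    load = compression_load(grid, cfg.traction)
    k = assemble_stiffness(grid, c_cells)
    from .fem import neumann_load_vector

    f = neumann_load_vector(grid, load.neumann)
    fixed, vals = _dirichlet_dofs(grid, load.dirichlet_nodes,
                                  load.dirichlet_values)
    u = _solve_constrained(k, f, fixed, vals).reshape(-1, cfg.dim)
    u_fine = DisplacementField(grid, u)
    u_macro = _subsample(u_fine, cfg.macro_subsample, cfg.macro_grid())
    windows = [_extract_window(u_fine, origin, size)
               for origin, size in cfg.windows]
    return SpecimenData(config=cfg, u_macro=u_macro, windows=windows,
                        u_fine=u_fine)


def _node_array(u: DisplacementField) -> np.ndarray:
    g = u.grid
    return u.values.reshape(*g.n_nodes_axis, g.dim, order="F")


def _subsample(u: DisplacementField, factor: int,
               coarse: StructuredGrid) -> DisplacementField:
    arr = _node_array(u)
    sel = (slice(None, None, factor),) * u.grid.dim
    sub = arr[sel]
    return DisplacementField(coarse, sub.reshape(-1, u.grid.dim, order="F"))


def _extract_window(u: DisplacementField, origin_cells, size_cells
                    ) -> DisplacementField:
    g = u.grid
    arr = _node_array(u)
    sel = tuple(slice(o, o + s + 1) for o, s in zip(origin_cells, size_cells))
    sub = arr[sel]
    wgrid = StructuredGrid(tuple(size_cells), g.h,
                           origin=tuple(g.origin[a] + origin_cells[a] * g.h[a]
                                        for a in range(g.dim)))
    return DisplacementField(wgrid, sub.reshape(-1, g.dim, order="F"))


def gaussian_smooth(u: DisplacementField, sigma: float) -> DisplacementField:
    """Separable Gaussian smoothing of a displacement field, per component;
    ``sigma`` in grid units (pixels), reflective boundary handling.  The
    pre-filter applied to optically measured displacement images to damp
    measurement noise without erasing mesoscale fluctuations."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return DisplacementField(u.grid, u.values.copy())
    arr = _node_array(u)
    out = np.empty_like(arr)
    for c in range(u.grid.dim):
        out[..., c] = ndimage.gaussian_filter(arr[..., c], sigma,
                                              mode="reflect")
    return DisplacementField(u.grid,
                             out.reshape(-1, u.grid.dim, order="F"))


def reduced_validation_config(seed: int = 0) -> ExperimentConfig:
    """Desk-scale 2D compression experiment: domain 16 ell with Q=4
    non-overlapping windows of 4 ell, fine grid 4 cells/ell (64x64), macro
    observation grid 16x16; truth b* = (0.40, 125 um, 13.75 GPa, 3.587 GPa)
    and top traction 5e7 N/m^2."""
    ell = 125e-6
    b = HyperPoint(0.40, ell, 13.75, 3.587)
    w = 16  # window size in fine cells (4 ell)
    windows = [((8, 8), (w, w)), ((40, 8), (w, w)),
               ((8, 40), (w, w)), ((40, 40), (w, w))]
    return ExperimentConfig(domain_size=16 * ell, traction=5e7, b_true=b,
                            cells_per_ell=4, macro_subsample=4,
                            windows=windows, dim=2, seed=seed)


def paper_scale_config(seed: int = 0) -> ExperimentConfig:
    """Full-scale 2D preset: 1x1 cm domain (80 ell), Q=16 windows of 1x1 mm,
    fine grid 4 cells/ell (320x320), macro observation 25x25-ish
    (subsample 16 -> 20x20 nodes of 25 elements... kept node-aligned at
    subsample 16)."""
    ell = 125e-6
    b = HyperPoint(0.40, ell, 13.75, 3.587)
    w = 32  # 1 mm = 8 ell = 32 fine cells
    windows = [((8 + 72 * i, 8 + 72 * j), (w, w))
               for i in range(4) for j in range(4)]
    return ExperimentConfig(domain_size=80 * ell, traction=5e7, b_true=b,
                            cells_per_ell=4, macro_subsample=16,
                            windows=windows, dim=2, seed=seed)
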