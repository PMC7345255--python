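"""Non-Gaussian positive-definite matrix-valued random field sampler.

Implements the maximum-entropy prior family for apparent elasticity (or
compliance) fields at mesoscale: a statistically homogeneous random field of
symmetric positive-definite Kelvin matrices with prescribed mean, dispersion
coefficient ``delta`` and spatial correlation lengths ``ell``.

Construction
------------
Each field value is ``C(x) = Lbar^T G(x) Lbar`` where ``Lbar`` is the
Cholesky factor of the mean Kelvin matrix and ``G(x)`` is a normalized random
matrix field with identity mean, built from n(n+1)/2 independent stationary
Gaussian germ fields ``U_ij(x)``:

* ``G = L^T L`` with ``L`` upper triangular,
* off-diagonal entries ``L_ij = sigma U_ij`` (i<j) with
  ``sigma = delta/sqrt(n+1)``,
* diagonal entries ``L_jj = sigma sqrt(2 h_j)`` where
  ``h_j = F_Gamma(a_j)^{-1}(Phi(U_jj))`` maps the Gaussian germ through its
  CDF onto a gamma variable of shape ``a_j = (n+1)/(2 delta^2) + (1-j)/2``.

This yields ``E[G] = I`` and a dispersion coefficient
``sqrt(E||G - I||_F^2 / n) = delta``, defined for
``0 <= delta < delta_sup(n) = sqrt((n+1)/(n+5))`` (0.7977 for n=6).  Note
``delta`` is the dispersion of the normalized field ``G``; the dispersion of
``C`` itself is smaller by a mean-dependent factor (see
:func:`field_dispersion_factor`).

Germs are sampled spectrally by circulant embedding on a padded periodic
extension of the grid, which reproduces the target autocorrelation exactly
at the grid lags.  Fields are piecewise constant per element (evaluated at
element centroids).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.fft
from scipy.special import gammaincinv, ndtr

from .elasticity import ElasticTensor
from .grids import StructuredGrid

__all__ = [
    "FieldSpec",
    "FieldRealization",
    "SfePlusSampler",
    "delta_sup",
    "germ_correlation",
    "sample_field",
    "sample_gaussian_germ",
    "empirical_dispersion",
    "field_dispersion_factor",
]

KERNELS = ("squared_exponential", "sinc2")


def delta_sup(n: int) -> float:
    """Upper bound of the dispersion coefficient for Kelvin dimension ``n``:
    sqrt((n+1)/(n+5)); 0.7977 for n=6."""
    if n < 1:
        raise ValueError("n must be a positive integer")
    return math.sqrt((n + 1.0) / (n + 5.0))


def germ_correlation(kernel: str, eta: "float | np.ndarray",
                     ell: float = 1.0) -> np.ndarray:
    """Normalized germ autocorrelation r(eta) at lag ``eta`` for correlation
    length ``ell``; r(0)=1 and the one-sided integral of r equals ``ell``.

    ``squared_exponential``: r = exp(-pi eta^2 / (4 ell^2)).
    ``sinc2``: r = sinc^2(eta/(2 ell)) (numpy sinc convention), the
    cardinal-sine-squared kernel.
    """
    eta = np.abs(np.asarray(eta, dtype=float))
    if np.any(eta < 0):
        raise ValueError("lag must be non-negative")
    if kernel == "squared_exponential":
        return np.exp(-math.pi * eta**2 / (4.0 * ell**2))
    if kernel == "sinc2":
        return np.sinc(eta / (2.0 * ell)) ** 2
    raise ValueError(f"unknown germ kernel {kernel!r}; choose from {KERNELS}")


@dataclass
class FieldSpec:
    """One member of the prior random-field family.

    Parameters
    ----------
    mean : ElasticTensor
        Mean Kelvin matrix (stiffness or compliance; 6x6 for the fields used
        in this package).
    delta : float
        Dispersion coefficient of the normalized germ matrix field, in
        [0, delta_sup(n)).
    ell : tuple of float
        Correlation lengths (l1, l2[, l3]), meters; an entry may be
        ``inf`` (the germ is constant along that axis).  For plane problems
        l3 = inf is implied by sampling on a 2D grid.
    kernel : str
        Germ autocorrelation kernel identifier.
    seed : int
        Base RNG seed of the family.
    """

    mean: ElasticTensor
    delta: float
    ell: tuple[float, ...]
    kernel: str = "squared_exponential"
    seed: int = 0

    def __post_init__(self) -> None:
        n = self.mean.n
        if not 0.0 <= self.delta < delta_sup(n):
            raise ValueError(
                f"delta={self.delta} outside [0, {delta_sup(n):.4f}) for n={n}"
            )
        self.ell = tuple(float(l) for l in np.atleast_1d(self.ell))
        if any(l <= 0 for l in self.ell):
            raise ValueError("correlation lengths must be positive")
        if self.kernel not in KERNELS:
            raise ValueError(f"unknown germ kernel {self.kernel!r}")


@dataclass
class FieldRealization:
    """Piecewise-constant field of Kelvin matrices on a structured grid."""

    grid: StructuredGrid
    values: np.ndarray  # (n_cells, n, n)
    kind: str = "stiffness"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[0] != self.grid.n_cells:
            raise ValueError("values must be (n_cells, n, n)")


class SfePlusSampler:
    """Sampler with precomputed spectral embedding for one (spec, grid) pair.

    Realization ``r`` is seeded deterministically from ``(spec.seed + base
    offset, r)`` so sequences are reproducible and independent across r.
    """

    def __init__(self, spec: FieldSpec, grid: StructuredGrid,
                 min_cells_per_ell: int = 2, warn: bool = True):
        self.spec = spec
        self.grid = grid
        n = spec.mean.n
        self.n = n
        self.n_germs = n * (n + 1) // 2
        ell = spec.ell
        if len(ell) < grid.dim:
            raise ValueError("spec.ell must cover every grid axis")
        for a in range(grid.dim):
            if np.isfinite(ell[a]) and ell[a] < min_cells_per_ell * grid.h[a]:
                if warn:
                    import warnings

                    warnings.warn(
                        f"grid spacing h={grid.h[a]:.3g} under-resolves "
                        f"correlation length ell={ell[a]:.3g} on axis {a}",
                        stacklevel=2,
                    )
        self._eigs = self._embedding_eigenvalues() if spec.delta > 0 else None
        # mean factor: mean = lbar_lower @ lbar_lower.T
        self._lbar = np.linalg.cholesky(spec.mean.kelvin)
        delta = spec.delta
        if delta > 0:
            self._sigma = delta / math.sqrt(n + 1.0)
            j = np.arange(1, n + 1)
            self._shape = (n + 1.0) / (2.0 * delta**2) + (1.0 - j) / 2.0
            self._diag_idx, self._offd_idx = _triu_index_split(n)

    def _embedding_eigenvalues(self) -> np.ndarray:
        grid, spec = self.grid, self.spec
        shape = []
        cov_axes = []
        for a in range(grid.dim):
            n_a, h_a, l_a = grid.n_elems[a], grid.h[a], spec.ell[a]
            if not np.isfinite(l_a):
                shape.append(1)
                cov_axes.append(np.ones(1))
                continue
            # pad by 6 correlation lengths, capped at 6 domain extents: for
            # ell >> domain the covariance is ~1 at every admissible lag and
            # the embedding degenerates gracefully to a near-constant field
            pad = int(math.ceil(6.0 * min(l_a, n_a * h_a) / h_a))
            size = scipy.fft.next_fast_len(n_a + pad, real=True)
            lags = np.minimum(np.arange(size), size - np.arange(size)) * h_a
            cov_axes.append(germ_correlation(spec.kernel, lags, l_a))
            shape.append(size)
        cov = cov_axes[0]
        for c in cov_axes[1:]:
            cov = np.multiply.outer(cov, c)
        eigs = scipy.fft.fftn(cov).real
        return np.sqrt(np.clip(eigs, 0.0, None))

    def _sample_germs(self, rng: np.random.Generator) -> np.ndarray:
        """(n_germs, n_cells) standard-normal germ values at cell centroids."""
        grid = self.grid
        full = self._eigs.shape
        w = rng.standard_normal((self.n_germs, *full))
        axes = tuple(range(1, 1 + len(full)))
        x = scipy.fft.ifftn(self._eigs[None] * scipy.fft.fftn(w, axes=axes),
                            axes=axes).real
        sel = tuple(slice(0, max(ne, 1)) if sz > 1 else slice(0, 1)
                    for ne, sz in zip(grid.n_elems, full))
        x = x[(slice(None), *sel)]
        x = np.broadcast_to(
            x, (self.n_germs, *grid.n_elems)
        )
        return x.reshape(self.n_germs, -1, order="F").copy()

    def sample(self, index: int, base_seed: "int | None" = None) -> FieldRealization:
        """Draw realization ``index`` of the field."""
        spec, grid, n = self.spec, self.grid, self.n
        if spec.delta == 0.0:
            vals = np.broadcast_to(spec.mean.kelvin,
                                   (grid.n_cells, n, n)).copy()
            return FieldRealization(grid, vals, kind=spec.mean.kind)
        seed = spec.seed if base_seed is None else base_seed
        rng = np.random.default_rng([int(seed) % (2**31), int(index)])
        u = self._sample_germs(rng)  # (n_germs, n_cells)
        g = self._normalized_matrix(u)
        vals = np.einsum("ik,zkl,jl->zij", self._lbar, g, self._lbar,
                         optimize=True)
        vals = 0.5 * (vals + np.swapaxes(vals, 1, 2))
        return FieldRealization(grid, vals, kind=spec.mean.kind)

    def _normalized_matrix(self, u: np.ndarray) -> np.ndarray:
        """Germ values (n_germs, N) -> normalized SPD matrices G (N, n, n)."""
        n, sigma = self.n, self._sigma
        big_n = u.shape[1]
        ell_mat = np.zeros((big_n, n, n))
        rows_d, (rows_o, cols_o, germs_o) = self._diag_idx, self._offd_idx
        # diagonal: gamma transform of the germ through the Gaussian CDF
        u_diag = u[rows_d[1]]  # (n, N) germ per diagonal entry
        p = np.clip(ndtr(u_diag), 1e-300, 1.0 - 1e-16)
        gam = gammaincinv(self._shape[:, None], p)
        ell_mat[:, np.arange(n), np.arange(n)] = (
            sigma * np.sqrt(2.0 * gam)
        ).T
        ell_mat[:, rows_o, cols_o] = sigma * u[germs_o].T
        return np.einsum("zki,zkj->zij", ell_mat, ell_mat, optimize=True)


def _triu_index_split(n: int):
    """Germ-index bookkeeping: germ g covers upper-triangle entry (i, j)."""
    rows, cols = np.triu_indices(n)
    diag_mask = rows == cols
    diag_germs = np.nonzero(diag_mask)[0]
    diag_rows = rows[diag_mask]
    off = ~diag_mask
    return (diag_germs, diag_rows), (rows[off], cols[off], np.nonzero(off)[0])


def sample_field(spec: FieldSpec, grid: StructuredGrid, ns: int,
                 base_seed: "int | None" = None) -> list[FieldRealization]:
    """Draw ``ns`` independent realizations of the field on ``grid``."""
    sampler = SfePlusSampler(spec, grid)
    return [sampler.sample(r, base_seed=base_seed) for r in range(ns)]


def sample_gaussian_germ(grid: StructuredGrid, ell: tuple[float, ...],
                         kernel: str, rng: np.random.Generator,
                         n_fields: int = 1) -> np.ndarray:
    """Sample ``n_fields`` independent unit-variance Gaussian germ fields at
    cell centroids; returns (n_fields, *n_elems) in grid axis order."""
    mean = ElasticTensor(np.eye(6), kind="stiffness", form="full3d")
    spec = FieldSpec(mean=mean, delta=0.3, ell=tuple(ell), kernel=kernel)
    sampler = SfePlusSampler.__new__(SfePlusSampler)
    sampler.spec = spec
    sampler.grid = grid
    sampler.n = 6
    sampler.n_germs = n_fields
    sampler._eigs = SfePlusSampler._embedding_eigenvalues(sampler)
    flat = sampler._sample_germs(rng)
    return flat.reshape(n_fields, *grid.n_elems, order="F")


def empirical_dispersion(values: np.ndarray,
                         mean: "np.ndarray | None" = None) -> float:
    """Empirical dispersion coefficient sqrt(E||A - Abar||^2)/||Abar|| of a
    sample of Kelvin matrices ``values`` (N, n, n); uses the empirical mean
    when ``mean`` is None."""
    values = np.asarray(values, dtype=float)
    mbar = values.mean(axis=0) if mean is None else np.asarray(mean)
    num = np.mean(np.sum((values - mbar) ** 2, axis=(1, 2)))
    return float(np.sqrt(num) / np.linalg.norm(mbar))


def field_dispersion_factor(mean: ElasticTensor) -> float:
    """Ratio dispersion(C)/dispersion(G) implied by the construction at
    second order: sqrt((1 + tr(M)^2/||M||^2)/(n+1)) for mean matrix M."""
    m = mean.kelvin
    n = m.shape[0]
    return math.sqrt((1.0 + np.trace(m) ** 2 / np.sum(m * m)) / (n + 1.0))
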