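"""Cost functions of the multi-objective identification problem.

Four indicators compare model predictions to full-field observations:

* ``j_macro`` — spatial mean-square Frobenius distance between the model and
  experimental strain fields at macroscale;
* ``j_delta`` — squared relative distance between the Monte-Carlo mean of the
  model's pseudo-dispersion coefficient D_E and its experimental counterpart;
* ``j_ell`` — summed squared relative distances between mean pseudo
  correlation lengths of the model strain field and the experimental ones,
  per spatial axis;
* ``j_h`` — squared relative Frobenius distance between the Monte-Carlo mean
  effective stiffness E{C_eff(b)} and the macroscale stiffness C_macro(a).

The pseudo statistics treat a single strain field's *spatial* fluctuations
as if the field were homogeneous: V is the spatial variance, D = sqrt(V)
normalized by the Frobenius norm of the spatial mean strain, and the pseudo
correlation length along an axis is the empirical autocorrelation of the
centered field integrated to its first non-positive lag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .elasticity import ElasticTensor
from .grids import StrainField

__all__ = [
    "DispersionStat",
    "CorrLengthEstimate",
    "IndicatorValues",
    "j_macro",
    "dispersion_stat",
    "j_delta",
    "corrlen_estimate",
    "j_ell",
    "j_h",
]


@dataclass
class DispersionStat:
    """Spatial variance V and pseudo-dispersion D = sqrt(V)/||mean strain||
    of one strain field."""

    v: float
    d: float


@dataclass
class CorrLengthEstimate:
    """Pseudo correlation length along one axis; ``saturated`` marks a field
    with no decorrelation inside the window (estimate clipped to extent)."""

    value: float
    saturated: bool = False


@dataclass
class IndicatorValues:
    """Evaluated indicators with Monte-Carlo standard errors for the
    stochastic three (None for the deterministic macro indicator)."""

    j_macro: float = np.nan
    j_delta: float = np.nan
    j_ell: float = np.nan
    j_h: float = np.nan
    se_delta: float = np.nan
    se_ell: float = np.nan
    se_h: float = np.nan


def _check_same_grid(a: StrainField, b: StrainField) -> None:
    if a.grid.n_elems != b.grid.n_elems or a.grid.h != b.grid.h:
        raise ValueError("strain fields live on different grids")


def j_macro(eps_model: StrainField, eps_exp: StrainField) -> float:
    """Spatial average of the squared Frobenius norm of the strain mismatch."""
    _check_same_grid(eps_model, eps_exp)
    diff = eps_model.values - eps_exp.values
    return float(np.mean(np.sum(diff * diff, axis=1)))


def dispersion_stat(eps: StrainField) -> DispersionStat:
    """Spatial variance and pseudo-dispersion of a strain field.

    Raises if the spatial mean strain vanishes (D undefined)."""
    mean = eps.spatial_mean()
    mean_norm = float(np.linalg.norm(mean))
    diff = eps.values - mean
    v = float(np.mean(np.sum(diff * diff, axis=1)))
    if mean_norm <= 1e-14 * max(np.sqrt(v), 1e-300):
        raise ValueError("pseudo-dispersion undefined: spatial-mean strain "
                         "is zero")
    return DispersionStat(v=v, d=np.sqrt(v) / mean_norm)


def j_delta(meso_stats: "list[DispersionStat]",
            exp_stat: DispersionStat) -> tuple[float, float]:
    """((E{D_E} - delta_exp)/delta_exp)^2 and its Monte-Carlo standard
    error (delta-method)."""
    if len(meso_stats) < 1:
        raise ValueError("at least one realization required")
    if exp_stat.d <= 0:
        raise ValueError("experimental pseudo-dispersion must be positive")
    ds = np.array([s.d for s in meso_stats])
    mean_d = ds.mean()
    j = ((mean_d - exp_stat.d) / exp_stat.d) ** 2
    if len(ds) > 1:
        se_mean = ds.std(ddof=1) / np.sqrt(len(ds))
        se = abs(2.0 * (mean_d - exp_stat.d) / exp_stat.d**2) * se_mean
    else:
        se = np.inf
    return float(j), float(se)


def corrlen_estimate(eps: StrainField, axis: int) -> CorrLengthEstimate:
    """Pseudo correlation length of a strain field along ``axis``.

    Empirical autocorrelation of the component-wise centered field along the
    axis (pooled over strain components and transverse lines, each component
    weighted by its variance share), integrated by the trapezoid rule to the
    first non-positive lag; clipped to the axis extent.  Needs >= 8 samples
    along the axis.
    """
    grid = eps.grid
    n_ax = grid.n_elems[axis]
    if n_ax < 8:
        raise ValueError("need at least 8 cells along the axis")
    delta_h = grid.h[axis]
    extent = n_ax * delta_h
    nstr = eps.values.shape[1]
    f = eps.values.reshape(*grid.n_elems, nstr, order="F")
    f = np.moveaxis(f, axis, 0).reshape(n_ax, -1)  # (n_ax, lines*comps)
    f = f - f.mean(axis=0, keepdims=True)  # center per line/component
    c0 = np.sum(f * f) / f.size
    if c0 <= 0.0:
        return CorrLengthEstimate(value=extent, saturated=True)
    ell_hat = 0.5 * delta_h
    saturated = True
    for k in range(1, n_ax):
        ck = np.sum(f[:-k] * f[k:]) / f.size
        r = ck / c0
        if r <= 0.0:
            saturated = False
            break
        ell_hat += r * delta_h
    value = min(ell_hat, extent)
    return CorrLengthEstimate(value=float(value),
                              saturated=saturated or value >= extent)


def j_ell(meso_lengths: np.ndarray,
          exp_lengths: np.ndarray) -> tuple[float, float]:
    """Sum over axes of ((E{L_alpha} - l_exp_alpha)/l_exp_alpha)^2, plus a
    Monte-Carlo standard error.

    ``meso_lengths``: (Ns, n_axes) per-realization estimates;
    ``exp_lengths``: (n_axes,) experimental estimates.
    """
    meso = np.atleast_2d(np.asarray(meso_lengths, dtype=float))
    exp_l = np.asarray(exp_lengths, dtype=float)
    if meso.shape[1] != exp_l.shape[0]:
        raise ValueError("axis count mismatch between model and experiment")
    if np.any(exp_l <= 0):
        raise ValueError("experimental correlation lengths must be positive")
    means = meso.mean(axis=0)
    rel = (means - exp_l) / exp_l
    j = float(np.sum(rel**2))
    if meso.shape[0] > 1:
        se_means = meso.std(axis=0, ddof=1) / np.sqrt(meso.shape[0])
        se = float(np.sqrt(np.sum((2.0 * np.abs(rel) / exp_l * se_means) ** 2)))
    else:
        se = np.inf
    return j, se


def j_h(c_eff_mean: ElasticTensor, c_macro: ElasticTensor) -> float:
    """(||E{C_eff} - C_macro||_F / ||C_macro||_F)^2."""
    if c_eff_mean.form != c_macro.form:
        raise ValueError("tensor forms differ")
    num = np.linalg.norm(c_eff_mean.kelvin - c_macro.kelvin)
    den = np.linalg.norm(c_macro.kelvin)
    return float((num / den) ** 2)
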