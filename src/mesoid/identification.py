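"""Two-stage identification of the macroscale moduli and the mesoscale
hyperparameters.

Stage 1 (macroscale): Nelder-Mead minimization of the macroscopic indicator
over the isotropic moduli a = (kappa, mu).

Stage 2 (mesoscale, per observation window): minimization of the
multi-objective cost (J_delta, J_ell, J_h) over the hyperparameter vector
b = (delta, ell, kappa_bar, mu_bar) on a discretized admissible set, either
by a fixed-point (coordinate-descent) iteration in which each indicator is
minimized over its dedicated coordinate grid, or by a genetic algorithm that
builds a Pareto front and selects the best compromise (nondominated point
nearest the origin).

Robustification: the per-window solutions are treated as independent draws
of a random hyperparameter vector with a maximum-entropy prior (uniform for
delta on (0, delta_sup); gamma for ell; gamma densities with a shared shape
hyperparameter lambda for (kappa_bar, mu_bar)); its parameters are fitted by
maximum likelihood and the robust optimum is the mode of the fitted density
(for delta: the sample mean, the mode being flat).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import optimize, special

from .elasticity import IsotropicModuli, isotropic_compliance, \
    isotropic_stiffness
from .fem import LoadCase, solve_macro, strain_from_displacement
from .grids import DisplacementField, StrainField, StructuredGrid
from .homogenization import RveConfig, mc_effective_mean
from .indicators import (corrlen_estimate, dispersion_stat, j_delta, j_ell,
                         j_h, j_macro)
from .random_field import FieldSpec, SfePlusSampler, delta_sup
from .homogenization import stiffness_cells
from .fem import solve_meso

__all__ = [
    "AdmissibleSet",
    "HyperPoint",
    "MesoSolution",
    "PriorParameters",
    "discretize_admissible_set",
    "identify_macro",
    "MesoModel",
    "fixed_point_identify",
    "genetic_identify",
    "pareto_filter",
    "gamma_mle",
    "h_mle",
    "robust_identify",
    "fp_evaluation_count",
    "ga_evaluation_count",
]


class HyperPoint(NamedTuple):
    """Hyperparameter vector b = (delta, ell, kappa_bar, mu_bar); ell in
    meters, moduli in GPa."""

    delta: float
    ell: float
    kappa: float
    mu: float


def discretize_admissible_set(interval: tuple[float, float],
                              nv: int) -> np.ndarray:
    """``nv`` equidistant points including both endpoints."""
    lo, hi = float(interval[0]), float(interval[1])
    if not hi > lo:
        raise ValueError("empty admissible interval")
    if nv < 2:
        raise ValueError("nv >= 2 required")
    return np.linspace(lo, hi, nv)


@dataclass
class AdmissibleSet:
    """Reduced admissible hypercube for b with its grid resolution ``nv``."""

    delta: tuple[float, float]
    ell: tuple[float, float]
    kappa: tuple[float, float]
    mu: tuple[float, float]
    nv: int = 10

    def __post_init__(self) -> None:
        if not (0.0 <= self.delta[0] < self.delta[1] < delta_sup(6)):
            raise ValueError("delta interval must lie inside [0, delta_sup)")
        for name in ("ell", "kappa", "mu"):
            lo, hi = getattr(self, name)
            if not 0.0 < lo < hi:
                raise ValueError(f"invalid {name} interval")
        if self.nv < 2:
            raise ValueError("nv >= 2 required")

    def grids(self) -> dict[str, np.ndarray]:
        return {name: discretize_admissible_set(getattr(self, name), self.nv)
                for name in ("delta", "ell", "kappa", "mu")}

    def widths(self) -> np.ndarray:
        return np.array([hi - lo for lo, hi in
                         (self.delta, self.ell, self.kappa, self.mu)])


@dataclass
class MesoSolution:
    """Identified hyperparameters for one observation window."""

    b: HyperPoint
    n_iter: int
    evaluations: int
    converged: bool = True
    solver: str = "fixed_point"
    history: list = field(default_factory=list)


def fp_evaluation_count(nv: int, ns: int, n_iters) -> int:
    """Stochastic-model calls of the fixed-point solver: 3 * nV * Ns * sum(n_q)."""
    return int(3 * nv * ns * np.sum(n_iters))


def ga_evaluation_count(ni: int, ns: int, n_gens) -> int:
    """Stochastic-model calls of the genetic solver: 3 * nI * Ns * sum(n_q)."""
    return int(3 * ni * ns * np.sum(n_gens))


# ---------------------------------------------------------------------------
# macroscale stage


def identify_macro(eps_exp: StrainField, grid: StructuredGrid, load: LoadCase,
                   init: IsotropicModuli,
                   bounds: "tuple | None" = None,
                   xtol: float = 1e-6) -> IsotropicModuli:
    """Nelder-Mead minimizer of the macroscopic indicator over (kappa, mu).

    ``bounds`` is an optional ((kappa_lo, kappa_hi), (mu_lo, mu_hi)) box the
    result is clipped to.  Relative tolerance 1e-6 on parameters and values.
    """
    dim = grid.dim
    form = "plane2d" if dim == 2 else "full3d"

    def cost(a: np.ndarray) -> float:
        kappa, mu = a
        if kappa <= 0 or mu <= 0:
            return 1e30
        c = isotropic_stiffness(IsotropicModuli(kappa, mu), form=form)
        _, eps = solve_macro(grid, c, load)
        return j_macro(eps, eps_exp)

    x0 = init.as_array()
    res = optimize.minimize(
        cost, x0, method="Nelder-Mead",
        options={"xatol": xtol * max(x0), "fatol": xtol * max(cost(x0), 1e-30),
                 "maxiter": 400})
    if not res.success:
        import warnings

        warnings.warn("macroscale identification did not converge; returning "
                      "best point found", stacklevel=2)
    kappa, mu = res.x
    if bounds is not None:
        kappa = float(np.clip(kappa, *bounds[0]))
        mu = float(np.clip(mu, *bounds[1]))
    return IsotropicModuli(float(kappa), float(mu))


# ---------------------------------------------------------------------------
# mesoscale stage: stochastic model evaluator


class MesoModel:
    """Evaluator of the three mesoscale indicators for one observation window.

    Holds the experimental statistics of the window (pseudo-dispersion and
    pseudo correlation lengths of the measured strain field), the identified
    macroscale stiffness, and Monte-Carlo settings.  Evaluations are memoized
    per hyperparameter point with common random numbers (the germ seeds do
    not depend on b), so grid comparisons are noise-consistent and repeated
    visits are free; the printed evaluation-count bookkeeping is formulaic
    and unaffected by caching.
    """

    def __init__(self, window: DisplacementField, a_macro: IsotropicModuli,
                 ns: int, rve: RveConfig = None, seed: int = 0,
                 store: "str | None" = None,
                 ceff_cache: "dict | None" = None):
        grid = window.grid
        self.window = window
        self.grid = grid
        self.dim = grid.dim
        self.ns = int(ns)
        self.rve = rve if rve is not None else RveConfig()
        self.seed = int(seed) % (2**31 - 1)
        # 2D plane stress samples the compliance field; 3D the stiffness field
        self.store = store or ("compliance" if self.dim == 2 else "stiffness")
        form = "plane2d" if self.dim == 2 else "full3d"
        self.c_macro = isotropic_stiffness(a_macro, form=form)
        eps = strain_from_displacement(grid, window)
        self.eps_exp = eps
        # experimental targets; overridable (e.g. for self-consistency runs)
        self.exp_stat = dispersion_stat(eps)
        self.ell_exp = np.array([corrlen_estimate(eps, ax).value
                                 for ax in range(self.dim)])
        self._meso_cache: dict[HyperPoint, tuple] = {}
        self._ceff_cache = ceff_cache if ceff_cache is not None else {}

    # -- model construction

    def field_spec(self, b: HyperPoint) -> FieldSpec:
        m = IsotropicModuli(b.kappa, b.mu)
        if self.store == "compliance":
            mean = isotropic_compliance(m, form="full3d")
        else:
            mean = isotropic_stiffness(m, form="full3d")
        ell = (b.ell,) * self.dim
        return FieldSpec(mean=mean, delta=b.delta, ell=ell, seed=self.seed)

    # -- indicator evaluations

    @property
    def delta_exp(self) -> float:
        return self.exp_stat.d

    def meso_samples(self, b: HyperPoint) -> tuple[list, np.ndarray]:
        """Per-realization pseudo-dispersion stats and correlation-length
        estimates (Ns, dim) of the model strain field at ``b`` (memoized)."""
        b = HyperPoint(*map(float, b))
        if b not in self._meso_cache:
            spec = self.field_spec(b)
            sampler = SfePlusSampler(spec, self.grid, warn=False)
            d_stats = []
            lengths = np.empty((self.ns, self.dim))
            for r in range(self.ns):
                real = sampler.sample(r)
                eps = solve_meso(self.grid, stiffness_cells(real, self.dim),
                                 self.window)
                d_stats.append(dispersion_stat(eps))
                lengths[r] = [corrlen_estimate(eps, ax).value
                              for ax in range(self.dim)]
            self._meso_cache[b] = (d_stats, lengths)
        return self._meso_cache[b]

    def meso_indicators(self, b: HyperPoint) -> tuple[float, float, float, float]:
        """(J_delta, J_ell, se_delta, se_ell) at ``b`` with Ns realizations;
        experimental targets are the window's pseudo statistics."""
        d_stats, lengths = self.meso_samples(b)
        jd, se_d = j_delta(d_stats, self.exp_stat)
        jl, se_l = j_ell(lengths, self.ell_exp)
        return (jd, jl, se_d, se_l)

    def j_h(self, b: HyperPoint) -> tuple[float, float]:
        """(J_h, standard error) at ``b``."""
        key = tuple(np.round([b.delta, b.ell, b.kappa, b.mu], 12))
        if key not in self._ceff_cache:
            spec = self.field_spec(b)
            self._ceff_cache[key] = mc_effective_mean(
                spec, self.rve, self.ns, dim=self.dim)
        eff = self._ceff_cache[key]
        jh = j_h(eff.mean, self.c_macro)
        se = 2.0 * math.sqrt(max(jh, 0.0)) * eff.stderr / math.sqrt(max(eff.ns, 1))
        return jh, se

    def objectives(self, b: HyperPoint) -> np.ndarray:
        jd, jl, _, _ = self.meso_indicators(b)
        jh, _ = self.j_h(b)
        return np.array([jd, jl, jh])


# ---------------------------------------------------------------------------
# fixed-point (coordinate descent) solver


def fixed_point_identify(model: MesoModel, adm: AdmissibleSet,
                         tol: float = 1e-9, max_iter: int = 20,
                         init: "HyperPoint | None" = None) -> MesoSolution:
    """Coordinate-descent minimization on the admissible grid.

    Each iteration minimizes J_delta over the delta grid, J_ell over the ell
    grid, then J_h over the kappa_bar and mu_bar grids (a pair of line
    searches sharing one Monte-Carlo batch).  Stops when the residual norm
    between successive iterates (scaled by the interval widths) drops below
    ``tol``; the reported iteration count includes the verifying iteration.
    """
    grids = adm.grids()
    widths = adm.widths()
    if init is None:
        mid = adm.nv // 2
        b = HyperPoint(grids["delta"][mid], grids["ell"][mid],
                       grids["kappa"][mid], grids["mu"][mid])
    else:
        b = init
    history = [b]
    converged = False
    n_iter = 0
    for _ in range(max_iter):
        n_iter += 1
        b_old = b
        jd_vals = [model.meso_indicators(b._replace(delta=d))[0]
                   for d in grids["delta"]]
        b = b._replace(delta=float(grids["delta"][int(np.argmin(jd_vals))]))
        jl_vals = [model.meso_indicators(b._replace(ell=l))[1]
                   for l in grids["ell"]]
        b = b._replace(ell=float(grids["ell"][int(np.argmin(jl_vals))]))
        jh_vals = [model.j_h(b._replace(kappa=k))[0] for k in grids["kappa"]]
        b = b._replace(kappa=float(grids["kappa"][int(np.argmin(jh_vals))]))
        jh_vals = [model.j_h(b._replace(mu=m))[0] for m in grids["mu"]]
        b = b._replace(mu=float(grids["mu"][int(np.argmin(jh_vals))]))
        history.append(b)
        res = np.linalg.norm((np.array(b) - np.array(b_old)) / widths)
        if res < tol:
            converged = True
            break
    if not converged:
        import warnings

        warnings.warn("fixed-point iteration did not converge; returning "
                      "last iterate", stacklevel=2)
    return MesoSolution(b=b, n_iter=n_iter,
                        evaluations=fp_evaluation_count(adm.nv, model.ns,
                                                        n_iter),
                        converged=converged, solver="fixed_point",
                        history=history)


# ---------------------------------------------------------------------------
# genetic solver (Pareto front + best compromise)


def pareto_filter(points: np.ndarray) -> np.ndarray:
    """Boolean mask of nondominated rows of an (n, m) objective array
    (minimization; a point is dominated if another is <= everywhere and <
    somewhere)."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        if not mask[i]:
            continue
        dominates_i = np.all(pts <= pts[i], axis=1) & np.any(pts < pts[i],
                                                             axis=1)
        if np.any(dominates_i):
            mask[i] = False
    return mask


def _nondominated_rank(pts: np.ndarray) -> np.ndarray:
    ranks = np.full(len(pts), -1)
    remaining = np.arange(len(pts))
    rank = 0
    while len(remaining):
        mask = pareto_filter(pts[remaining])
        ranks[remaining[mask]] = rank
        remaining = remaining[~mask]
        rank += 1
    return ranks


def _crowding(pts: np.ndarray) -> np.ndarray:
    n, m = pts.shape
    dist = np.zeros(n)
    for j in range(m):
        order = np.argsort(pts[:, j])
        span = pts[order[-1], j] - pts[order[0], j]
        dist[order[0]] = dist[order[-1]] = np.inf
        if span > 0 and n > 2:
            dist[order[1:-1]] += (pts[order[2:], j] - pts[order[:-2], j]) / span
    return dist


def genetic_identify(model: MesoModel, adm: AdmissibleSet, ni: int = 40,
                     n_gen: int = 15, seed: int = 0,
                     p_crossover: float = 0.9,
                     p_mutate: float = 0.25) -> tuple[np.ndarray, MesoSolution]:
    """Elitist genetic algorithm over the discretized admissible set.

    Individuals are grid-index vectors (the identified values printed by the
    method lie on the nV grid).  Selection is binary tournament on
    (nondominated rank, crowding distance); variation is uniform crossover
    plus per-coordinate mutation (random step or reset).  Returns the Pareto
    front of ALL evaluated points (an external archive, so no noninferior
    solution generated along the way is lost) and the best-compromise
    solution: the nondominated point minimizing the Euclidean distance to
    the origin of the objective space.
    """
    rng = np.random.default_rng(seed)
    grids = adm.grids()
    names = ("delta", "ell", "kappa", "mu")
    nv = adm.nv

    def to_point(idx: np.ndarray) -> HyperPoint:
        return HyperPoint(*(float(grids[nm][i]) for nm, i in zip(names, idx)))

    obj_cache: dict[tuple, np.ndarray] = {}

    def evaluate(idx: np.ndarray) -> np.ndarray:
        key = tuple(int(i) for i in idx)
        if key not in obj_cache:
            obj_cache[key] = model.objectives(to_point(idx))
        return obj_cache[key]

    pop = rng.integers(0, nv, size=(ni, 4))
    objs = np.array([evaluate(ind) for ind in pop])
    gen = 0
    for gen in range(1, n_gen + 1):
        ranks = _nondominated_rank(objs)
        crowd = _crowding(objs)
        # binary tournament
        parents = []
        for _ in range(ni):
            a, b = rng.integers(0, ni, 2)
            better = a if (ranks[a], -crowd[a]) < (ranks[b], -crowd[b]) else b
            parents.append(pop[better])
        parents = np.array(parents)
        children = parents.copy()
        for i in range(0, ni - 1, 2):
            if rng.random() < p_crossover:
                swap = rng.random(4) < 0.5
                children[i, swap], children[i + 1, swap] = (
                    children[i + 1, swap].copy(), children[i, swap].copy())
        mut = rng.random(children.shape) < p_mutate
        steps = np.where(rng.random(children.shape) < 0.3,
                         rng.integers(0, nv, size=children.shape),
                         children + rng.choice([-1, 1], size=children.shape))
        children = np.where(mut, np.clip(steps, 0, nv - 1), children)
        child_objs = np.array([evaluate(ind) for ind in children])
        # elitist (mu+lambda) NSGA-II style reduction
        allpop = np.vstack([pop, children])
        allobj = np.vstack([objs, child_objs])
        ranks = _nondominated_rank(allobj)
        crowd = _crowding(allobj)
        order = np.lexsort((-crowd, ranks))
        keep = order[:ni]
        pop, objs = allpop[keep], allobj[keep]
    # archive: every grid point evaluated during the run
    arch_pop = np.array([k for k in obj_cache], dtype=int)
    arch_objs = np.array([obj_cache[tuple(k)] for k in arch_pop])
    front_mask = pareto_filter(arch_objs)
    front_objs = arch_objs[front_mask]
    front_pop = arch_pop[front_mask]
    best = int(np.argmin(np.linalg.norm(front_objs, axis=1)))
    sol = MesoSolution(b=to_point(front_pop[best]), n_iter=gen,
                       evaluations=ga_evaluation_count(ni, model.ns, gen),
                       converged=True, solver="genetic")
    return front_objs, sol


# ---------------------------------------------------------------------------
# hyperprior maximum-likelihood robustification


def gamma_mle(values: np.ndarray) -> tuple[float, float, float]:
    """Maximum-likelihood (shape, scale) of a gamma sample and the density
    mode (shape-1)*scale.

    Solved from the digamma equation log(a) - psi(a) = log(AM/GM) by Newton
    iteration from the standard log-moment initializer.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least two values")
    if np.any(x <= 0):
        raise ValueError("gamma sample must be positive")
    s = math.log(x.mean()) - np.mean(np.log(x))
    if s < 1e-12:
        raise ValueError("degenerate sample: all values (numerically) equal")
    a = (3.0 - s + math.sqrt((s - 3.0) ** 2 + 24.0 * s)) / (12.0 * s)
    for _ in range(100):
        num = math.log(a) - special.digamma(a) - s
        den = 1.0 / a - special.polygamma(1, a)
        step = num / den
        a_new = a - step
        if a_new <= 0:
            a_new = a / 2.0
        if abs(a_new - a) < 1e-12 * a:
            a = a_new
            break
        a = a_new
    scale = x.mean() / a
    mode = (a - 1.0) * scale if a > 1.0 else 0.0
    return float(a), float(scale), float(mode)


@dataclass
class HPriorFit:
    """Fitted mean-moduli prior: gamma(1-lambda, rate lambda1) for kappa_bar
    and gamma(1-5*lambda, rate lambda2) for mu_bar, sharing lambda."""

    lam: float
    lam1: float
    lam2: float
    mode_kappa: float
    mode_mu: float
    at_bound: bool = False


def h_mle(kappa_values: np.ndarray, mu_values: np.ndarray,
          lambda_min: float = -50.0) -> HPriorFit:
    """Joint MLE of (lambda, lambda1, lambda2) for the mean-moduli prior.

    The rates are profiled out analytically (lambda1 = (1-lambda)/mean(kappa),
    lambda2 = (1-5*lambda)/mean(mu)); the scalar profile likelihood is
    maximized over lambda in [lambda_min, 1/5).  With zero-spread samples the
    likelihood increases without bound as lambda -> -inf (the prior forbids
    deterministic moduli); the boundary hit is flagged.
    """
    k = np.asarray(kappa_values, dtype=float)
    m = np.asarray(mu_values, dtype=float)
    if np.any(k <= 0) or np.any(m <= 0):
        raise ValueError("moduli samples must be positive")
    q = len(k)
    sk, slk = k.mean(), np.mean(np.log(k))
    sm, slm = m.mean(), np.mean(np.log(m))

    def neg_profile(lam: float) -> float:
        s1 = 1.0 - lam
        s2 = 1.0 - 5.0 * lam
        if s1 <= 0 or s2 <= 0:
            return 1e30
        l1 = s1 / sk
        l2 = s2 / sm
        ll = q * (s1 * math.log(l1) - special.gammaln(s1)
                  + (s1 - 1.0) * slk - l1 * sk
                  + s2 * math.log(l2) - special.gammaln(s2)
                  + (s2 - 1.0) * slm - l2 * sm)
        return -ll

    res = optimize.minimize_scalar(neg_profile,
                                   bounds=(lambda_min, 0.2 - 1e-9),
                                   method="bounded",
                                   options={"xatol": 1e-10})
    lam = float(res.x)
    at_bound = lam <= lambda_min * (1.0 - 1e-6) + 1e-12 or \
        abs(lam - lambda_min) < 1e-6 * max(abs(lambda_min), 1.0)
    lam1 = (1.0 - lam) / sk
    lam2 = (1.0 - 5.0 * lam) / sm
    mode_k = -lam / lam1 if lam < 0 else 0.0
    mode_m = -5.0 * lam / lam2 if lam < 0 else 0.0
    return HPriorFit(lam=lam, lam1=lam1, lam2=lam2,
                     mode_kappa=float(mode_k), mode_mu=float(mode_m),
                     at_bound=at_bound)


@dataclass
class PriorParameters:
    """Hyperprior parameter vector s = (a1,b1,a2,b2,a3,b3, lambda, lambda1,
    lambda2) together with degeneracy flags."""

    ell_shape: tuple[float, float, float]
    ell_scale: tuple[float, float, float]
    lam: float
    lam1: float
    lam2: float
    ell_degenerate: bool = False
    h_degenerate: bool = False
    lam_at_bound: bool = False

    def as_vector(self) -> np.ndarray:
        out = []
        for a, b in zip(self.ell_shape, self.ell_scale):
            out += [a, b]
        out += [self.lam, self.lam1, self.lam2]
        return np.array(out)


def robust_identify(solutions: "list[MesoSolution] | list[HyperPoint]",
                    lambda_min: float = -50.0
                    ) -> tuple[HyperPoint, PriorParameters]:
    """Robustified optimum across Q observation windows.

    delta: sample mean (flat prior on (0, delta_sup)); ell: mode of the
    gamma MLE fit; (kappa_bar, mu_bar): modes of the fitted mean-moduli
    prior.  Degenerate (all-equal) component samples fall back to the common
    value and are flagged.
    """
    bs = [s.b if isinstance(s, MesoSolution) else HyperPoint(*s)
          for s in solutions]
    if len(bs) == 0:
        raise ValueError("need at least one window solution")
    arr = np.array(bs)  # (Q, 4)
    delta_opt = float(arr[:, 0].mean())
    ells = arr[:, 1]
    ell_deg = len(bs) == 1 or np.ptp(ells) < 1e-12 * max(ells.mean(), 1e-300)
    if ell_deg:
        ell_opt = float(ells[0])
        a_ell, b_ell = math.inf, 0.0
    else:
        a_ell, b_ell, ell_opt = gamma_mle(ells)
    kappas, mus = arr[:, 2], arr[:, 3]
    h_deg = len(bs) == 1 or (
        np.ptp(kappas) < 1e-12 * kappas.mean()
        and np.ptp(mus) < 1e-12 * mus.mean())
    if h_deg:
        kappa_opt, mu_opt = float(kappas[0]), float(mus[0])
        fit = HPriorFit(lam=lambda_min, lam1=(1 - lambda_min) / kappas.mean(),
                        lam2=(1 - 5 * lambda_min) / mus.mean(),
                        mode_kappa=kappa_opt, mode_mu=mu_opt, at_bound=True)
    else:
        fit = h_mle(kappas, mus, lambda_min=lambda_min)
        kappa_opt, mu_opt = fit.mode_kappa, fit.mode_mu
    prior = PriorParameters(
        ell_shape=(a_ell,) * 3, ell_scale=(b_ell,) * 3,
        lam=fit.lam, lam1=fit.lam1, lam2=fit.lam2,
        ell_degenerate=bool(ell_deg), h_degenerate=bool(h_deg),
        lam_at_bound=fit.at_bound)
    return HyperPoint(delta_opt, ell_opt, kappa_opt, mu_opt), prior
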