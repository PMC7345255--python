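# Methods

## Problem and model

`mesoid` identifies the elastic properties of a random heterogeneous
linear-elastic material — the motivating application is cortical bone — from
full-field displacement measurements made simultaneously at two scales on a
single specimen under static compression:

* at **macroscale** the material is modeled as deterministic and homogeneous,
  with an isotropic elasticity tensor `C_macro(a)` parameterized by
  `a = (kappa, mu)` (bulk and shear moduli, GPa);
* at **mesoscale** the apparent elasticity (or compliance) field is a
  statistically homogeneous, non-Gaussian, positive-definite matrix-valued
  random field with hyperparameters `b = (delta, ell, kappa_bar, mu_bar)`:
  a dispersion coefficient, a spatial correlation length (one value,
  `l1 = l2 (= l3)`), and the isotropic mean moduli.

The prior random-field family is the maximum-entropy construction for SPD
matrix fields: `C(x) = Lbar^T G(x) Lbar` with `Lbar` the Cholesky factor of
the mean Kelvin matrix and `G(x)` a normalized matrix field with identity
mean built from `n(n+1)/2 = 21` independent stationary Gaussian germs, gamma
transforms on the squared diagonal Cholesky entries, and
`sigma = delta/sqrt(n+1)`.  The dispersion coefficient obeys
`0 <= delta < sqrt((n+1)/(n+5))` (≈ 0.7977 for n = 6).  `delta` is the
dispersion of the *normalized* field `G`; the dispersion of `C` itself is
smaller by the mean-dependent factor
`sqrt((1 + tr(M)^2/||M||_F^2)/(n+1))`, which the test suite verifies by
Monte Carlo against the closed form.

All tensor algebra is done in Kelvin (Mandel) form — a `sqrt(2)` weight on
shear rows/columns — so matrix Frobenius norms equal fourth-order tensor
norms and plane-stress reduction is plain sub-block extraction of the
compliance matrix.  In 2D plane stress the *compliance* field is sampled
(6x6), reduced to its in-plane 3x3 block per element and inverted; in 3D the
stiffness field is sampled directly.

## Identification procedure

1. **Macroscale** (`identify_macro`): Nelder-Mead minimization of
   `J_macro(a)`, the spatial mean of the squared Frobenius strain mismatch
   between the model compression solve and the measured field.
2. **Mesoscale, per observation window** (`fixed_point_identify` /
   `genetic_identify`): minimize the vector cost
   `(J_delta, J_ell, J_h)` over a grid of `nV` equidistant points per
   coordinate:
   * `J_delta` compares the Monte-Carlo mean of the pseudo-dispersion
     `D = sqrt(V)/||mean strain||` of the model strain (meso Dirichlet
     problem driven by the measured boundary displacements) with the same
     statistic of the measured field.  The square root in `D` makes it a
     relative coefficient comparable to `delta` (`V` is quadratic in
     strain).
   * `J_ell` compares pseudo correlation lengths per axis: the empirical
     autocorrelation of the centered strain field along the axis, pooled
     over strain components (variance-weighted) and transverse lines,
     integrated by trapezoid to its first non-positive lag and clipped to
     the window extent.  This real-space integral estimator is the
     Wiener–Khinchin equivalent of a periodogram estimate and is robust on
     short windows; both the model and the experimental side use the
     identical estimator, so its bias cancels in the comparison.  Under
     plane stress the axis sum runs over {1, 2}.
   * `J_h` compares the Monte-Carlo mean effective stiffness `E{C_eff(b)}` —
     homogenized over an RVE with static uniform (traction) boundary
     conditions, rigid modes removed by minimal corner pinning — with
     `C_macro(a_macro)`.  `E{C_eff}` is the mean of per-realization
     stiffness inverses.
   The fixed-point pass minimizes `J_delta` over the `delta` grid, `J_ell`
   over the `ell` grid, then `J_h` over the `kappa_bar` and `mu_bar` grids
   (a pair of line searches sharing one Monte-Carlo batch, so one iteration
   costs `3*nV*Ns` model calls), and stops when the width-scaled residual
   between iterates drops below `tol = 1e-9` (grid solutions make this an
   exact-repeat test; the count includes the verifying iteration).  The
   genetic alternative evolves grid-index individuals (the published
   identified values all lie on the `nV` grid, so the discrete encoding
   matches the method as practiced) with tournament selection, uniform
   crossover, per-coordinate step/reset mutation and elitist nondominated
   sorting, and returns the Pareto front of *all* points evaluated during
   the run (an external archive, so no noninferior solution generated along
   the way is lost) plus the best compromise: the nondominated point
   nearest the origin of objective space.  On noisy coupled surfaces the
   best compromise can legitimately sit one grid step away from the
   fixed-point solution.
3. **Robustification across Q windows** (`robust_identify`): the per-window
   solutions are treated as independent draws of a random vector with a
   maximum-entropy prior — uniform for `delta` on `(0, delta_sup)` (so its
   robust value is the sample mean), gamma for `ell` (robust value = MLE
   mode `(shape-1)*scale`), and for `(kappa_bar, mu_bar)` gamma densities
   `h^-lambda exp(-lambda1 h)` and `h^-5 lambda exp(-lambda2 h)` sharing one
   shape hyperparameter `lambda < 1/5`, fitted by profile maximum
   likelihood.  With a zero-spread moduli sample the likelihood grows
   unboundedly as `lambda -> -inf` (the prior forbids deterministic
   moduli); `lambda` is floored at a configurable `lambda_min = -50` and
   the boundary hit is flagged.

Monte-Carlo estimates reuse one batch of germ realizations per line search
(common random numbers; germ seeds are independent of `b`), making grid
comparisons noise-consistent, and every stochastic indicator is reported
with a standard error.

## Synthetic-data generator

`insilico.generate_specimen` emulates the in-silico validation protocol:
one realization of the prior field sampled over the whole macroscopic
domain on a fine grid (4 cells per correlation length), a clamped-bottom /
uniformly-loaded-top plane-stress compression solve (Q4 elements, Kelvin
constitutive matrices, sparse direct factorization), nodal subsampling to a
coarse macroscale observation grid, and extraction of Q non-overlapping
fine-resolution mesoscale windows.  Gaussian germ fields are sampled
spectrally by circulant embedding on a padded periodic extension (padding 6
correlation lengths, capped at 6 domain extents), which reproduces the
target autocorrelation exactly at grid lags; realizations are seeded per
`(seed, index)` and bit-reproducible.

Default conditions (`reduced_validation_config`): domain 16 `ell` with
`ell = 125 um`, truth `b* = (0.40, 125 um, 13.75 GPa, 3.587 GPa)`, top
traction 5e7 N/m^2, Q = 4 windows of 4 `ell`, macroscale observation grid
16x16.  The full-scale preset (`paper_scale_config`, domain 80 `ell`,
Q = 16 windows of 8 `ell`) reproduces the published validation geometry and
runs in minutes rather than seconds.  A separable Gaussian pre-filter
(`gaussian_smooth`, sigma in grid units, reflective boundaries) reproduces
the smoothing applied to optical displacement images before
identification.

What the generator does *not* emulate: speckle rendering and the image
correlation algorithm itself, correlated measurement noise, specimen
misalignment, or any non-linear material response.  Passing tests therefore
demonstrate the statistical consistency of the inverse method on data drawn
from its own model class, not robustness to real measurement artifacts.

## Numerical choices

* Strains enter every indicator at element centroids; on rectangular
  bilinear elements the centroid strain equals the element average, which
  makes the spatial-average identity `mean(E_meso) = mean(eps_exp)` hold
  per realization to solver precision (the strongest single solver test)
  and keeps estimators mesh-consistent between model and data.
* Moduli are carried in GPa everywhere; FEM assembly converts to Pa so that
  tractions in N/m^2 and meters give displacements in meters.
* Desk-scale identification uses an RVE of 10 correlation lengths at 2
  cells per length (the full-scale presets keep the published 20 and 4);
  the induced shift in `E{C_eff}` was measured at ~1.5%, an order of
  magnitude below the `kappa_bar` grid spacing.
* Rank-deficient traction problems are detected by a post-solve residual
  check (SuperLU can factor a numerically singular system silently).
* Degenerate inputs: `D` is undefined for zero-mean strain fields (error);
  a strain field constant along an axis returns the axis extent with a
  `saturated` flag; all-equal robustification samples fall back to the
  common value and are flagged.

## Known limitations

* Only isotropic mean models (`nsym = 2`) are implemented; the general
  anisotropic mean parameterization and the fully anisotropic 63-length
  correlation structure are out of scope.
* The pseudo-correlation-length response saturates when candidate `ell`
  approaches the window size: on 4-`ell` windows the model-side mean
  estimate rises only ~25% while `ell` spans the admissible interval, so
  per-window `ell` identification is noise-limited; published campaigns
  show the same per-window scatter.  Identification should use windows of
  at least ~8 correlation lengths per side.
* Per-window identified hyperparameters scatter by one to three grid steps
  around the truth (single-realization window statistics); only the
  robustified cross-window estimate is accurate, which is precisely the
  motivation for the hyperprior + MLE stage.
* The `lambda` floor in the mean-moduli MLE is a modeling choice; with a
  degenerate sample the mode approaches the sample mean as the floor is
  lowered.
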