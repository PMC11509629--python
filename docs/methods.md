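# Methods

## Problem and models

AFM nanoindentation on soft matter infers a Young's modulus E from a
force-indentation curve F(h).  Real "sharp" AFM probes are not perfect cones:
the apex is a spherical cap of radius R (tens to hundreds of nanometres) that
merges tangentially with a conical or pyramidal body of half-angle θ.  At the
shallow depths required for thin samples (to avoid substrate effects) the cap
dominates the contact and neither the Hertz law nor Sneddon's cone law is
correct.

`bluntfit` implements the exact elastic contact models for these blunted
shapes and a simplified estimator that makes them usable in routine fitting.
Throughout, E* = E/(1 − ν²) is the reduced modulus of a rigid indenter on an
isotropic elastic half-space, and b = R cos θ is the transition contact
radius where the cap meets the body, reached at the transition depth
h_T = b²/R.

**Exact blunted cone** (contact radius a ≥ b):

    F = 2E* [ a·h − (a²/2tanθ)(π/2 − arcsin(b/a)) − a³/3R
              + √(a²−b²) ( b/2tanθ + (a²−b²)/3R ) ]

    h = (a/R)(a − √(a²−b²)) + (a/tanθ)(π/2 − arcsin(b/a))

For a < b the contact is Hertzian, F = (4/3)E*√R h^{3/2}, and the two
branches join continuously at a = b (the correction terms vanish
analytically there, forcing h(b) = b²/R).  The blunted k-sided pyramid is the
same pair of relations with every 1/tanθ term multiplied by (k/π)·sin(π/k),
which tends to 1 as k → ∞.  The depth relation is transcendental; the forward
map is inverted with Brent's method on the dimensionless variable a/b
(relative tolerance 1e−12, geometric bracket expansion from [b, 2b]).  The
dimensionless formulation matters: an absolute root tolerance of order 1e−12
metres would be ~1e−4 *relative* at nanometre scales.

**Simplified power-law estimator.**  Sneddon's general solution for an
axisymmetric profile f(r) = B·rⁿ is

    F = 2E* (n/(n+1)) [G/(√π B)]^{1/n} h^{1+1/n},
    G = Γ(n/2+1/2)/Γ(n/2+1),

with force exponent m = 1 + 1/n.  For a blunted tip B is depth-dependent
(B = 1/2R with n = 2 near contact; B = 1/tanθ with n = 1 at depth, with
different units).  The simplification replaces B^{1/n} by the interpolation

    B^{1/n} ≈ (2R)^{1/n−1} tanθ^{n−2} / f(n),   f(n) = n^{2−n},

which is dimensionally consistent for every n and exact at both anchors
(f(1) = f(2) = 1).  Substituting gives the closed-form prefactor

    c(n) = 2E* (n/(n+1)) (2R)^{1−1/n} (n·tanθ)^{2−n} [G/√π]^{1/n},

so a measured curve can be fitted to the trivial law F = c·h^m, the shape
exponent recovered as n = 1/(m−1), and E obtained by linear inversion of
c(n) ∝ E*.  The n = 1 and n = 2 reductions reproduce the Sneddon and Hertz
prefactors to machine precision, which pins the otherwise easy-to-misread
algebraic grouping; the consistency of c(n)·h^{1+1/n} with the general
axisymmetric law under the interpolated B is asserted in the tests.

**Accuracy of the simplification.**  The interpolation is validated for
h_max < 3R.  On noiseless full curves (depths from ≈0 to h_max) at the
validation geometries (θ = 35°, R = 100–200 nm, h_max ≤ 2R) the recovered E
is within ~2.5% of truth; across a wider grid (θ = 25–35°, h_max up to ~3R)
the bias stays within ~12%, worst near θ = 25°, h_max ≈ 1.5R where the
cap-to-body crossover is broadest.  Fits restricted to the blunted segment
[h_T, h_max] alone carry 4–6% bias.  The X-ratio diagnostic X = A·E*/c
quantifies this: it is the factor by which the estimator would mis-state E*
for a given geometry and fit window.  Note that X is ill-conditioned in the
fitted exponent (∂X/∂m ≈ 5 at n ≈ 3), so its third decimal depends on fit
minutiae; only its percent-level magnitude is meaningful.

**Depth-corrected sphere.**  For true spherical indentation up to h < R the
Hertz law is scaled by Z = c₁ + (3/4)c₂(h/R)^{1/2} + (1/2)c₃(h/R)^{3/2} with
c₁ = 1.014, c₂ = −0.09059, c₃ = −0.09431.  Z < 1 near h = R explains both
the modulus underestimation of naive Hertz fits and the sub-3/2 exponents
(1 < m < 1.5) observed on cap-dominated curves.

**Large depth (h > 3R).**  With h_T ≈ R, the deep contact radius expands to
r_c ≈ (2/π)[h·tanθ + R(1 − tanθ/2)].  Integrating the contact stiffness
S = 2E*·r_c gives the forward model
F = (2/π)E*[tanθ·h² + (2 − tanθ)R·h], which matches the exact model to 0.5%
at h = 3R and tends to Sneddon's law as h/R → ∞.  For inversion, the
stiffness identity S = m·c·h^{m−1} = 2E*·r_c is evaluated at h_max on the
fitted (c, m).

## Method selection

`select_method` implements the decision thresholds, checked in this
precedence order: h_max/R < 0.1 → Hertz with fixed m = 3/2; h_max < 3R →
simplified estimator with free m; h_max/R > 10 → Sneddon cone with fixed
m = 2; otherwise (3R < h_max ≤ 10R) → large-depth closed form.  A fitted
exponent well below 1.4 at large h/R is flagged as possible tip damage: a
flattened (worn or contaminated) apex has nearly constant contact area, which
makes F(h) nearly linear.

## Fitting choices

* Power-law fits are unweighted nonlinear least squares on the raw (h, F)
  samples (Levenberg–Marquardt, xtol = ftol = 1e−12), initialised from an
  ordinary log-log regression on the positive-force points.  Unweighted LS
  matches standard AFM practice; the fitted exponent is invariant under unit
  rescaling of h and F.
* Noise can push near-contact forces below zero; such points are kept in the
  fit (only the log-log initialisation needs positives).  Depths must be
  strictly positive: curves are assumed baseline-corrected with the contact
  point at the origin, and no contact-point detection is attempted (a reader
  hook drops negative-depth rows).
* The classic fit is a one-parameter linear projection: since the exact
  model force g(h) at unit E* is linear in E*, E*_LS = Σ F·g / Σ g².  It is
  exact to machine precision on noiseless self-generated curves and serves
  as the oracle for the simplified route.
* R² is defined as 1 − SS_res/SS_tot about the mean force, on untransformed
  data.
* The exponent guard m > 1 + 1e−6 rejects flat-punch-like data rather than
  inverting an undefined n = 1/(m−1).

## Synthetic data

The generator emulates the validation protocol: an elastic half-space with
E = 20 kPa, ν = 0.5, sphero-conical and 4-sided blunted-pyramidal tips
(R = 0.1–0.2 µm, θ = 35°), a 0.1 N/m cantilever, and additive i.i.d.
zero-mean Gaussian force noise.  The noise SD defaults to 2% of the curve's
maximum force, chosen so that the scatter of recovered moduli over 30
replicates is a few hundred Pa at 20 kPa, the order reported for such
simulations; an equivalent deflection-space mode (σ in metres, converted
through the spring constant) is available but off by default.  Depth grids
are uniform on [h_max/n_points, h_max] (zero depth excluded), 200 points by
default — fitted coefficients shift by <0.1% between 100 and 1000 points.
Everything is reproducible bit-for-bit under a fixed seed.

What the generator does *not* emulate: baseline/contact-point uncertainty,
deflection-sensitivity and spring-constant calibration error, hydrodynamic
drag, adhesion, viscoelastic drift, substrate stiffening, and cell
heterogeneity.  Passing tests therefore demonstrate correctness of the
contact models and estimators under ideal elastic conditions, not robustness
to the full error budget of live-cell experiments.

## Problem sizes

Default analyses use 200-point curves; batch validations use 30 replicates.
These sizes put sampling-density sensitivity of the fits well below the
percent level while keeping the whole suite fast.

## Known limitations

* No adhesion (JKR/DMT), viscoelasticity, or finite-thickness
  (bottom-effect) corrections — out of scope by design.
* The simplified estimator's bias grows with fit-window depth (~5% for
  windows reaching h ≈ 8R) and with cap-dominated windows at small θ.
* Blunted-pyramid curves are handled either exactly (side-factor models) or
  via the unchanged conical prefactor; no equivalent-angle remapping is
  applied by default (an effective θ can be supplied).
* Proprietary vendor file formats are not read; curves must be exported to
  two-column text.
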