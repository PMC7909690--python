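# Methods

This note documents the models implemented in `chreodkit`, the estimators
and their assumptions, the synthetic-data generator, and the numerical and
design choices that were genuinely open.

## The canalization model

Developmental canalization — the tendency of a perturbed individual
trajectory to return to its target — is modelled as mean reversion. In
continuous time the trait follows an Ornstein–Uhlenbeck process
dx = −θ(x − μ)dt + σ dW with stationary variance σ²/(2θ); at discrete
observation ages this becomes an autoregressive process of order 1. The
working model lets both the strength of canalization θ_t and the
individual-specific target trajectory μ_t vary over age:

    x_{t+1} − x_t = c_t − θ_t (x_t − μ_t) + ε_t,
    c_t = (baseline growth)_t + g_t + ζ_t μ_t.

θ_t is assumed common to all individuals at a given age (canalization as a
property of the shared genetic–developmental architecture), while μ_t
varies between individuals. Deviations d_t = x_t − μ_t, innovations ε_t,
new deterministic effects g_t and measurement errors η_t are zero-mean
Gaussian and mutually uncorrelated — these independence assumptions are
what make θ_t and the canalized variance estimable although μ_t is never
observed.

Key estimable quantities per age step:

* **Strength of canalization** θ̃_t: minus the OLS slope of
  (x_{t+1} − x_t) on x_t. Unbiased when all individuals share one target
  trajectory; with trajectory variance it converges to
  θ/(1 + var μ/var d) − ζ/(1 + var d/var μ), i.e. heterogeneity attenuates
  it toward zero and trajectory divergence pushes it negative
  (`theta_bias`).
* **Canalized variance**: the exact reduction is (θ² − 2θ)·var(d),
  maximal (most negative) at θ = 1. Since (θ² − 2θ) ≈ −1.5θ on
  0 < θ < 0.6 (maximum absolute error 0.0625 at the interval edge and at
  θ = 0.25), it is estimated as 1.5 × cov(x_{t+1} − x_t, x_t), which needs
  no estimate of var(d) and is not biased by var(μ) — only by long-term
  trends among the trajectories.
* **Variance decomposition**: the per-step change in cross-sectional
  variance splits into var(g) + (ζ² + 2ζ)var(μ) + (θ² − 2θ)var(d) + var(ε).
  The profile reports the cross-sectional variance, the canalized-variance
  approximation and "newly added variance". The latter is defined as the
  residual of the decomposition against the reported per-age
  cross-sectional variances, so closure is exact by construction for every
  dataset, including ones with missing grid values (where the pair set of
  a step differs from the per-age sets).
* **Measurement error**: independent error η inflates apparent
  canalization (regression to the mean): the expected estimate becomes
  (θ var d − cov(c, μ) + var η)/(var d + var μ + var η). The lag covariance
  is corrected by *adding* the replicate-estimated var η; θ̃ itself is not
  corrected by default — an error-corrected slope
  (cov + var η)/(var − var η) is available behind an explicit flag as an
  extension. Replicate variance is pooled per (individual, age) cell and
  across cells weighting by degrees of freedom.
* **Lag selection**: the partial autocorrelation of the trait with its own
  lags, computed by the successive-regression definition — per age pair,
  both endpoint values are regressed across individuals on the intervening
  values, residuals are standardized and pooled over age pairs, and the
  pooled residuals correlated. The approximate 95% band is
  ±1.96/√(pooled pairs). Higher-order reversion is estimated by the
  multiple regression of the change on p lagged values (negated
  coefficients).

## Multivariate canalization and compensation

For p traits the reversion coefficient is a p × p matrix Θ_t
(`x_{t+1} − x_t = c_t − d_t′Θ_t + ε_t`): diagonal entries are per-trait
canalization strengths, off-diagonal entries the strength with which a
deviation in one trait induces compensating change in another. Θ̂ is minus
the multivariate regression coefficient cov(x_t)⁻¹cov(x_t, x_{t+1} − x_t);
because this inverts a covariance matrix it is only computed when
n > p + 1 and the condition number is below 10¹⁰ (a pseudo-inverse is
available behind an explicit flag). Its canonical SVD (reduced-rank
regression) yields trait combinations with maximal strength of
canalization; the OLS slope of the projected change on the projected state
equals minus the corresponding singular value exactly.

For high-dimensional blocks the SVD of the cross-covariance matrix
cov(x_t, x_{t+1} − x_t) — two-block PLS — replaces the inversion. The
paired singular vectors (u_i, v_i) maximise the covariance between state
score x′u_i and change score (x_{t+1} − x_t)′v_i; that covariance equals
the singular value Λ_i and proxies the canalized variance of the feature
(1.5 Tr of the matrix gives the total, and Tr M = Σ Λ_i u_i′v_i ties the
per-dimension values to the trace). Since singular values are non-negative,
canalization versus compensation is read from u_i′v_i (≈ −1 pure
canalization, ≈ 0 compensation). The per-dimension strength-of-canalization
slope is computed univariate-style along u_i — minus the slope of the
change projected on u_i against the state projected on u_i — which is
independent of sign conventions, positive under canalization, and equal to
the univariate estimator when p = 1. A symmetry-departure index
‖Θ̂ − Θ̂′‖/‖Θ̂‖ is reported (the cross-covariance reading presumes roughly
symmetric compensation) without a pass/fail threshold, since none is
canonical.

Numerical conventions: each singular-vector pair is flipped so the
largest-magnitude entry of u_i is positive (deterministic output);
consecutive singular values closer than 10⁻⁸ relative to the largest are
flagged degenerate (only the subspace is identified); percent squared
covariance is Λ_i²/ΣΛ_j² × 100.

## Morphometric preprocessing

Landmark configurations are superimposed by generalized Procrustes
analysis: centre, scale to unit centroid size, rotate each specimen to the
current mean (orthogonal solution with determinant +1 — reflections are
never used), re-estimate the mean, iterate until the mean changes by less
than 10⁻⁸ (max 100 iterations; the first specimen seeds the mean, which
does not affect the fixed point to tolerance). The converged configuration
is put into a canonical orientation — principal axes of the mean shape,
with the 180° ambiguity resolved by the sign of the landmark farthest from
the centroid along the major axis — so the output is invariant to how the
input specimens were positioned, rotated or scaled. The reported mean is
the arithmetic mean of the aligned specimens; centroid sizes are reported
in input units (a pixel-to-mm factor is left to the user as data scaling,
e.g. via the TPS `SCALE=` record).

Semilandmarks slide along their outline curves to minimise thin-plate-
spline bending energy against the Procrustes mean: tangents are
finite-difference neighbour chords, the optimal tangential shifts solve a
small linear system exactly, and slid points are projected back onto the
specimen's original piecewise-linear outline so they cannot drift off the
curve. Sliding alternates with re-superimposition; the total bending energy
is monitored and a step that would increase it (possible through the
curve-projection) is rejected and iteration stopped, so energy is
non-increasing across outer iterations by construction. Curve endpoints
act as fixed anchors; curve membership is user-declared input.

## Preprocessing of longitudinal records

Irregularly timed records are interpolated onto a yearly grid by unweighted
local linear regression in a closed window of 2.5 years (the default;
values at the window edge are included). Windows with fewer than two
observations yield missing values; step estimators then use only
individuals observed at both ages of the step, recording n per step.
Group-mean removal (e.g. sexual dimorphism) subtracts the age- and
group-specific average; it requires at least two members per group, since a
singleton's variance contribution would silently vanish. Coefficients of
variation always use the raw, pre-centring values (centring would zero the
mean). All variances and covariances use the unbiased n − 1 denominator —
the motivating applications have small n.

## The synthetic-data generator

The generator emulates the structure of a classic longitudinal radiographic
growth study in which such models are applied: ~26 individuals split into
two sexes, yearly observations over ages 2–17, individual-specific target
trajectories (initial chreod variance plus per-step divergence and a
per-step group-mean offset producing sexual dimorphism), AR(1)
perturbations with an age-varying θ schedule, measurement-error variance
of the order of 1–2% of between-individual variance, and a separate
timing-variation simulator (location-shifted logistic growth curves) that
reproduces the rise-then-fall variance signature of growth-spurt timing
differences, which mimics canalization without any mean reversion. The
Ornstein–Uhlenbeck simulator uses exact discretization (the conditional
Gaussian transition), so step size never biases its distribution, and the
population simulators iterate the discrete model exactly as written above.
All draws flow from one seeded generator per simulation call; fixed seed
means bit-identical output.

What the generator does *not* emulate: non-Gaussian perturbations,
individual variation in θ_t, correlated-in-time perturbations, nonlinear
(asymmetric) reversion, or stage-homologous (rather than chronological)
sampling. Passing tests therefore show that the estimators recover the
model's own quantities under its assumptions — not that real growth data
satisfy those assumptions.

## Verification strategy and problem sizes

The test suite checks closed-form values directly, verifies estimators
against the generative truth by Monte Carlo (agreement within 3 Monte Carlo
standard errors), and pits implementations against independent oracles
(brute-force SVD of explicitly computed matrices; classical partial
correlation for the PACF). The acceptance script uses isogenic recovery at
n = 5000 with 200 replicates for θ ∈ {0, 0.25, 0.5, 1, 1.5}; bias- and
error-law grids at n = 2000 with 150 replicates; Θ recovery at p = 4 and
n ∈ {200, 2000, 20000} (10 replicates each, expecting the ~1/√n error
decay); 4000 independent OU paths for the stationary variance; these sizes
keep the full run under a minute on one core while leaving Monte Carlo
standard errors far below the effect sizes being checked. Bias-law
comparisons use the ratio-of-means estimator pooled over replicates (its
small-sample ratio bias is an order of magnitude below the Monte Carlo
standard error, unlike the mean of per-replicate ratios).

## Known limitations

* Iterative ARMA/Kalman-filter estimation is deliberately not provided;
  with unstable, nonlinear growth trajectories the direct regression
  estimators are the intended tool.
* θ̃ remains biased by trajectory heterogeneity; group-mean removal only
  eliminates the between-group part. The canalized-variance estimate is
  the more robust quantity.
* The 1.5 factor is fixed (not replaced by the exact 2 − θ̃ at the
  estimated θ̃); beyond θ ≈ 0.6 the approximation degrades.
* The PLS reading of canalization assumes roughly symmetric compensation
  and small Θ entries; the symmetry-departure index flags, but cannot fix,
  violations.
* Sliding semilandmarks uses the standard linearized step; strongly curved
  outlines with sparse semilandmarks can make the tangent approximation
  coarse.
* Landmarks are 2-D only.
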