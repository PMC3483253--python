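# Methods

This note documents the models and procedures implemented in `nwaymeta`,
the choices made where the methodology leaves room, and what the synthetic
test bed does and does not establish.

## Data model

Trajectory data live in a 3-way array with modes (observation, state
variable, time point). Time points are phases in [0, 1) of one oscillation
cycle on a shared grid; the real-time cycle length (period, hours) is
carried per observation. This phase representation makes cycles of
different periods commensurable; it also means "time-to-peak" summaries are
phase × period, anchored at the cycle-start crossing defined below. Ragged
per-observation time grids are out of scope by design — cycles are
interpolated to the common grid upstream.

## Preprocessing

Calibration data are mean-centred and standardised using calibration
statistics only; test data reuse them. For tensors two dispersion schemes
are offered because "standardise the 3-way array" is genuinely ambiguous:

* **columnwise** (default): every (variable, time) column of the unfolded
  array gets its own mean and sample (n−1) standard deviation. This matches
  common PLSR practice and makes the 2-way benchmarking exactly comparable.
* **slab**: per-column centring, but one pooled dispersion per state
  variable (root mean of its column variances), preserving within-variable
  waveform shape.

Neither is asserted to be "the" right choice; the scheme is an explicit
config field. Zero-variance columns are an error (naming the column), not
silently dropped. An optional natural-log transform per variable precedes
centring (used for outputs whose response is multiplicative; non-positive
values are an error).

## Trilinear PLS core

Factors are extracted sequentially. For factor *a* the second/third-mode
weight pair is the dominant singular pair of the J × K reshaping of
Xᵀu, which maximises covariance between the first-mode score
t = X(wᵛᵃʳ ⊗ wᵗⁱᵐᵉ) and the current response score u; for multiway
responses the response weights are obtained the same way from Yᵀt. Both
blocks are then deflated by their projection onto t (loading vectors
p = Xᵀt/tᵀt, c = Yᵀt/tᵀt). Consequences:

* scores are mutually orthogonal, so the inner relation Ŷ = T Cᵀ is an
  ordinary least-squares fit computable factor by factor;
* per-mode weight vectors are **not** orthogonal across factors (regional
  sensitivity maps inherit this caveat, see below);
* with a singleton third mode the procedure reduces *exactly* to 2-way
  NIPALS PLS2 — verified in the tests against an independently coded NIPALS
  oracle at 1e-8. All 2-way analyses (polynomial follow-up, benchmarking)
  reuse this code path.
* after rank(X) factors the response is fit exactly; noise-free trilinear
  data of known rank reach 100% explained response variance at that rank.

Sign conventions (for cross-platform determinism and sign-stable
sensitivity maps): each factor's second-mode regressor weight has its
largest-magnitude element positive; for multiway responses the third-mode
response weight is likewise pinned positive, which resolves the inherent
SVD sign ambiguity of the response pair. Weight iteration: initial u is the
response column with the largest sum of squares; convergence at relative
1e-10 on t, capped at 500 iterations.

Predicted response-side scores T̂_Y = T C are produced for downstream
classification. Several conventions exist for constructing this score
map; the standard least-squares inner relation is used here and surfaced
as `score_map` rather than hidden.

## Factor-count selection

Seeded 10-fold cross-validation with folds as equal as possible (remainder
spread one per fold). Candidate A = argmin of CV-MSE over 1..A_max,
truncated to the largest A such that *every* included factor adds at least
1% (configurable) of total cross-validated response variance; the floor is
one factor. Within each CV fold the model is fitted once at A_max and
per-A predictions are read off the score sequence.

## Hierarchical layer

Protocol (inverse first):

1. Global inverse model (tensor → parameters), CV-chosen factor count.
2. Fuzzy C-means (Euclidean, m = 2, tolerance 1e-6 on centre shift) on the
   global first-mode X-scores of all factors passing the 1% rule. Cluster
   labels are re-ordered by the first coordinate of their centres so
   labellings are reproducible. Crisp clusters with < 10 members are
   dissolved; their observations are excluded from regional fitting but
   remain in the global model.
3. QDA (default; LDA / Gaussian naive Bayes available) trained on the
   scores with crisp labels. QDA is the default because regional behaviour
   differs in covariance, not just location.
4. One regional model per retained cluster, with its own CV-chosen factor
   count. Regional models are fitted on the globally standardised data
   **re-centred around the cluster mean** (scaling stays global). This
   gives each regional model the intercept any local regression carries
   implicitly; without it the cluster's mean offset leaks into the first
   factors and corrupts regional loadings — observed directly on the
   synthetic fixture, where local centring restores the generator's
   sensitivity sign patterns.

The classical direction reuses the inverse clusters (classical response
factors are linear images of the design and reflect the parameter design
rather than output behaviour, so clustering on them is refused). New
observations without trajectories are classified via the bridge: predicted
classical response-side scores → second-order polynomial OLS (squares and
cross terms) → inverse score space → the inverse classifier.

Prediction modes: `most_probable` (default, the single regional model of
the posterior-argmax cluster) and `weighted` (posterior-weighted sum over
regional predictions). Posteriors, not fuzzy memberships, weight the sum so
that calibration and new observations follow the same path.

Cluster-count selection re-fits the hierarchy for each C in a range and
re-predicts the calibration set *as new observations* (classification
included); the chosen C is the smallest whose mean R² is within a margin
(default 0.02) of the curve maximum — an explicit, overridable rule in
place of by-eye judgement. CV factor selection is re-run per candidate C.
R² is squared Pearson correlation by default (per variable; for tensors per
state variable over all observations × time points), with 1 − SSE/SST
available by config; note the correlation form is blind to offset and sign,
which the tests document explicitly.

## Sensitivity estimation

For a classical model, sensitivity = (second-mode regressor loadings) ×
(second-mode response loadings)ᵀ summed over the model's retained factors
(no per-factor weighting), one matrix per regional model plus the global
one. On autoscaled data these are standardised effects. Two caveats are
inherited from the methodology and surfaced in the API docs: the loadings
are non-orthogonal, so factor contributions overlap; and the third mode is
marginalised, so a parameter acting with opposite signs at different phases
can cancel. Treat the maps as screens, confirmed where needed by the
2-way polynomial follow-up: parameters plus squares and cross terms
(autoscaled) against a single centred (optionally logged) output, with the
nonlinear block deflated against the first-order block (OLS with intercept)
in regional models so first-order and nonlinear effects separate;
per-term regression coefficients are the report.

## Designs

Multi-level binary replacement: each factor with L = 2^b equally spaced
levels becomes b bits; every bit is a non-zero GF(2) linear form over k
independent base columns, and the design is the image of the full 2^k
factorial. Per-factor independence of the forms guarantees exact balance
(2^k/L runs per level); overall rank k guarantees distinct rows. The
"optimised" confounding pattern minimises the maximum absolute pairwise
correlation among factor level columns over a fixed number of random
feasible assignments (deterministic under the optimizer seed); the chosen
masks serialise to JSON so a design is exactly reproducible. Levels are
derived from (min, max, L); rounded step-size displays are never used. Column sample variance of a balanced design is
d²(L²−1)/12 · n/(n−1) for spacing d, which is the analytic check the
acceptance script exercises. Monte-Carlo test designs draw each cell
uniformly from the factor's discrete level set.

## Limit-cycle extraction

Integration (scipy RK45, rtol 1e-8 / atol 1e-10) proceeds in windows after
a transient; cycles are delimited by upward crossings of the reference
variable through its running mean, refined by root bracketing on the dense
solution. The running-mean level is one concrete, offset-robust choice —
any level crossed once per cycle delimits the same period. Convergence requires, on the last
two complete cycles: relative period difference < 0.001, and, after
interpolation at 200 equally spaced phase points and per-variable min–max
rescaling to [0, 1], a summed absolute difference < 0.0001 over all
n_vars × 200 points (3200 for 16 variables). The second cycle is returned
un-rescaled. Failure reasons are explicit (integration failure, fixed
point, no crossings, period, synchrony, max time, default 4000 h ≈ 100
cycles of the demo oscillator). An amplitude floor (relative 1e-6)
distinguishes a decayed fixed point from numerical jitter. Convergence
decisions for the demo system are stable under halving the integrator
tolerances (period moves by ~4e-10 relative).

The built-in demo systems are a 3-state Goodwin oscillator (Hill
repression, h = 10; equal default rates v = 1, d = 0.1; oscillatory since
the effective Hill slope exceeds the secant bound of 8, verified in tests
by a Jacobian eigenvalue oracle) and a 16-variable variant with first-order
follower chains for exercising the pipeline at large-model width. Any user
ODE plugs in via the adapter contract (state names, RHS, initial state,
reference variable).

## Synthetic trilinear generator

The generator emulates the *structure* the method assumes: parameters drawn
uniformly, observations split into regimes by thresholds on the first
parameter, scores affine in the parameters with regime-specific maps and
well-separated regime centres, and a tensor that is an exact sum of
score × (variable ⊗ time) rank-one terms per regime plus Gaussian noise.
Defaults — 1500 observations, 8 variables, 32 phase points, 3 factors,
3 regimes, noise sd 0.05, centre separation 4, per-factor score scales
0.8^a — were chosen once for the test bed: a scaled-down analogue of a
large simulation campaign, small enough that the whole suite runs in
seconds, large enough that clustering, classification and regional fits
are well-conditioned.
Time loadings are non-negative so that truth sensitivity signs are
unambiguous; a synthetic period 18 + 12·p₁ h makes aggregated-output
summaries well defined.

What passing on this fixture does **not** show: real trajectory data are
not exactly trilinear, regimes are not separated by a single parameter, and
unfolding real data loses structure that the fixture's unfolded form does
not — which is why the benchmarking test asserts parity with the (lossless
here) unfolded 2-way variant and dominance only over lossy aggregation,
rather than dominance over both.

## Known limitations

* Only 2- and 3-way blocks are implemented; the API reserves the extension
  point but N > 3 modes, PARAFAC-constrained or orthogonalised variants are
  out of scope.
* No phase/shift correction preprocessing; differences in time-to-peak
  across observations therefore consume factors.
* No variance-based (Sobol-type) sensitivity indices and no uncertainty
  intervals on the loading-product sensitivities.
* Fuzzy C-means seeks spherical clusters in score space; alternative
  clusterings are deliberately not offered.
* Correlation-form R² scores offset, scale and sign-flipped predictions as
  perfect; switch to the SSE form when that matters.
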