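# Methods

## Model

A compartmentalised metabolic network at metabolic steady state is described
by its stoichiometric matrix `S` (balanced metabolites × reactions), flux
bounds, pool-size bounds, and per-reaction atom transitions.  Reversible
reactions are split into non-negative forward and backward sub-fluxes,
because isotopic label is transported in both directions even when the net
flux is one-way; the net flux reported everywhere is `forward − backward`.
All flux-space operations (sampling, estimation, profiling) act on
null-space coordinates `u` of the split system, `w = w₀ + K·u`, so
`S·w = 0` holds to machine precision at every iterate — steady state is a
parameterisation, never a penalty.  Exchange (backward) fluxes are thereby
ordinary free coordinates of the fit.

Labelling dynamics follow the EMU formalism: the state of an EMU of size
`n` is its MID, a probability vector over mass shifts M+0…M+n.  For each
EMU, influx terms are `coefficient · flux · (convolution of source MIDs)`
and the drain rate is the metabolite's total consumption flux divided by
its pool size; at steady state influx and drain balance EMU-wise (checked
as `balance_residual()`).  Boundary metabolites have constant MIDs fixed by
the tracer specification (per-atom labelled fractions; default fully
labelled, the indistinguishable-atom case of ¹³CO₂ / ¹⁵NO₃⁻ feeds).  The
initial condition is fully unlabelled at the tracer switch time.

## Numerical choices

- **Joint stacked solve.** All size levels are integrated together
  (block-triangular system) rather than level-by-level with interpolation.
  When no convolution couples two *unknown* EMUs the stacked system is
  affine with constant coefficients, and trajectories are computed exactly
  through the matrix exponential of the augmented generator
  `[[M, b], [0, 0]]` — this covers any network whose condensations draw
  only on tracer/boundary EMUs, and the whole toy chain.  Otherwise LSODA
  integrates the system at rtol 1e-8 / atol 1e-10, with one BDF retry at
  100× tighter tolerances on failure.
- **Simplex handling.** Raw solver output is validated (no component below
  −1e-6, sums within 1e-5 of one), then clipped at zero and renormalised;
  raw values are retained with `keep_raw=True`.
- **Brute-force oracle.** An independent full-isotopomer simulator
  (2ⁿ states per metabolite, capped at 4096 states) is kept solely as the
  correctness oracle: marginalising its isotopomer distributions to any
  EMU must agree with the EMU simulation (observed agreement ~1e-10,
  asserted < 1e-6).
- **Sampling.** Coordinate hit-and-run on the null-space coordinates with
  `100·dim` warm-up steps and `dim` thinning (the thinning is overridable;
  uniformity checks in the tests thin 40× to decorrelate the chain).
  Pool sizes are log-uniform within bounds, reflecting that concentrations
  spread over orders of magnitude.  Fluxes and pools are sampled
  independently.

## Estimation

`InstMfaModel.fit` minimises the weighted SSR with SciPy's
trust-region-reflective least squares over `(u, log c)`; pool sizes are
co-estimated on a log scale within their bounds by default or held fixed
when passed explicitly (recoverability experiments fix them at the
simulated truth, matching the setting in which concentrations are inputs).
Box bounds on the physical fluxes `w` cannot be expressed as a box on `u`,
so they are enforced by penalty residuals (weight ramped 1e3 → 1e5 when
needed) plus a final SLSQP projection of `u` onto the feasible polytope;
trial points whose clipping exceeds 1e-6 are assigned a flat high cost
without simulating, since a clipped vector no longer satisfies the steady
state the simulator assumes.  Finite-difference steps for the Jacobian are
1e-6 — far above the ODE-solver noise floor, which keeps the quasi-Newton
directions clean (this one choice is worth an order of magnitude in
iteration count).

Multi-start: starts are drawn by the sampling module, half from the chain
interior and half as Dirichlet mixtures of polytope vertices so that
low-flux corners are probed.  Every start runs under a capped evaluation
budget (`40·(n_params+1)`), and the two best basins are re-optimised to
full tolerance (gtol 1e-10, xtol 1e-12).  Explicit start points bypass the
capping, which keeps best-of-n monotonicity exact in tests.

`dof = n_measurements − n_free_parameters`; the reduced statistic
`L = SSR/dof` is accepted at level α iff it falls inside
`[χ²_{α/2,dof}, χ²_{1−α/2,dof}]/dof`, with `L` below the lower bound
flagged as over-fit.  Records with `sd = 0` are rejected outright rather
than infinitely weighted.

## Surrogates

One MLP per (EMU, time point) — hidden layers 216, 36, 6, ReLU, linear
output head with post-hoc clip-and-renormalise — maps the split flux
vector concatenated with (by default) log pool sizes, both standardised
per feature, to that EMU's MID.  Training uses adam, batch 32, 200 epochs,
learning rate 1e-3 with a step decay: the last quarter of the epoch budget
runs at lr/10, which removes most of the minibatch jitter that a constant
rate leaves (median holdout error on the toy grid drops from ~0.012 to
~0.005 at 5000 samples).  A fifth of the samples are held out per model;
`holdout_sd` — the standard deviation of held-out prediction errors — is
the fidelity figure that must stay below the measurement sd for the
surrogate swap to be harmless, and `validate_ensemble` recomputes it on
provably disjoint samples (hash check).  Predictions outside the training
hull raise an out-of-domain flag that the estimator counts.  The default
training-set size in the configuration is 10,000 samples at toy scale;
the acceptance experiment uses 5,000.

## Confidence intervals

Per-reaction profile CIs pin the net flux by adding one linear equality to
the null-space system and re-deriving the basis (the null space and the
minimum-norm particular solution are affine in the pinned value, so the
factorisations are cached per reaction).  The walk starts at 2% of |v̂|
(floored at 1% of the bound range), doubles until the re-optimised SSR
crosses `ssr_min + χ²₁(level)` (6.634897 at 99%), then bisects to
1e-4·(bound range); endpoints stopped by a flux bound are reported
censored, and profiles that dip below `ssr_min − 1e-6` raise a
local-minimum-hop warning.  Net fluxes are profiled for reversible
reactions (not the individual sub-fluxes).

## Evaluation

Recoverability: sample `n` true (flux, pool) pairs, simulate noisy
measurements, refit, and correlate per reaction.  Groups follow the
thresholds (0.3, 0.85) with the boundary values assigned to the middle
group.  Significance uses row permutations of the estimated matrix —
breaking the pairing while preserving both marginals — with add-one
smoothing, `p = (1 + #{null ≥ observed})/(n_perm + 1)`, and
Benjamini–Hochberg adjustment across reactions.  A fresh-samples null
would also be defensible; the permutation null was chosen because it is
exactly calibrated by construction.

## Synthetic data: what it does and does not emulate

The measurement generator simulates exact MIDs, adds i.i.d. Gaussian noise
(default sd 0.01), clips to [0, 1] and, by default, renormalises each MID
onto the simplex — as measured MIDs are reported.  Renormalisation
correlates the errors within a MID and shrinks their effective variance
(for a two-component MID by half), so fits against renormalised data show
`L` well below 1; chi-square calibration experiments therefore disable
renormalisation (rare cells that would leave the 1 ± 0.05 sum envelope
are still rescaled).  Values clipped at the 0/1 boundary retain about half
the nominal variance, which depresses mean `L` by a few percent on the toy
grid (measured mean ≈ 0.95 over 20 replicates).  Not emulated: natural
isotope abundance, instrument-specific heteroscedasticity, correlated
drift between time points, and compartment-mixing of signals — so passing
tests demonstrate estimator correctness under the stated noise model, not
robustness to real-instrument artefacts.

## Study conditions (built-in fixtures)

- *Toy network*: metabolites A–D, three reactions, fully labelled 2-atom
  feed, one free flux; atom arrows are a documented stand-in
  (R1: A(ab)→B(ab); R2: B(ab)→C(a)+D(b); R3: C(a)+D(b)→drain).
- *Rich network*: eight metabolites over cytosol and chloroplast, one
  reversible transport, one cleavage, one condensation with two internal
  substrates (exercising the nonlinear EMU path), 10 traced atoms total so
  the isotopomer oracle still applies.  All seven net fluxes and the
  exchange flux are structurally identifiable from the full-EMU
  measurement set at five time points; noiseless oracle-mode fits recover
  them to machine precision.
- Flux bounds [0, 10] (transport [−2, 10]), pool bounds (0.1, 10),
  time points 0.25–4 in units of typical pool turnovers, noise sd 0.01,
  measurement targets = full-atom EMUs of every balanced traced
  metabolite.  Problem sizes in the acceptance experiments (10 recovery
  distributions, 20 calibration replicates, 5000 training samples,
  50 CI replicates, 15 evaluation distributions) are the package's chosen
  desk-scale study conditions.

## Known limitations

- The isotopomer oracle is exponential in atom count and exists only for
  fixture-scale networks; at larger scale the EMU path is validated by its
  internal balance checks and simplex invariants.
- Surrogate accuracy degrades toward the edges of the sampled solution
  space; out-of-domain inputs are flagged, not extrapolated reliably.
- Profile CIs assume the one-parameter chi-square threshold; they are not
  simultaneous intervals.
- Hit-and-run mixing is adequate for low-dimensional polytopes; genome-
  scale sampling would need longer chains or specialised samplers.
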