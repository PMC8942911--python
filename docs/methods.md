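# Methods

## Data model and count reconstruction

The unit of analysis is a pooled 4-level rating-count vector per
(experiment, encoding condition, item class) cell. The bundled study used
equal trials per participant within each cell (word experiment: 27 targets
and 9 lures of each of three types per participant, groups of 27/26;
picture experiment: 18 targets, 6 category lures, 6 colour lures, 9
critical lures, groups of 35/36), so the participant-mean proportions in
the published summary table equal the pooled proportions exactly. Pooled
integer counts are recovered as round(pᵢ·N·T) with largest-remainder
rounding: floor every cell, then distribute the shortfall to the cells with
the largest remainders (ties to the lower rating index). This guarantees
the sum constraint; if any cell would need an adjustment of one whole count
or more, the table and design are inconsistent and reconstruction refuses.
For every bundled row the largest adjustment is below 0.5, i.e. the printed
3-decimal proportions are exactly consistent with integer counts.

Counterbalancing of stimulus-to-role assignment in the picture experiment
is irrelevant to pooled counts and is ignored. Reconstruction assumes
complete data (no excluded trials).

## UVSDT estimation

New-item strength is N(0, 1); old-item strength N(μ, σ²) with free σ;
criteria c₁ < c₂ < c₃. The likelihood is the product of two multinomials
whose cell probabilities are Gaussian CDF differences at the criteria.

* **Parameterisation.** Optimisation runs over (μ, log σ, c₁, log Δ₂,
  log Δ₃), so σ > 0 and criterion ordering hold by construction.
* **Starts.** A deterministic grid μ ∈ {0.5, 1.5, 2.5} × σ ∈ {1, 1.5}
  (criteria start at 0, 0.8, 1.6); Nelder–Mead with tight tolerances; best
  likelihood kept. The grid makes fits exactly reproducible.
* **Standard errors.** Inverse of the numerically differentiated observed
  information in the natural parameterisation (μ, σ, c₁, c₂, c₃);
  se(*d*ₐ) by the delta method with ∂*d*ₐ/∂μ = √(2/(1+σ²)) and
  ∂*d*ₐ/∂σ = −μ√2·σ·(1+σ²)^(−3/2). Observed (not expected) information is
  used; the two differ only at higher order here, and the resulting SEs
  reproduce the published table to the printed precision.
* **x꜀ convention.** *x*꜀ is c₂ on the new-distribution axis (the boundary
  between "probably new" and "probably old"), which matches the published
  values; z-transform conventions were checked and rejected.
* **Guards.** Cell probabilities are floored at 1e-12 inside the
  likelihood so a positive count in a vanishing cell yields a large finite
  penalty; degenerate inputs (all mass in one rating) are rejected up
  front.

Two-sample comparisons use the Wald statistic
z = (θ̂₁ − θ̂₂)/√(se₁² + se₂²) with a two-sided normal p-value, appropriate
for estimates from independent groups.

## MPT engine

A model is a set of independent multinomial trees; each branch is an
ordered product of parameter slots taken directly (θ) or complemented
(1 − θ) and ends in a rating category. Slots sharing a name share a free
parameter. Bindings can additionally equate differently named slots, pin a
slot to a constant, or express a slot as scale × base — the ratio
("shrinkage") reparametrization used for interaction tests, where the
scale factor λ is free and positive (unbounded above, since a ratio may
exceed 1) and only the product is required to stay inside (0, 1).

* **Evaluation.** Branch products are evaluated vectorised (padded factor
  matrix, sign mask for complements, bincount accumulation per category),
  which keeps a 19-parameter, 8-tree fit around 0.1 s and makes the
  200-replicate calibration runs cheap.
* **Fitting.** Product-multinomial ML by L-BFGS-B on logit-transformed
  unit parameters (log-transformed scale factors). Starts: one neutral
  anchor (all probabilities 0.5, scales 1.0) plus n_starts − 1 seeded
  random interior points, plus any caller-supplied warm starts (used for
  constrained refits and bootstrap resamples). A generic tree model has no
  generic moment estimator, so the deterministic anchor plays the
  reproducibility role a moment start would. Likelihood ties are broken by
  the lexicographically smallest parameter vector.
* **G².** 2·Σ obs·ln(obs/exp) with 0·ln 0 ≡ 0, computed against the
  saturated per-tree model; df = free categories − nominal free
  parameters, the convention of the standard MPT software this package is
  interoperable with (see the identifiability note below). ΔG² for nested
  models uses the χ² reference with the df difference; a ΔG² below −10⁻³
  raises, signalling an under-optimised general fit.
* **Boundary handling.** Unit estimates are clamped to [10⁻⁶, 1 − 10⁻⁶]
  and flagged; flags propagate to the fit object and the log.
* **Bootstrap.** Parametric: B per-tree multinomial resamples at the
  fitted probabilities, each refit warm-started at the point estimates;
  per-parameter SD and 2.5/97.5 percentile intervals; non-converged
  resamples are dropped, counted, and warned about above 5%. Default
  B = 1000.
* **Identifiability check.** Central-difference Jacobian of the stacked
  category probabilities at random interior points; the rank uses a
  tolerance of 10⁻⁶ times the leading singular value — far above the
  ~10⁻¹⁰ finite-difference noise floor, so noise is never counted as a
  direction. Model files use a plain-text .eqn-style format (one branch
  per line).

## The 2HTM variants and their identifiability

The joint two-condition model has, per condition, *D*ₒ, *s* and per lure
type (*D*ₙₖ, *n*ₖ), with the guessing parameters *g*, *a*ₒ, *a*ₙ shared
across conditions — guessing reflects the test situation, not the study
episode. That sharing is inferred from the degrees-of-freedom bookkeeping
(24 free categories − 19 parameters = 5 per experiment, 10 combined) and
is exposed as a `share_guessing` flag. The combined model concatenates the
two per-experiment joint models with no cross-experiment sharing.

**The shared-guessing 2HTM is locally non-identified.** There is an exact
one-dimensional ridge: perturb g and compensate with
(1 − *D*ₙₖ)′ = (1 − *D*ₙₖ)·g/g′ and a matching *n*ₖ adjustment in every
lure tree, (1 − *D*ₒ)′ = (1 − *D*ₒ)(1 − g)/(1 − g′) and a matching *s*
adjustment in every target tree — all 24 category probabilities are
unchanged (verified analytically and to 10⁻¹⁶ numerically). The Jacobian
rank is therefore 18 of 19 nominal parameters (36 of 38 combined), and
fixing g removes the ridge. Consequences:

* every likelihood-based quantity — G², all ΔG², p-values, expected
  counts — is a function of the identified manifold and is unaffected;
  the conventional df (nominal parameter count) is retained for
  comparability with the standard software and the published statistics;
* individual parameter *values* (and their bootstrap SDs) are meaningful
  only up to the ridge; recovery simulations accordingly check the fitted
  category probabilities, and per-parameter recovery after pinning g;
* equality constraints across conditions are *not* absorbed by the ridge
  (it moves both conditions' parameters together through the shared g),
  which is why the ΔG² battery is well behaved.

The interaction test reparametrizes *D*(colour) = λₑ·*D*(category) per
experiment. With λ₁, λ₂ free this is a pure reparametrization (identical
maximum likelihood, checked by a test); the ratio-invariance hypothesis
λ₁ = λ₂ costs one df. λ is reported per experiment (from the combined
fit) and under the constraint.

## Synthetic-data generator

The generator reproduces the study's design: two between-subject encoding
conditions with the printed group sizes and per-participant trial counts
(word experiment 27/9/9/9 over 27+26 participants by default; the picture
design is available as an `ExperimentDesign`), responses on the 4-point
scale from either the 2HTM branch process or the UVSDT strength process.
Each trial's rating is drawn from the exact branch-probability multinomial
of its item-class tree, which is distribution-identical to sampling every
detect/guess split independently. Participants are homogeneous by default,
matching the pooled-fitting assumption; an optional beta heterogeneity
knob (concentration κ, participant parameters ~ Beta(pκ, (1−p)κ)) is off
by default. Replicate r of seed s uses `default_rng([s, r])`, so any
replicate is reproducible in isolation.

Baseline parameter values (detection ≈ 0.45–0.60, high-confidence
responses ≈ 0.60–0.85, g ≈ 0.45, *a*ₒ ≈ 0.40, *a*ₙ ≈ 0.35) are typical of
pooled recognition-rating fits of this kind of design. Presets:
`null-interaction` (no condition differences), `word-like` (colour-lure
detection 0.35 under colour vs 0.75 under category encoding) and
`picture-like` (category-lure detection 0.75 vs 0.45, mirrored pattern).

What the generator does *not* emulate: stimulus-level structure (words,
door photographs, specific colours), sequential or practice effects, and —
by default — individual differences. Passing calibration tests therefore
shows that the estimator and test battery behave correctly when the model
family is true and participants are exchangeable, not that the 2HTM is the
true model of any real dataset.

## Problem sizes and numerical tolerances used in the test suite

The type-I-error and power calibrations run 200 replicates each at the
word-experiment sample size, fitting the general and the constrained model
per replicate (warm-started, two optimizer starts); the rejection rate of
the ΔG²(1) test at the 3.84 cutoff is required to fall within 0.05 ± 0.04
under the null preset and above 0.9 under the word-like preset. Recovery
checks use 100× the study's sample size. Bootstrap scaling uses a
3-parameter saturated tree with B = 300 (on the ridge-bearing joint model,
along-ridge wander adds variance to parameter SDs that does not scale with
n). Reproduction tolerances: |ΔG²| ≤ 0.5 and |G²| ≤ 0.3 (count
reconstruction rounds each cell by up to half a count; optimisers differ),
|*d*ₐ|, |*x*꜀| ≤ 0.03, Wald z ≤ 0.02, descriptives at printed precision.

## Known limitations

* Pooled fitting only; hierarchical/per-participant MPT or SDT estimation
  is out of scope.
* The df convention counts nominal parameters; because of the guessing
  ridge the effective dimension is one lower per experiment, so the χ²
  reference for the *absolute* G² is conservative by one df in the
  conventional reading. The published statistics follow the same
  convention, so all comparisons are like-for-like.
* The ratio reparametrization keeps λ·base inside (0, 1) by penalty during
  optimisation rather than by a hard bound; estimates near that edge are
  reported but their SEs are unreliable (as with any boundary estimate).
* The `.eqn` reader infers category order from first appearance, which may
  differ from the writing model's declared order; align counts by category
  label when interoperating.
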