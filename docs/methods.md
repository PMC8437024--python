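# Methods

This note records the models implemented in `paleotip`, the choices made
where the method left room, and what the synthetic-data tests do and do
not demonstrate.

## Setting and conventions

The package dates the radiation of a clade known only from fossils — the
motivating case is a superfamily of Ordovician brachiopods scored for 65
discrete shell characters across ~39 species-level exemplars of 38 genera
— by combining three sources of information on a fixed model cladogram:

* a discrete-character (Mk) likelihood of morphological change through
  time,
* fossilized birth-death (FBD) prior probabilities of branch durations
  under origination/extinction/sampling rates estimated from a large
  occurrence database,
* priors over each taxon's uncertain first appearance (FA).

Ages are in Ma before present ("older" = numerically larger), durations
in Myr, all rates per lineage-Myr. Trees are rooted; tips sit at first
appearances; zero-length terminal branches encode sampled ancestors.

## Occurrence-derived skyline rates

Collections are binned into stage-slices; a collection spanning a slice
boundary receives a uniformly drawn age within its bounds (one seeded
draw per collection, shared by co-occurring taxa). Turnover follows
three-timer logic: for slice *i*, taxa sampled in *i−1*, *i*, *i+1* are
three-timers; taxa sampled in *i−1* and *i+1* but not *i* are part-timers
and are direct evidence of non-sampling.

The classical uniform-rate sampling correction is replaced by a lognormal
distribution of per-taxon sampling rates fitted to each slice's counts.
Where enough range-through taxa exist (sampled on both sides of the
slice), their counts — zeros included, since a range-through zero is a
part-timer — are fitted as a plain Poisson-lognormal mixture over the full
slice duration. Otherwise the fit is a zero-truncated Poisson-lognormal
over taxa sampled in the slice, and a second pass corrects the exposure:
a taxon sampled within a slice was typically extant for only part of it,
so counts are refitted against the expected extant time implied by the
first-pass origination/extinction estimates (a mixture of
boundary-crossers with Exp(μ) residual lifetimes and within-slice
originators). Completeness marginals `E_r[1 − exp(−r·d)]` always use the
full slice duration *d*.

Per-slice rates: survival across slice *i* is estimated from the fraction
of range-through taxa re-sampled on the far side, divided by the
lognormal-marginal probability of being sampled there, and converted to a
per-Myr rate as `−ln(survival)/duration` (clamped at zero). Only the
sampling-completeness term is modified relative to classic three-timer
estimation; the origination/extinction corrections keep their form, and
the presence-based `3t/(3t+pt)` ratio is retained as a diagnostic. Slices
with no three-timers yield undefined rates, filled by linear
interpolation on the rate scale with flat extension at the ends (the FBD
integrator needs rates everywhere on the scan window). Rates deeper than
the focal clade's record are meant to come from a broader taxon set's
occurrence table; the module treats that as just another input.

Known limitation: with count-informed completeness, the classical
invariance "doubling every count at fixed incidence leaves origination
and extinction untouched" holds only asymptotically (as completeness
saturates); and conditioning range-through status on neighbouring-slice
sampling slightly favours well-sampled taxa when heterogeneity is large.

## FBD priors on branch durations

Under piecewise-constant origination λ(t), extinction μ(t) and sampling
ψ(t), the probability E(t) that a lineage alive at age *t* is never
sampled and leaves no sampled descendant satisfies the Riccati equation
`dE/dt = μ − (λ+μ+ψ)E + λE²` (t increasing into the past) with E = 1 at
the young edge of the window — there is no extant-sampling probability ρ
because every analysed taxon is a fossil. Within each constant-rate piece
the equation has a closed form (logistic in `exp(−ct)` with
`c = sqrt((λ+μ+ψ)² − 4λμ)`), stitched continuously across boundaries;
degenerate cases (λ = 0; ψ = 0 with λ = μ) use their own closed forms.

A branch spanning `[younger, older]` has log prior
`−∫ [ψ(t) + λ(t)(1 − E(t))] dt`: no sampled ancestor along the branch and
no birth on it that leaves sampled descendants. The integral is evaluated
in closed form per piece, with cumulative lookups so a branch costs O(1)
after setup. A tree's lnP FBD is the sum over branches (plus the stem
from the basal divergence when one is supplied). The prior is not
conditioned on the clade having been sampled; this is recorded in the CLI
output metadata.

## Mk morphological clock

Characters evolve under the k-state Mk model with uniform root
frequencies. Expected change on a branch is the time-integral of a
per-character per-Myr rate α(t): constant (strict clock, the phyletic
gradualism analogue) or stepping from α_early down to α_late at a
breakpoint age τ (early burst; default τ = 462 Ma). Among-character rate
variation uses four lognormal quantile-midpoint classes
(`exp(σ·z_p)`, p = 1/8, 3/8, 5/8, 7/8) with equal weights, so the class
median equals the nominal α; per-character likelihoods are averaged over
classes before logging. Missing and inapplicable cells are marginalized.
No ascertainment correction is applied by default — the fitted lognormal
spread predicts about as many invariant characters as morphological
matrices of this size contain — but a variable-characters-only
conditioning is available. Characters are unordered by default; an
ordered (stepwise) model can be switched on per character.

σ is estimated once, before dating, by fitting lognormal and gamma
Poisson mixtures to per-character Fitch step counts on the fixed topology
(the lognormal's fit is compared to the gamma's, and the expected number
of zero-change characters is reported); the fitted lognormal σ is then
held fixed during dating. Joint estimation is possible via the
re-optimization flag but is not the default.

The pruning implementation vectorizes over rate classes and over
characters sharing a state count, exploits the rank-one structure of the
Mk transition matrix (`P·v = x·v + (1−x)·mean(v)`), rescales partials per
node, and caches per-node partials and messages so that moving a single
node age re-evaluates only the path to the root — the operation the node
dating performs thousands of times.

## Posterior assembly, FA priors, and the scan

For a taxon with N candidate first-appearance collections, each replicate
draws one age per collection uniformly within its bounds (shared
collections get one draw used by every linked taxon); the taxon's FA is
its oldest drawn candidate. The prior that the replicate's FA set is the
true one is a per-taxon beta(1, N) mass over candidates in stratigraphic
order: the j-th oldest candidate carries
`(1−(j−1)/N)^N − (1−j/N)^N`, uniform when N = 1. The ranking is by
midpoint of the candidate's age bounds (ties by older bound, then
collection id), which keeps masses summing to one while the drawn ages
decide which candidate actually provides the FA.

The posterior is assembled additively in log space,

    ln posterior = lnP FAs + lnL α + lnP FBD ,

and the search is a deterministic grid over basal divergence ages
(defaults 466–521 Ma, 1 Myr step) with nested optimization, not MCMC.
Given a basal age and a replicate: internal node ages maximize
lnL α (+ lnP FBD for the FBD models) by coordinate ascent — each node
within (oldest descendant, parent age) by golden-section to 0.01 Myr,
coarse first sweep, alternating sweep direction, stopping when a sweep
gains < 0.02 log units — and clock rates maximize lnL α by bounded search
on the log scale (tolerance 1e-4), alternating twice with the node
dating. The clock is optimized on the first replicate of each grid age
and shared across replicates (a flag re-optimizes per replicate); later
replicates and neighbouring grid ages warm-start from the previous
solution. The per-model surface averages replicate posterior masses,
each weighted by its FA prior.

Three models are compared. The FA-priors-only strict clock ignores the
FBD term during optimization and in its surface, but its reported
decomposition still includes the lnP FBD of the resulting tree, so every
row of the output table obeys the additivity identity. Credible
intervals are highest-posterior-density sets on the grid (ties resolved
toward the higher-posterior point). Bayes factors are ratios of
grid-summed posterior masses; because two models can favour different
divergence times, a conditional variant (one model's surface compared at
the two favoured ages) is also provided, and the definition used is
written into the CLI output metadata.

## Cladogenesis rates on the dated tree

An internal branch ends in the divergence that defines it. Its
likelihood under a hypothesized cladogenesis rate λ(t) is the probability
of exactly one *sampled* cladogenetic event — Poisson with mean
`Λ = ∫ λ(t)(1−E(t)) dt` — times the probability of zero sampled
ancestors, `exp(−∫ψ)`. E here is computed with the origination rate set
to `species_per_genus × λ(t)` (default 2): a genus-level divergence is
only observed if at least one species of the side clade is ever sampled.
A terminal branch ends at its taxon's first appearance — a sampling
event, not a divergence — so in whole-tree fits it contributes zero
sampled divergences and zero sampled ancestors (its terminating sampling
density does not depend on λ). Zero-length sampled-ancestor attachments
are excluded: they have no duration to inform a rate. The per-branch
maximum-likelihood rates (the rate-profile scatter against branch
midpoint age) use the one-divergence likelihood for every
positive-duration branch.

Two forms are fitted: constant λ₀, and exponential decay
`λ(t) = λ₀·exp(−κ(t₀−t))` anchored at the basal divergence t₀ with κ
bounded in [0, 2]/Myr and discretized at 1 Myr for the E computation.
The decay fit is initialized from the constant fit (κ = 0), so its
likelihood cannot fall below the constant one, and the two are compared
by a likelihood-ratio test against χ² with one degree of freedom. The
extinction and sampling rates stay fixed at their occurrence-derived
values throughout; the species-per-genus multiplier is used only here,
never in the dating priors.

## Synthetic data

The generator forward-simulates the budding birth-death-sampling process
the analysis assumes: one lineage enters at the clade origin (default
470 Ma, with rates defined back to 521 Ma on 3-Myr slices), events follow
the piecewise-constant skyline (default origination 0.8/lineage-Myr
during the 470–462 Ma radiation pulse and 0.3 outside it, extinction
0.35, sampling 0.5 — species-level turnover plausible for early
Palaeozoic brachiopods), and fossilization events are Poisson in each
lineage, with optional lognormal among-lineage rate multipliers (default
scale 1). Characters evolve along the reconstructed tree under the Mk
clock (default early burst 0.03 → 0.01 changes per character per Myr at
τ = 462 Ma, σ = 1, 65 characters, ~10% missing). Occurrence events are
grouped onto 0.25-Myr collection horizons with a few localities each, age
bounds ±1 Myr; a taxon's FA candidates are its collections whose bounds
genuinely overlap its oldest collection's bounds. A genus-collapsing step
(sizes 1 + Poisson, mean 2 species per genus, grouped along the tree)
emits genus-level exemplars for the dating stage, mirroring how
genus-level analyses use species-level occurrence data.

What the simulations do not emulate: real character correlation
structure, biogeography, taphonomic covariation of sampling with
environment, or taxonomic-opinion noise in occurrence databases. Passing
recovery tests therefore show internal consistency of the estimators
under the model's own assumptions, not robustness to violations of them.

## Problem sizes and numerics

The default synthetic bundle is sized like the motivating study (~40
analysed genera, 65 characters, a few thousand occurrence rows); its
scan covers ~6 grid ages with 3 FA replicates, which the full
pipeline completes in a few minutes on one core. Recovery suites use 10–20
seeded replicates at 15–40 sampled taxa. Quadratures: lognormal
marginals use 64 (sampling fits) or 128 (rate-spread fits)
quantile-midpoint nodes. The FA-weighted replicate averages use
log-sum-exp; pruning partials are rescaled per node; Brent/golden-section
tolerances are 0.01 Myr (node ages), 1e-4 (log rates); FBD branch
integrals are closed-form with cumulative lookups. All stochastic steps
derive from a single master seed (per-replicate seeds by fixed prime
increments, kept below 2³¹).

## Known limitations

* The scan optimizes node ages by coordinate ascent; on ladder-like trees
  it can stop within ~1–2 log units of the joint optimum. Model ranking
  is robust to this because all models share the same procedure.
* The sampling-rate exposure correction is a moment-style approximation
  (first-pass turnover rates, stationarity within a slice), not a joint
  likelihood over lifetimes.
* The cladogenesis likelihood scores branches independently; it ignores
  the survivorship conditioning induced by the reconstructed tree, which
  leaves a mild upward bias in decay-rate estimates.
* Bayes factors depend on the scanned grid through the marginal masses;
  the conditional variant is provided for cross-checks.
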