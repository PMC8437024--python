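# paleotip

Bayesian tip-dating of fossil-only clades with fossilized birth-death
(FBD) skyline priors, Mk morphological clocks, and occurrence-derived
diversification rates.

`paleotip` is for palaeobiologists asking *when* a clade known only from
fossils began to radiate, and *how* — at a constant rate of anatomical
change (a strict morphological clock) or with an early burst of elevated
rates. The motivating case is an Ordovician brachiopod superfamily whose
genera are scored for discrete shell characters on a fixed cladogram and
whose fossil record comes from a large occurrence database, but every
stage is generic: any clade with a model phylogeny, a discrete character
matrix, and dated fossil collections fits.

## The model

The log posterior of a divergence-time and rate hypothesis decomposes
additively:

    ln posterior = lnP FAs + lnL α + lnP FBD

* **lnP FAs** — each taxon's first appearance (FA) is uncertain among *N*
  candidate collections with age bounds; a replicate draws one age per
  collection and the prior mass of the resulting FA set is beta(1, *N*)
  per taxon over candidates in stratigraphic order (uniform when *N* = 1).
* **lnL α** — Lewis's Mk model with uniform root frequencies; expected
  change on a branch is the time-integral of α(t), either constant
  (strict clock) or stepping from α_early to α_late at a breakpoint τ
  (early burst); among-character rate variation enters as four lognormal
  quantile-midpoint classes whose median is the nominal α.
* **lnP FBD** — under piecewise-constant origination λ(t), extinction
  μ(t) and fossil-sampling ψ(t) estimated from occurrence data by a
  modified three-timer method (lognormal among-taxon sampling rates
  replacing the uniform-rate correction), the probability of sampling no
  ancestor along a branch and no sampled side clade from it is
  `exp(−∫ ψ + λ(1−E) dt)`, with E(t) the closed-form piecewise solution
  of `dE/dt = μ − (λ+μ+ψ)E + λE²` and E = 1 at the young edge of the
  record (all tips are fossils).

The basal divergence age is scanned on a grid; node ages and clock rates
are optimized deterministically (coordinate ascent + golden section), FA
uncertainty is integrated over seeded replicates weighted by their
priors, and models are compared by Bayes factors over grid-summed
posterior masses. A final stage reconstructs per-branch cladogenesis
rates on the dated tree and tests constant against exponentially
declining origination with a likelihood-ratio test.

A forward simulator (`paleotip.synthetic_data`) generates the whole data
constellation — birth-death-sampling trees, heterogeneous fossil records
grouped into collections, FA candidate sets, Mk character matrices, and a
background fauna for rate estimation — so the pipeline runs end-to-end
without any database access.

## Worked example

Simulate a study-sized data set (about 40 genera, 65 characters, a few
thousand occurrences), estimate rates, and scan the three models:

```sh
paleotip simulate --seed 1 --out-dir bundle
paleotip rates --occurrences bundle/occurrences.csv \
               --timescale bundle/timescale.yaml --seed 1 --out-dir out
paleotip date  --tree bundle/tree.newick --matrix bundle/matrix.nex \
               --fa-candidates bundle/fa_candidates.csv \
               --rates out/rates.csv --config bundle/config.yaml \
               --out-dir out
```

`out/model_posteriors.csv` then holds one row per model (this is the
actual output for seed 1):

```
                                model  basal_divergence  ci_older  ci_younger  lnP_FAs  lnL_alpha  lnP_FBD  ln_posterior
             Strict Clock + FA Priors            473.68    479.68      473.68   -26.22    -638.76  -446.79      -1111.76
Strict Clock + FA Priors + FBD Priors            470.68    470.68      470.68   -35.77    -599.47  -186.06       -821.30
 Early Burst + FA Priors + FBD Priors            470.68    470.68      470.68   -35.77    -594.92  -184.85       -815.54
```

Read: with FA priors alone the clade seems to diverge ~3 Myr earlier
than the FBD-informed models allow; adding branch-duration priors pulls
the divergence toward the fossil record; the early-burst clock fits the
characters better at no prior cost, beating the strict clock by ~5.8 log
units (its fitted early/late rate ratio is ≈ 2.2 against a simulated
truth of 3, and the simulated clade's true root age of 469.7 Ma lies
1 Myr below the scan floor of this run). Every row satisfies
`ln posterior = lnP FAs + lnL α + lnP FBD` exactly.

The remaining stages:

```sh
paleotip priors --tree out/dated_early_burst_and_fa_priors_and_fbd_priors.newick \
                --rates out/rates.csv --out-dir out
paleotip clado  --tree out/dated_early_burst_and_fa_priors_and_fbd_priors.newick \
                --rates out/rates.csv --out-dir out
```

write per-branch FBD log-priors, per-branch origination-rate MLEs, and
the constant-versus-decay comparison (`out/clado_fit.json`).

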