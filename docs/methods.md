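# Methods

This note documents the models, rules and numerical choices behind
`poolscreen`: what each stage assumes, which parameters matter, what the
simulators emulate (and deliberately do not), and where the design was
genuinely open.

## Screen simulation

The simulator collapses the multi-day pooled competition to a single
endpoint abundance model. For hairpin *h* of gene *g* in biological
replicate *r*:

* `N0 ~ Poisson(representation)` cells seed the replicate
  (default `representation = 1000` cells/hairpin, the library coverage
  maintained through selection). Both arms of a replicate share `N0`
  because the culture is split after selection, so seeding noise cancels
  in the ratio.
* control-arm endpoint: `N0`.
* stress-arm endpoint: `N0 · survival · 2^(δ_g · e_h + ε)`, with
  `survival = 0.5` by default (the stress dose is titrated to roughly
  halve cell number), `δ_g` the gene's signed log2 fitness effect of full
  knockdown (0 for neutral genes), `e_h ~ Uniform(0.5, 1)` the hairpin's
  knockdown efficacy, and `ε ~ N(0, noise_sd²)` lognormal biological
  replicate noise on the log2 scale (`noise_sd = 0.25` by default).
  Growth dynamics within the treatment window are unobservable from
  endpoint arrays, so they are deliberately absorbed into the single
  factor `2^(δ·e)`.
* array readout: a shared lognormal PCR-bias factor per probe multiplies
  both channels (sd 0.25 log2 units — it cancels in the ratio, as in the
  real protocol where both samples pass through the same amplification);
  channel foreground = gain × abundance + additive lognormal background
  (median 50 intensity units, log-sd 0.5, gain 1 unit/cell). The recorded
  background column equals the additive contamination, so
  foreground − background recovers the signal exactly; background noise
  on the net intensity is not modeled.
* competitive hybridization (`equalize_channel_mass=True`, the default):
  equal amounts of labeled product are hybridized per channel, so each
  channel's abundances are rescaled to a common total per replicate.
  Measured ratios therefore report *relative* abundance and neutral genes
  center at R/G ≈ 0 — this is why the fixed ±0.7 hit threshold is
  meaningful. With the flag off, the raw ratio carries `log2(survival)`
  for neutral genes (useful for testing the abundance model itself).

Per-hairpin efficacy is drawn rather than fixed so that multi-hairpin
concordance — the hit rule's premise — is a real property: a gene's
hairpins agree in direction but differ in magnitude. Infection dynamics
(MOI, per-cell multiplicity) are not modeled beyond Poisson seeding:
puromycin selection makes pre-selection dynamics unobservable. No
dye-swap, hybridization cross-talk, saturation or spatial artifacts are
simulated, so passing recovery tests says nothing about robustness to
those real-array pathologies.

## Preprocessing

* **Background filter**: a probe row is discarded when either channel's
  foreground is *strictly* below `fold × background` (default fold 2; a
  value exactly at the threshold survives). The rule is applied per
  replicate independently, so a hairpin's R/G entry is missing only in
  replicates where it failed — this maximizes retained data and matches
  per-array filtering practice. Which channel(s) the original rule tested
  is not documented anywhere we know of; both-channels is the default,
  single-channel variants are a flag.
* **R/G ratio**: `log2((cy5_fg − cy5_bg)/(cy3_fg − cy3_bg))`. Background
  subtraction before the ratio is a config switch (`subtract_background`);
  it is on by default because the simulated channels carry additive
  background. Non-positive net intensities yield missing entries (counted
  by QC), never exceptions.
* **Quantile normalization** is applied to the replicate columns jointly
  *within each sub-pool's probe set* (each sub-pool was a separate
  physical array); normalizing all pools as one group is a flag. The
  implementation follows the standard reference-quantile construction:
  the reference is the mean of the per-column empirical quantile
  functions on a common probability grid, and each value maps through the
  reference at its plotting position `rank/(n_obs − 1)` computed among
  that column's non-missing values only (no imputation). Ranks are
  ordinal with stable tie order. On complete data this is exactly
  "replace the k-th order statistic by the mean of all columns' k-th
  order statistics": all columns end with identical sorted values, and
  the operation is idempotent. Columns with fewer than two non-missing
  values pass through unnormalized with a QC warning.
* **QC** reports pairwise replicate Pearson correlations over jointly
  non-missing entries (undefined below 3 shared points), the discarded
  fraction, the empirical R/G range and a histogram.

## Hit calling

A hairpin event requires `|R/G| > τ` (τ = 0.7, strict) in at least
`min_reps = 2` of the replicates **and** replicate CV < 0.5 (strict),
where CV = sample (n−1) standard deviation over |mean| of the log2
ratios. The absolute mean in the denominator is a deliberate choice: a
plain "stdev/ave" is sign-ambiguous on log ratios, and the absolute value
makes the criterion scale-free and sign-safe; a zero mean leaves the CV
undefined and produces no event. Thresholds fail on exact ties, mirroring
the strict inequalities of the printed rule.

A gene is protective when ≥ 2 hairpins are enriched, lethal when ≥ 2 are
depleted. Hairpin pairs must share a direction — mixed-direction pairs
are biologically incoherent for a knockdown phenotype — and a gene whose
distinct hairpin subsets satisfy both directions is flagged ambiguous and
classed none (`--allow-mixed-direction` disables this). Cross-condition
overlap intersects protective and lethal hit sets separately.

No p-values are attached to hit calls: the rule is deterministic, and its
operating characteristics are measured instead (see the null-calibration
test, which compares the pipeline's gene-hit rate on a fully neutral
screen with a direct Monte-Carlo estimate of the rule's crossing
probability).

## Second-best-hairpin ranking

Per-hairpin score = mean log2 R/G over non-missing replicates (the
simplest faithful log-fold-change statistic). Gene score = the *second*
most extreme hairpin score in the tested direction; a single off-target
construct therefore cannot carry a gene. Genes with fewer than two scored
hairpins are excluded.

The null is built by drawing, for each hairpin-count stratum *m*, B
pseudo-genes of *m* scores sampled without replacement (within a draw)
from the global hairpin-score pool and taking their second-best. The
stratification matters because the distribution of a second order
statistic depends on *m*. `NES = (score − μ_null)/σ_null` per stratum;
`1/NES` is reported as the conventional proxy. B defaults to 1000 (desk
scale); the permutation stream is seeded. Ranks order genes from most to
least extreme in the tested direction, NaN NES last, ties broken
lexicographically by gene id for determinism. A degenerate stratum (null
sd 0, e.g. all scores identical) reports NES as undefined rather than
crashing. The exact normalization used by the original GENE-E/RIGER
tooling is not published; this stratified z-normalization is this
package's documented stand-in.

## Expression signatures

* **Zero transformation** subtracts each gene's mean over designated
  scramble-control samples, turning log2 expression into log2 change
  versus control; it is idempotent for fixed controls.
* **Occurrence/fold filter** keeps genes with `|log2 value| ≥ log2(fold)`
  in at least `min_arrays` samples (defaults 1.7-fold, 6 arrays). The
  threshold is read on the *linear fold* scale by default —
  "values greater than 1.7" on zero-transformed log2 data could also mean
  1.7 log2 units, and `--filter-scale log2` selects that reading. The
  occurrence comparison is inclusive (≥), matching common occurrence-
  filter semantics; a strict mode exists.
* **Signature creation**: genes ranked by absolute signal-to-noise ratio
  `(m1 − m0)/(s0 + s1)` (class sds floored at 1e-6 and logged when
  degenerate), top `n_sig = 100` retained; SVD of the selected,
  training-mean-centered submatrix gives a factor basis; class membership
  is fitted on the top `k = 2` factor scores by ridge-penalized probit
  (ridge 1e-3, intercept unpenalized, solved by BFGS on the penalized
  likelihood). The ridge keeps coefficients finite on perfectly separable
  6-to-9-sample training sets. `n_sig` and `k` are this module's own
  documented defaults (the original GenePattern module's defaults are not
  printed) and are exposed in config.
* **Projection** restricts a profile to the signature genes, centers,
  maps through the basis and the probit link. Centering defaults to the
  *training* gene means, which presumes the test data are
  zero-transformed on the same scale as training. An external cohort with
  no scramble controls cannot be placed on that scale; `center="test"`
  instead centers each gene on the cohort's own mean — the no-controls
  analogue of zero transformation — and is what the cohort pipeline uses.
  Whether to regress raw or logit-transformed probabilities is another
  open point; raw probabilities are used.
* **Signature regression**: ordinary least squares of one signature's
  per-sample probabilities on the other's, slope t-test p-value; a
  zero-variance predictor reports an undefined slope.

The expression simulator plants two knockdown programs of `n_de = 50`
genes (±`effect_size` log2 shifts, Rademacher signs) sharing 60% of their
genes with identical signs, on i.i.d. Gaussian noise (sd 0.5) over a
baseline of ~2000 genes; the cohort draws a latent activation
`a ~ Uniform(0, 1)` per sample applied to the union program. Real tumor
cohorts have correlated gene-gene structure, batch effects and
heteroscedastic noise, none of which is emulated — recovery results bound
what the method does under its own assumptions, not on real arrays.

## Metabolite summaries

Raw values are divided by per-sample protein content first; everything
downstream is scale-invariant to joint rescaling of raw values and
protein. Hypoxia change per (cell line, metabolite) is the ratio of
replicate means, `fold = mean_H / mean_N` (percent = (fold − 1)·100), with
SEM propagated by the delta method,
`sem ≈ fold · sqrt((sem_H/m_H)² + (sem_N/m_N)²)` — appropriate at n = 3.
Substrate/product ratios are computed per replicate and then averaged
(mean ± SEM), matching per-replicate error bars; ratio-of-means is a
flag. Zero denominators exclude the sample with a log entry rather than
failing.

## Pipeline and problem sizes

All orchestration flows from one YAML config with explicit seeds; every
run writes its resolved config and per-stage record counts next to its
outputs, and identical configs produce byte-identical files. Child seeds
are derived from the master seed via `SeedSequence`.

Default simulated sizes are the study conditions the package emulates:
500 genes × 4 hairpins in 6 pools, triplicates, 20 + 20 planted genes at
|δ| = 1.2 with efficacy ~ U(0.6, 1.0) and noise sd 0.25 for the screen;
2000 genes, 50 DE per program, 6 + 6 training samples and a 130-sample
cohort for signatures; 2 cell lines × 2 conditions × 3 replicates for
metabolites. The null-calibration check uses 2000 neutral genes. At these
sizes the full test suite and the acceptance script each run in seconds
on one CPU.

## Known limitations

* The background model is idealized (recorded background equals the
  additive contamination), so the 2-fold filter's false-negative behavior
  under background *estimation* error is untested.
* The permutation null treats hairpin scores as exchangeable across
  genes; strong genome-wide effect structure would violate this.
* NES values for genes sharing a stratum are computed from one shared
  null draw per stratum, so they are correlated across genes (as in any
  pooled permutation scheme).
* The probit signature assumes factor scores capture class separation in
  k = 2 dimensions; programs with more complex geometry would need larger
  k, at the cost of stability at tiny n.
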