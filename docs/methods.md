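# Methods

`aposcape` quantifies how facultatively apomictic plant populations divide
their reproduction between a sexual (meiotic) and an asexual (aposporous)
pathway, how efficiently each pathway converts its ovule-stage
representation into seeds, what that costs in maternal fitness, and how the
balance responds to climate.  This note records the models, the defaults
and the design decisions, in the order the pipeline runs.

## Reproductive pathway model

Each scored ovule falls in one of four classes: MES-only (a meiotic embryo
sac), AES-only (one or more aposporous sacs), mixed (both), or
aborted/absent.  Writing `nm_only`, `na_only`, `nma`, `nab` for those
counts and `nt` for their sum:

* **Reproductive potential** of a pathway is the fraction of ovules
  carrying its sac: `(nm_only + nma)/nt` for sexuality,
  `(na_only + nma)/nt` for apomixis.  Mixed ovules count toward both, so
  the potentials may sum to more than 1 — that surplus is exactly the arena
  of within-ovule competition.
* **Observed proportions** default to the competing-only basis
  `nm_any/(nm_any + na_any)`; a shared-credit basis
  `(nm_only + 0.5 nma)/(nm_only + na_only + nma)` is offered for
  sensitivity analyses.  Seed-stage observed proportions are
  `sexual/(sexual + apomictic)`.
* **Expected seed proportions** under the independence null — both sac
  types develop independently and form a seed with the same probability —
  credit mixed ovules half to each pathway: `(nm_only + 0.5 nma)/nt` and
  `(na_only + 0.5 nma)/nt`.  Their sum falls short of 1 by exactly the
  aborted fraction.

  The two readings of "ovules with a MES" (any-MES for potentials,
  MES-only plus half the mixed class for expectations) are deliberate:
  only that combination lets potentials sum above 1 while keeping expected
  proportions on the probability scale.
* **Pathway efficiency** is observed/expected per pathway; 1 means the
  pathway converts its expected share exactly, values above 1 mean it
  out-competes the other inside mixed ovules or at fertilization.  By
  construction `observed = efficiency x expected`, which the pipeline
  asserts row-wise.  Efficiencies are reported at 3 decimals,
  half-away-from-zero, mirroring field-survey reporting conventions.

Departures from the null are tested with Pearson's chi-squared (two
classes, df = 1, no continuity correction) on seed counts against the
expected proportions renormalized over the two competing classes.  An
exact enumeration of all two-class outcomes under the binomial null is
provided as an independent small-sample reference
(`exact_goodness_of_fit_p`).  Note that for small totals no asymptotic
p-value can track the exact discrete tail closely: the most central
outcome always has exact tail probability 1 while the asymptotic p is
well below 1 (at n = 21 the gap is still ~0.17), so the enumeration is a
diagnostic, not a drop-in replacement.

Stage (ovule vs. seed) comparisons use a paired t across populations;
season comparisons use Welch's t on per-population proportions
(fractional Satterthwaite df), with a 2x2 chi-squared homogeneity test of
pooled counts as an alternative.  Population statistics pool counts over
individuals by default (samples of ~3 individuals make per-individual
proportions noisy); a mean-of-individuals mode is exposed.

## Flow cytometry seed screen

Seed origin is read off the embryo and endosperm DNA-content peaks of a
single-seed fluorescence histogram.  For a tetraploid pseudogamous
aposporous plant with maternal 2C embryos, endosperm:embryo C-value ratios
identify: sexual 3C/2C = 1.5, apomictic 5C/2C = 2.5, and a BIII seed
(fertilized unreduced egg) by an embryo near 3C.  Decision windows are
ratio 1.5 +- 0.15 (sexual), 2.5 +- 0.25 (apomictic), embryo C within 0.3
of maternal (or of 1.5x maternal for BIII) — wide enough for 5%-CV peaks,
narrow enough to stay disjoint.  The true assay publishes no explicit
windows; these are this package's explicit substitutes and are
configurable.

Peak detection smooths the histogram with a 5-channel moving average
(edge-replicated padding), ignores channels below a debris floor (default
channel 20), takes prominence-filtered local maxima, and refines each by
iterated moment estimation followed by a Poisson-weighted least-squares
fit of a Gaussian plus constant baseline on a +-3 sigma window.  The
baseline term keeps debris from inflating the width estimate; Poisson
weights bring the CV estimator close to its information bound (standard
error ~0.1 percentage points of CV at 3000 particles).

Quality gates follow the assay's conventions: at least 3000 particles per
histogram, at least two retained peaks, and every peak CV at most 5%,
compared at the 0.1% precision cytometry software reports.  Seeds
generated at exactly 5% CV are borderline by construction and a small
fraction (~3%) are rejected by an unbiased estimator; seeds at 10% CV are
rejected essentially always.  Gate failures are tallied as unclassified.

## Fitness decomposition

Fecundity comes from bagged inflorescences whose full/empty spikelets are
counted by weight extrapolation (`100 x total / mean of three
hundred-spikelet weights` — scale-invariant in the weighing units).  The
population fecundity proportion averages per-individual full fractions
(equal plant weighting); the pooled count ratio is also exposed because
the two differ whenever individuals contribute unequal spikelet totals.
Germinability is the germinated fraction of sown seeds, averaged over
individuals.  Maternal fitness is the product fecundity x germinability,
computed from unrounded components; paternal effects are ignored, which
is appropriate for self-pollinated pseudogamous apomicts whose embryos
carry no paternal genome.  Regional summaries report mean and standard
error per group; singleton groups get a missing (not zero) SE.

## Environmental response

Covariates are consumed from a flat per-population table (bioclim-style
columns; raster extraction is out of scope).  Screening is by Pearson
correlation of each covariate with the sexual and apomictic proportions;
|r| >= 0.5 marks a covariate as selected, matching the moderate-to-high
correlations that motivate the mean-diurnal-range (MDR) analysis.

Two models link MDR (x, degrees C) to the sexual proportion (y):

* a Gaussian GLM with inverse link, `mu = 1/(b0 + b1 x)`, fitted by IRLS
  (statsmodels), t statistics on df = n - 2;
* a four-parameter bounded logistic
  `S(x) = s_lo + (s_hi - s_lo)/(1 + exp(-k (x - x0)))`,
  fitted by RSS grid search with a bounded least-squares polish that never
  increases the RSS.  The upper plateau `s_hi < 1` encodes the observation
  that full sexuality is never fixed in these polyploids; predictions
  `(S, 1 - S)` therefore always stay inside (0, 1) and sum to 1.

The logistic form is this package's design choice for a saturating,
bounded response; the mean function is pluggable so an alternative
parametric form can be swapped in unchanged.

Default grid: `s_lo` in [0, 0.3] step 0.02; `s_hi` in [0.2, 0.95] step
0.05; `x0` over the observed covariate span (20 steps); `k` log-spaced in
magnitude over [0.1, 5] (20 steps) *and symmetric in sign*.  The signed
grid matters: a positive-only gradient grid would make the bootstrap sign
test degenerate and could never produce a confidence interval covering
k = 0 under a flat response.  Fits whose predicted spread over the data
span is below 0.02 are flagged as gradient-unidentified.

Significance of the gradient uses a nonparametric case-resampling
bootstrap (default B = 1000): percentile 95% CI for k and the two-sided
sign rule `p = 2 min(Pr*(k<=0), Pr*(k>=0))` clipped to [2/B, 1].  Each
replicate refit runs a coarse signed grid and then polishes from the
better of that grid point and the full-data estimate; the per-replicate
grid is what lets the sign of k flip when the resampled data favor it —
a warm start alone inherits the full-data sign and undercovers badly when
the gradient is weak.  Replicates are counted as failures only when the
optimizer itself fails; more than 10% failures aborts.  All bootstrap
randomness flows through one seeded generator, so results are bit-identical
under a fixed seed.

Model checking mirrors the field design: predictions at an MDR outside
the sampled range are compared with common-garden observations by a
one-sample t (df = n - 1; an exact-match check replaces the t when the
garden values have zero variance), and populations of matched sexual
potential (greedy grouping within +-0.02 of the running group mean) are
tested for a positive within-group slope of sexual efficiency on MDR.

## Synthetic data

The generator emits every input table with the statistical structure the
analysis assumes, at the field-study scale: 20 populations, 3 individuals
each, 17 ovules per individual, 75 screened seeds per population.  Ovule
classes are multinomial with default simplex (0.186, 0.495, 0.299, 0.020)
for (MES-only, AES-only, mixed, aborted) — chosen so the implied mean
potentials are ~0.49 (sexual) and ~0.79 (apomictic) with ~2% failed
ovules, the regime the survey reports; 40% of AES-bearing ovules carry
multiple AES.  Seed formation is all-or-nothing per ovule: MES-only forms
a sexual seed with probability `sigma_sexual`, AES-only an apomictic seed
with `sigma_apomictic`, and a mixed ovule resolves apomictically with
probability `omega * sigma_apomictic`, sexually with
`(1 - omega) * sigma_sexual`, else nothing.  `omega = 0.5` with equal
`sigma` (default 0.8 each; the level only sets seed yield, not
proportions) is exactly the independence null, so the generator doubles
as the Monte-Carlo oracle for the expected-proportion formula; `omega > 0.5`
produces the apomixis-dominant regime with apomictic efficiency above 1.
Seed tables are subsampled without replacement to the screening depth.

The environmental generator draws MDR uniformly on [11, 15] degrees C,
sets sexual proportions on the bounded logistic with default truth
(0.05, 0.45, 1.2, 12.5) plus Gaussian noise (sd 0.05), clips to
(0.001, 0.999) to keep the inverse link defined, and adds independent
decoy covariates on bioclim-like scales.  FCSS histograms superpose two
Gaussian peaks at the diagnostic C-values (55%/44% of particles for
embryo/endosperm, 1% uniform debris) with Poisson channel noise, default
3% CV and 5000 particles on 1024 channels.  Fitness data are binomial
around cytotype-level truths (fecundity 0.37/0.17 and germinability
0.739/0.791 for diploids/tetraploids) with lognormal weighing noise.

What the generator does *not* emulate: spatial autocorrelation between
populations, genotype structure or inheritance of the apomixis locus,
S-phase nuclei and doublets in histograms, and covariate collinearity
(decoys are independent).  Passing tests therefore demonstrate that the
estimators recover the generative truth under the study's sampling
structure and noise levels — not that real surveys are free of the
confounds above.

All generators are deterministic given `SimConfig.rng_seed`, and emitted
tables always satisfy the invariants of their consuming types.

## Numerical choices and problem sizes

* Table dialect is fixed (TSV, UTF-8, `.` decimal, `NA` missing) to avoid
  locale drift; round-trips preserve counts exactly and reals to 1e-12.
* Efficiency with a zero expected component is reported as missing (NaN),
  never infinity; zero-variance correlation columns are likewise missing.
* IRLS runs at tolerance 1e-10, max 100 iterations; an exactly-fitting
  (zero-deviance) model is accepted as converged, and a constant response
  short-circuits to slope 0.
* Grid search is fully vectorized; the polish uses bounded
  trust-region-reflective least squares, with plateau order normalized via
  the identity `S(x; a, b, k, x0) = S(x; b, a, -k, x0)`.
* Verification runs use 50 datasets for parameter recovery, 100 datasets
  x B = 1000 for bootstrap coverage, 1000 seeds for screen accuracy, and
  1e5 ovules for the independence null — sizes at which Monte-Carlo error
  is a small fraction of each tolerance.

## Known limitations

* Published per-population proportions are printed at 3 decimals, so
  efficiencies recomputed from them carry input-rounding noise of up to
  ~0.006 in two populations; the raw counts behind the survey tables were
  never released.
* The bounded-logistic form is an assumption; only its qualitative
  features (saturation, bounded plateaus) are identified by ~20
  populations.
* Percentile bootstrap CIs for a nonlinear parameter at n = 20 are
  approximate; coverage near nominal was verified only under the
  generator's noise model.
* The FCSS classifier assumes exactly one embryo and one endosperm peak
  survive the gates; aneuploid or chimeric seeds fall to unclassified.
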