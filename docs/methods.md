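# Methods

## The qSIP transform chain

`predsip.qsip` maps density-fraction observations to per-taxon isotope
incorporation and growth:

1. **Weighted average density (WAD).** For each taxon and sample,
   W = Σ ρ_f y_f / Σ y_f with weights y_f = relative abundance × total
   16S copies per fraction. The estimate is invariant to rescaling the
   qPCR totals; all-zero weights are an error and the taxon is dropped
   with a log entry.
2. **GC and molecular weight.** GC = (W_light − 1.646057)/0.083506
   (clamped to [0,1] with a warning), M_light = 0.496·GC + 307.691 g/mol
   per nucleotide. These and the remaining calibration constants live in
   a frozen `IsotopeConstants` block (transcribed from the standard qSIP
   calibration) so alternative calibrations are configuration, not code
   edits.
3. **Atom fraction excess.** M_lab = M_light·(W_lab/W_light);
   AFE = (M_lab − M_light)/ΔM_max·(1 − a_nat), where ΔM_max is
   12.07747 g/mol for ¹⁸O (GC-independent) and
   (10 − 0.5·GC)·0.9974564 g/mol for ¹³C (per-carbon excess at 100
   atom %). Natural abundances: 0.2000429% (¹⁸O), 1.111233% (¹³C).
4. **Growth.** r = −ln(1 − A/A_w)/t: new DNA carries oxygen at the water
   AFE A_w, so taxon AFE saturates at A_w as labeled strands replace the
   unlabeled pool. The pair (A(r), r(A)) is an exact analytic inverse,
   which the round-trip tests exploit. A ≥ A_w is unresolvable
   (saturation error / NaN); negative AFEs are **retained and flagged**,
   not truncated, preserving the error structure for downstream
   averaging (flooring is available but off by default).
5. **Water AFE.** Two-pool mass mixing of added enriched water and
   background water at natural abundance, minus natural abundance. With
   equal masses of 97 atom % water and background, A_w ≈ 0.484, the
   default incubation condition.
6. **¹³C uptake.** AFE_C13 normalized by substrate enrichment and
   incubation length — a relative per-day index, not an absolute flux.

**Replicates and filtering.** AFE is computed per labeled replicate
against the mean unlabeled WAD and averaged; uncertainty by bootstrap
over replicates (seeded, optional). Taxa must be detected in ≥2
fractions in every replicate of both treatments (configurable); when a
table spans several experiments the requirement is evaluated within
each taxon's experiment.

## Predator classification

Six groups are treated as putatively predatory; *Bdellovibrionales* and
*Vampirovibrionales* are obligate, the rest facultative. Assignment is a
pure function of the lineage string: case-insensitive token match at
class, order or family rank (genus for *Lysobacter*), coarsest matching
rank wins, and a cross-group match raises loudly rather than guessing.
The token table (including rank synonyms such as the class Cytophagia
for the order Cytophagales, and Streptomycetaceae for Streptomycetales)
ships as an editable CSV so new clades (e.g. marine OM27) can be added
without code changes.

## Dual-isotope correction

The shipped default is the published linear correction
corrected = m − (0.0383·m + 0.0065), applied **only** to predator taxa.
A correction can also be re-derived from any predator/nonpredator pair
of major-axis fits: invert the predator line to an implied ¹³C AFE and
predict the water-only ¹⁸O from the nonpredator line, giving
a = 1 − s_n/s_p and b = (s_n/s_p)·b_p − b_n. Applied to the rounded
published relations (0.625/0.051 and 0.628/0.043) this yields
(−0.0048, 0.0082), which does **not** reproduce the published
(0.0383, 0.0065); the derivation behind the published coefficients is
not algebraically specified, so the derived model is reported alongside
the printed one and never asserted equal. The major-axis estimator uses
the closed form slope = (S_yy − S_xx + √((S_yy−S_xx)² + 4S_xy²))/(2S_xy)
(first principal axis), with the vertical-axis case a degenerate-fit
error.

## Meta-analysis

Effects are log response ratios of unweighted arithmetic group means
(predator group vs the experiment's nonpredator control) with the
standard delta-method variance; nonpositive means exclude the effect
with a tallied reason. Two effects sharing a control covary by
sd²_C/(n_C·x̄²_C), assembled into a block-diagonal PSD matrix V.

The model y = Xβ + Σ_l Z_l u_l + e, e ~ N(0, V), u_l ~ N(0, τ²_l I) is
estimated by REML: the restricted likelihood is profiled over the
variance components (coarse grid seed, then bounded L-BFGS-B, ftol 1e-8,
≤500 iterations, τ² ∈ [0, 5]) with an analytic GLS inner step for β.
Random levels are named by effects-table columns, with `"a:b"`
interaction coding for nesting (e.g. isotope within site,
group within experiment); the default is a site random intercept.
Moderators are cell-means coded; between-level equality is tested by
Wald chi-square with normal/chi-square reference distributions (no
small-sample t correction, matching common meta-analytic defaults).
Levels with fewer than two effects are reported estimate-only and
excluded from the test. Percent differences are (e^β − 1)·100 with
delta-method SEs.

## Synthetic data generator

Two tiers share one `GeneratorConfig`:

* **Fraction level.** Growth rates are log-normal (median 0.035 d⁻¹,
  log-scale σ = 1.0 — σ brackets a central 95% range of roughly
  0.003–0.25 d⁻¹; the generator exposes σ rather than fixing it because
  no single σ matches an asymmetric printed range exactly). A
  `predator_fraction` (default 0.074) of taxa get groups drawn from the
  observed composition (64.7% Myxococcales, 16% Cytophagales, 9.2%
  Streptomycetales, 7% Bdellovibrionales, 2.1% Lysobacter, 1%
  Vampirovibrionales) and rates multiplied by (1 + mode effect)(1 +
  substrate effect)e^(site shift), site shifts N(0, 0.05) on the log
  scale. True AFEs follow the exact labeling curve. Each taxon's light
  density comes from GC ~ U(0.3, 0.7); the labeled density is the exact
  inverse of the AFE transform (round-trip guarantee); DNA mass spreads
  over fraction bins by a Gaussian kernel (SD 0.006 g/ml — the simplest
  kernel producing realistic multi-fraction profiles; no measurement
  model is prescribed by the underlying studies). Counts are multinomial
  at `reads_per_sample` depth allocated across fractions by DNA mass;
  qPCR totals carry log-normal noise with CV 0.1. Defaults: 15 fractions
  over 1.64–1.78 g/ml, 3 replicates per treatment, 7.1-day incubations,
  A_w = 0.484. Taxa whose density support nears the gradient edge are
  truncated with a logged warning.
* **Effect level.** Group summaries are drawn directly so the true LRR
  equals ln(1 + planted effect) plus the site shift, bypassing the slow
  physical simulation for meta-analysis testing. Observed means carry
  multiplicative log-normal error, mean_obs = μ·e^ε with
  ε ~ N(0, cv²/n): for means of log-normal per-taxon rates this is the
  natural error model and makes the planted log ratio the exact
  expectation of the observed one. Defaults chosen once as realistic for
  this survey scale: control n = 100 taxa, predator group n = 10,
  within-experiment CV 0.75, group presence probabilities echoing the
  observed occurrence frequencies; 15 sites × 6 experiments ≈ 400
  effects, with roughly a third of experiments receiving substrate
  additions (C or C+N) and isotope labels alternating so isotope nests
  within site.

Seeds are explicit everywhere; a master seed spawns per-stage streams,
and identical seed + config gives byte-identical outputs.

### What the generator does and does not emulate

It reproduces the statistical skeleton of a multi-site qSIP survey:
log-normal rate heterogeneity, rare predators with multiplicative
effects, shared-control dependence, site-level clustering, realistic
fraction profiles and counting noise. It does **not** simulate PCR or
primer bias, chimeras, 16S copy-number variation, read-level data,
prey-derived ¹⁸O in predator DNA, or death/turnover. Passing recovery
tests therefore demonstrates correctness of the estimators under the
stated measurement model, not robustness to those unmodeled processes.
In particular, because synthetic predator AFE contains no prey-derived
¹⁸O, applying the published correction to synthetic data deflates
predators by construction; recovery validation of the full pipeline
runs with `correction_mode: "none"`, while `as_printed` remains the
default for real analyses.

## Numerical choices and degenerate inputs

* Fraction-bin discretization limits WAD accuracy: with bin width h and
  kernel SD σ the aliasing error decays like exp(−2π²σ²/h²), so the
  1e-6-level round-trip checks use a fine gradient (72 fractions over
  1.60–1.82 g/ml, h ≈ σ/2) where discretization is below machine
  precision; at the default 15 fractions the residual WAD error is
  ~1e-4 g/ml, negligible against counting noise.
* REML: the τ² grid seed protects against the flat-likelihood corner at
  τ² = 0; the optimizer result is checked against a brute-force profile
  grid on small instances in the tests.
* Major-axis fit with S_xy = 0: horizontal axis → slope 0; vertical
  axis (S_yy > S_xx) → degenerate-fit error; < 3 points → error.
* GC outside [0,1] clamps with a warning (tolerance 1e-9 to ignore
  float dust); corrected AFEs below −natural abundance can be floored
  with a flag.
* Growth at AFE ≥ A_w: saturation error (scalar) or NaN (array), logged.

## Problem sizes

Recovery simulations use the survey scale the defaults encode:
effect-level runs with 15 sites and ~400 effects, and fraction-level
runs with a 2000-taxon community (median sampling SE ≈ 2.8% on the log
scale, comfortably inside the 10% recovery tolerance), 15 fractions and
3 replicates per treatment. The CI-coverage check uses 200 replicates
of a reduced 6-site survey.

## Known limitations

* The log of a small-n mean of heavy-tailed per-taxon rates is biased
  low by ≈ CV²/2n; with the survey-scale spread (σ = 1) and predator
  groups of only a few taxa this biases fraction-level LRRs downward.
  This is a property of the ratio-of-means estimator itself (shared
  with standard LRR meta-analysis), not of the implementation; the
  effect-level generator avoids it by construction, and end-to-end
  fraction-level validation uses group sizes where it is small relative
  to the SE.
* The presence filter preferentially retains abundant taxa; abundance is
  drawn independently of growth, so the community median is essentially
  unaffected, but real-data selection need not be so benign.
* ¹³C AFEs in the fraction-level truth table use a crude fixed coupling
  (half of new-DNA carbon from the substrate) — adequate as plumbing for
  dual-isotope tests, not a carbon-flux model.
* The fraction of DNA oxygen derived from water is taken as fixed by the
  calibration constants; oxygen-limitation effects on ¹⁸O assimilation
  are not modeled.
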