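# Methods

## The experimental design being modeled

The package targets repeated-measures perturbation experiments on
host-associated microbiomes: six host individuals each divided across five
treatments — an untreated control (CON) and four phage applications
crossing delivery route (injection INJ / suspension SUS) with dose (HI /
LO) — and biopsied at 0, 24 and 72 h. One sample per (individual,
treatment, timepoint) gives 90 samples; plate counts are taken in
triplicate per sample. Analyses consume a taxa × samples count table plus
this metadata; read-level processing (denoising, taxonomy assignment) is
out of scope and assumed done upstream.

## Synthetic community model

Each taxon carries a role with a baseline proportion at 0 h:

| role | default | behavior |
| --- | --- | --- |
| symbiont (1 taxon) | 0.43 | rises to 0.54 (control) / 0.53 (phage) at 24 h, falls to 0.52 / 0.42 at 72 h |
| opportunist (1) | 0.004 | blooms to 0.13 at 72 h under phage, only 0.03 in control |
| phage target (1) | 0.005 | flat (< 1 % throughout) |
| transients (5) | 0.14 total | decay ≥ 3.5-fold by 24 h, to 0.02 by 72 h |
| rare tail (150) | remainder (~0.42) | frozen geometric series (ratio 0.97), absorbs renormalization |

Role multipliers per (treatment class, timepoint) are derived from this
share table, so the renormalized expected composition hits the target
shares exactly; the template stores the multipliers, and user overrides
(`theta`, baseline shares, per-condition shares, rare-tail size, library
model) re-derive them.

Counts are Dirichlet-multinomial: composition `~ Dirichlet(theta * p)` with
`theta = 200` (concentration mass; chosen so replicate samples show the
visible but moderate overdispersion of real 16S replicates — at `theta =
200` the symbiont share has a between-replicate SD of ~0.035), then reads
`~ Multinomial(depth, composition)` with `depth = round(10^N(4.3, 0.25))`
truncated below at 5400 (the rarefaction depth used throughout, so no
simulated sample is lost to rarefaction by default). Individuals enter the
CFU model as random intercepts only; the count model draws samples
independently given their condition, i.e. it does not add a
host-individual random effect to composition. Passing tests on these data
therefore demonstrates correctness of the estimators under
Dirichlet-multinomial noise, not robustness to host-individual
compositional covariance, temporal autocorrelation, or sequencing-depth
confounding — none of which the generator emulates.

CFU plate counts follow `log10 CFU = a_i + b_t * t + e`, with per-treatment
slopes `b` (log10 CFU/h) CON 0.004, INJ-LO 0.023, SUS-HI 0.009 (reported
values), INJ-HI 0.015 and SUS-LO 0.012 (interpolated defaults bracketed by
that range), individual intercepts `a_i ~ N(3.5, 0.2)` and plate noise
`e ~ N(0, 0.15)`. The intercept scale is conventional — absolute CFU
magnitudes are not modeled on any measured value — and counts are rounded
to integers on the linear scale.

## Diversity

* **Alpha**: observed richness; Chao1 always in the bias-corrected form
  `S + F1(F1−1)/(2(F2+1))` (finite when doubletons are absent); Shannon
  entropy with log base 2 by default (configurable) — the base is recorded
  in the output.
* **Beta**: Bray–Curtis and Jensen–Shannon distance (log base 2, so both
  lie in [0, 1]) on proportions; Jaccard on presence/absence. UniFrac is
  out of scope (no phylogeny).
* **Rarefaction**: multivariate-hypergeometric subsampling without
  replacement to a fixed depth (default 5400); shallower samples are
  dropped with a warning, never padded. Drawing happens in canonical
  (sorted taxon id) order so results are invariant to input row order
  under a fixed seed.
* **PCoA**: Gower double-centering of −D²/2 and eigendecomposition;
  negative eigenvalues are counted and reported, not corrected; variance
  fractions are taken over positive eigenvalues; axis signs are fixed by
  making the largest-magnitude loading positive.
* **PERMANOVA**: exact sum-of-squares decomposition
  `SS_total = Σ_{i<j} D²/N`, `SS_within = Σ_g Σ_{i<j∈g} D²/n_g`, pseudo-F
  `= [SS_between/(a−1)]/[SS_within/(N−a)]`; p-values by free label
  permutation with the observed statistic included in numerator and
  denominator (`p = (1+k)/(B+1)`, never 0). Free permutation is the
  default; a strata option restricts permutations to within-individual
  blocks for repeated-measures designs — neither mode is asserted to be
  the "correct" one for any particular published analysis, and zero
  within-group sums of squares raise an explicit error rather than an
  infinite F.

## Dysbiosis score

`s(x) = d(x, centroid(reference)) − d(x, centroid(own group))`, with
centroid distances from the Gower identity applied directly to the
dissimilarity matrix (default Bray–Curtis on relative abundances, one
matrix over all samples; centroids restricted per timepoint). Design
choices, each configurable:

* A sample is **included in its own group's centroid** (leave-one-out is an
  option). Inclusion keeps singleton groups well-defined and reproduces the
  characteristic small negative control scores: a control sample is inside
  its own reference centroid but far from the treated pool.
* For reference samples the comparison class is the pooled non-reference
  samples at the same timepoint.
* Negative Gower squares (possible because Bray–Curtis is non-Euclidean)
  are clamped to 0 and flagged; this keeps distances real and is
  conservative (a clamped distance can only shrink a score's magnitude).
* An alternative `space="pcoa"` mode embeds samples by principal
  coordinates first and measures Euclidean centroid distances there; the
  direct Gower mode is the default. The two agree exactly when the metric
  is Euclidean-embeddable.
* Thresholds are linear-interpolation percentiles (default 10th/90th) of
  all baseline-timepoint scores pooled across groups; boundary values
  classify as intermediate.

### Calibration of the baseline thresholds

With 30 baseline samples (6 reference + 24 treated) the nominal "10 % above
the 90th percentile" is only asymptotic. Two finite-sample effects, both
intrinsic to the design rather than to the estimator, raise the expected
dysbiotic fraction *among treated samples* under a no-effect null:

1. the exceedance probability of an interpolated 90th-percentile estimate
   from n = 30 observations is ≈ 4/31 ≈ 12.9 % for a new draw, not 10 %;
2. reference samples score systematically negative (they sit inside their
   own centroid, n = 6, but are compared against the pooled n = 24), so
   nearly all threshold exceedances fall in the treated arm, scaling its
   rate by 30/24.

Together these predict ≈ 16 % treated exceedance under the null; the
simulation study in the test suite observes ≈ 16 % over 200 null runs, and
the same mechanism is why a real experiment of this shape flags ~3/24
treated samples at baseline. The calibration test therefore compares the
null rate to the nominal 10 % at the binomial 95 % scale of the treated
arm (2·√(0.1·0.9/24) ≈ 12 points).

## Differential abundance

* **Kruskal–Wallis** with mid-rank tie correction and chi-square p-values;
  an all-constant vector returns H = 0, p = 1 instead of an error.
* **Log-linear contrasts**: total-sum scaling, `log2(rel + pc)` with the
  pseudocount `pc` = half the taxon's smallest nonzero relative abundance
  across *all* samples of the table (computing it per-contrast would tie
  the pseudocount to the smaller group and bound recoverable fold changes);
  Log2FC = difference of group means with a pooled-variance t-test and BH
  FDR across taxa. This fixes one reasonable normalization; numeric
  agreement with other log-linear tools is not claimed.
* **LDA effect size** (two classes): Kruskal–Wallis/BH screen at α, then
  per-million scaling and a bootstrap (default 30 rounds, two-thirds
  subsampling per class, seeded) of the absolute class-mean difference —
  for a single feature this equals the class-mean displacement along its
  unit-normalized Fisher discriminant axis. Score = log10 of the bootstrap
  mean effect, clipped below at 1 (so scores are ≥ 0); a taxon passes at
  q < α and score > cutoff (default 2). The design goal is a stable
  ordinal surface (which taxa pass), not score-exact agreement with any
  published tool.
* **CFU growth**: per-treatment OLS of log10(CFU) on hours, pooling
  individuals and plates (n = 54 per treatment in the default design);
  zero counts are dropped with a warning; a per-individual mixed model is
  deliberately out of scope.

## Numerical conventions

Proportions must sum to 1 within 1e−6 per column; baseline template
proportions within 1e−9. Ties in top-*n* selection break lexicographically
by taxon id. All stochastic operations take an explicit seed;
`simulate_experiment` spawns independent child streams for counts and CFU
from one seed, so a single integer reproduces a dataset byte-identically.
Dissimilarity matrices are validated for symmetry and zero diagonal at
construction.

## Problem sizes used by tests and the acceptance script

Simulation studies use the default 90-sample design. The test suite runs
200 null replicates (threshold calibration), 200 disturbance replicates
(recovery), 1000 × 199-permutation PERMANOVA null draws and 2000
Kruskal–Wallis null draws; the acceptance script uses 100 null and 100
disturbance replicates and 500 PERMANOVA draws, which bounds its Monte
Carlo error at roughly one percentage point on the reported rates. These
sizes keep each statistical check's standard error well below the
tolerances being asserted.

## Known limitations

* The generator draws library sizes and compositions independently per
  sample; no compositional host-individual effect, no temporal
  autocorrelation within an individual.
* Bray–Curtis centroid distances rely on clamping; in heavily
  non-Euclidean configurations many clamps (reported per run) would make
  scores conservative.
* The PERMANOVA default ignores the repeated-measures structure (free
  permutation); use `strata` for within-individual permutation when the
  design demands it.
* The LDA effect size is two-class only and simplified as described; the
  log-linear contrast is a fixed-effects approximation that pools
  individuals.
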