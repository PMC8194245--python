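# Methods

## The screening model

`cernascreen` treats ceRNA discovery as staged filtering over three
feature classes (lncRNA, miRNA, mRNA) measured in two sample groups
(tumor, normal).  A triple (L, M, G) is reported when

- L and M, and M and G, are each significantly negatively correlated,
- L and G are significantly positively correlated,
- every endpoint is differentially expressed in the ceRNA-consistent
  direction (M down in tumor; L and G up), and
- both regulator→target pairs (L→M, M→G) are predicted by two
  independent interaction resources.

The assumptions are those of the sponge hypothesis read off bulk
expression: correlations are linear (Pearson), measured on the log2
scale within the tumor group only, and no attempt is made to
distinguish direct binding from shared confounding — the screen ranks
candidates, it does not prove mechanism.

## Statistics

**Differential expression.**  Per feature, log2FC is the difference of
group means of log2(x + 1) (pseudocount 1 guards against zeros;
negligible at typical abundances), and the p-value is a two-sided Welch
two-sample t-test on the same values.  This is a deliberately simple,
documented stand-in for count-model DE machinery: the packaged
worked-example tables already carry their printed log2FC/p values, so
the statistic only governs the synthetic path, and it is swappable
behind `compute_differential_expression`.  No multiple-testing
correction is applied; the screening rule is the raw cut
|log2FC| ≥ 1, p < 0.05, which is liberal and stated as such.  A feature
with zero variance in both groups gets p = 1 with a warning.

**Correlation.**  Sample Pearson r with the two-sided p-value from
t = r·√((n−2)/(1−r²)) on n−2 df (delegated to `scipy.stats.pearsonr`);
|r| = 1 is clamped to the smallest positive p.  Constant vectors are an
error, n ≥ 3 is required.  Correlations use tumor samples only — the
screen asks how the genes co-vary within the disease state; including
normals would inflate correlations through the shared group shift.
Significance is raw p < 0.05 per edge with no |r| magnitude cut; both
are exposed as parameters.

**Survival.**  Subjects are split at the marker median (ties → low, the
conventional high-expression-vs-rest contrast), curves are product-limit
estimates and the comparison is the one-degree-of-freedom log-rank test;
both are delegated to `lifelines`, with censored subjects counted in the
risk set at their censoring time (standard convention).  Times are in
months; unit conversion is the caller's concern.  Test oracles are kept
independent of lifelines: a hand-computed 8-subject product-limit table
and a vectorized observed/expected/variance permutation statistic
written directly from the log-rank definition.

**Assay formulas.**  2^−ΔΔCt with ΔΔCt = ΔCt(case) − ΔCt(control),
ΔCt = Ct(target) − Ct(reference) — the case-minus-control orientation
matches the knockdown-vs-control convention; and caliper volume
V = length × width² / 2 in mm³.

## The simulator

`generate_cerna_dataset` emulates the statistical structure the screen
assumes, not RNA-seq counts.  Everything is linear-Gaussian on the log2
scale:

- planted miRNA: M = μ_M − Δ·1[tumor] + ε, ε ~ N(0, 1);
- planted partners (lncRNA and mRNA, independent noise each):
  X = μ_X + Δ·1[tumor] − b·ε + e, e ~ N(0, σ);
- slope b = σ·c/√(1−c²) gives within-group corr(X, M) = −c exactly for
  target coupling c, and corr(L, G) = +c² — the ceRNA sign pattern;
- decoys are independent N(μ, 1) with no group shift;
- matrices are emitted on linear scale (2^log2), so they are
  non-negative like real expression profiles.

Defaults (chosen once as a realistic modest study): 50 tumor + 50 normal
samples, 5 planted triplets, 20/20/40 decoy lncRNA/miRNA/mRNAs,
differential shift Δ = 2 log2 units, coupling c = 0.7, residual
σ = 0.5, and decoy prediction pairs at rate 0.1 per resource (drawn
independently per resource, so the two-resource consensus removes most
of them).  Feature baselines μ are U(4, 10) log2 units.  One global
seed feeds named `SeedSequence` substreams (expression, pairs,
survival), so changing the decoy pair rate never perturbs expression
values.

Survival simulation draws exponential event times with per-subject
hazard λ₀·exp(β·z), z the standardized marker expression, λ₀ set to a
24-month baseline median, independent U(0, 60)-month censoring.

**What the simulator does not model:** count noise (negative binomial
over-dispersion), library-size/normalization artifacts, batch effects,
correlated decoys, many-to-many sponge topologies, or non-linear
regulation.  Passing the recovery tests therefore shows the pipeline's
logic and calibration are correct under its own assumptions — not that
the screen is well-powered on real RNA-seq data.

## Numerical and design choices

- **Determinism:** all outputs (pairs, triplets, networks) are sorted
  lexicographically by id; pipeline results are invariant to input row
  order, and fixed-seed CLI runs are byte-identical.
- **Identifier hygiene:** miRNA ids are normalized to miRBase-style
  `hsa-miR-…` (case, unicode dashes, known typographic variants such as
  `miR-29–2-5p` → `hsa-miR-29b-2-5p`); gene symbols are matched
  case-sensitively after whitespace trimming.
- **Pair classes:** regulator→target tables admit (lncRNA, miRNA) and
  (miRNA, mRNA); a third class (lncRNA, mRNA) carries
  correlation-evidence pairs — reported co-expression relations, not
  binding predictions — so the worked example's six pairs load through
  one reader.
- **Unique-gene counting:** the target-gene universe is counted over
  unique symbols across per-miRNA blocks (genes recur under several
  miRNAs); network building de-duplicates miRNA→gene edges the same way.
- **Candidate lncRNA–mRNA links** are generated from chains L→M→G of
  surviving pairs rather than all L×G combinations; this matches the
  sponge logic and keeps the correlation budget linear in the network
  size.
- **Degenerate inputs:** duplicate ids, self-pairs, illegal class
  combinations, all-equal median splits, zero-event log-rank inputs and
  constant correlation vectors all raise informative errors naming the
  offender (and the line number for file inputs).

## Problem sizes

The test suite and the reproduction script run at desk scale: recovery
is averaged over 20 simulated datasets of 100 samples each; null
calibration uses 100 correlation pairs at n = 10 and 1,000 survival
seeds; the permutation oracle uses 10,000 label permutations at n = 20.
The full suite completes in well under a minute on one core.

## Known limitations

- The Welch stand-in ignores mean–variance coupling of counts; printed
  DE tables from array/sequencing pipelines will not be numerically
  reproduced from raw data by this package (they are consumed as
  inputs).
- Raw per-edge p < 0.05 with no FDR control is faithful to the
  screening procedure but anti-conservative; `run_screen` exposes the
  level for stricter choices.
- The chi-square log-rank p-value is a large-sample approximation; at
  n ≈ 20 it can differ from the exact permutation p by ~0.01–0.02.
- Tumor-only correlation is a design choice, not a data-driven one;
  with very few tumor samples the screen loses power before it loses
  calibration.
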