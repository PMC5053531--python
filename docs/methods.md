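# Methods

This note documents the models behind `cnvsmoke`, the defaults and why they
were chosen, the conventions frozen for reproducibility, and what the
synthetic cohorts do and do not capture about real SNP-array data.

## Cohort generator (`simdata`)

The generator emulates an all-smoker adult cohort with the inclusion
criterion pack-years ≥ 10.

**Demographics.** Sex is Bernoulli with male fraction 0.570; age is a
truncated normal, mean 54.5, SD 8, support [45, 90] years; the per-subject
European-admixture score is Beta(2, 8) (mean 0.2, the typical average
European ancestry in African American cohorts); current-smoker status is
Bernoulli(0.805). The default cohort size is 2,889 with a focal deletion
carried by 77/2889 ≈ 2.7% of subjects and 372 further panel components
(373 CNV markers in total), frequencies uniform in 1–10% unless supplied.

**Copy numbers.** Carrier indicators for all components come from a
one-factor latent Gaussian threshold model: subject *i* carries component
*j* iff √ρ·g_i + √(1−ρ)·e_ij < Φ⁻¹(f_j), giving each component its marginal
frequency f_j and a single dependence knob ρ (default 0.2). This is the
simplest mechanism that produces the positive inter-component dependence
under which a max-statistic permutation threshold drops below Bonferroni.
A carrier is homozygous-deleted with probability 3/173 (the ratio of
homozygous to all deletion genotypes seen in array-replication data),
hemizygous otherwise.

**Phenotypes.** log₁₀ pack-years is Normal(μ, σ) truncated at 1 (resampling
draws below the pack-years floor of 10), with

μ = b₀ + 0.018·male + 0.05·(age − 54.5)/10 + β·(deleted focal copies).

σ defaults to 0.25; the source study does not report the dispersion of
log pack-years, so this is the package's own choice — it yields a
pack-years distribution with a realistic right skew and coefficient of
variation ≈ 0.6 for heavy-smoker cohorts, and it is configurable. The
intercept b₀ is calibrated deterministically by root-finding on the
closed-form truncated-log-normal mean, averaged over a fixed internal
covariate sample of 20,000, so that the expected cohort mean pack-years
equals the target (default 38.1). The default focal effect β = 0.11 per
deleted copy was set from the design target of an expected scan signal near
the genome-wide line: with 77 carriers of 2,889 and σ = 0.25, the slope's
standard error is ≈ 0.029, so β = 0.11 puts the expected −log₁₀ p around 4.

Cigarettes per day are tied to pack-years by the defining identity
pack-years = (cigs/day ÷ 20) × smoking-years, with smoking-years = age −
start-age and start-age uniform on [14, 22]; the resulting cohort mean
(~21/day) matches heavy-smoker profiles without a second free parameter.

**Intensities.** Probe LRR is Gaussian around the canonical per-state means
(CN0 −3.5, CN1 −0.66, CN2 0.0, CN3 +0.4; SD default 0.20). BAF uses a
B-allele population frequency of 0.5 at every probe: diploid probes cluster
at {0, ½, 1} with Hardy–Weinberg weights, hemizygous probes at {0, 1} (the
heterozygous band is lost), homozygous deletions give uniform noise, gains
cluster at {0, ⅓, ⅔, 1}; Gaussian noise (SD 0.03) is added and values are
clipped to [0, 1].

**What the simulation does *not* capture:** GC-content waviness and batch
structure in LRR, probe-specific B-allele frequencies and linkage
disequilibrium, mosaicism, genotyping-failure patterns, and the correlation
of CNV carriership with ancestry. Passing tests therefore demonstrate
correctness of the statistical machinery under the stated generative model,
not robustness to real-array artifacts.

## CNV calling (`cnvcall`)

The segmentation HMM is deliberately simple: four states (CN 0–3), Gaussian
LRR emissions at the canonical means, a BAF term computed from per-state
cluster mixtures, distance-independent transitions with stay probability
0.99, and an initial distribution equivalent to being preceded by a diploid
probe. Per-call confidence is the emission log-likelihood margin of the
called state over the all-diploid path across the call's probes (within-run
transition terms cancel). This is a stand-in for full production CNV
callers (no GC model, no family information, no B-allele genotype HMM); the
quantitative validation path is the median-LRR Gaussian-mixture genotyper,
which selects its number of mixture components (1–4) by BIC, maps fitted
means onto copy numbers by proximity to the canonical means, and falls back
to fixed-means nearest-mean classification when the fit is degenerate or
unidentifiable (mean further than 0.5 from every canonical value).

**Component construction.** The published construction this follows is
described only by citation in the source literature, so the package uses a
transparent reconstruction: per chromosome, call boundaries are converted to
half-open intervals, their breakpoint union defines atomic intervals, each
subject's copy number on an atomic interval is taken from any covering call
(conflicting overlaps are an error naming the subject), adjacent intervals
with identical per-subject profiles are merged, and intervals with carrier
frequency **strictly** above the threshold (default 1%) are retained.
Homozygous and hemizygous deletions both count as carriers.

**Coordinates.** 1-based inclusive internally; the *span* of a segment is
reported as end − start — the arithmetic convention of the CNV reports this
mirrors (6214264 − 6212573 = 1,691) — while BED export uses 0-based
half-open intervals.

## Association and multiple testing (`assoc`, `mtc`)

Dosage is coded as deleted copies (0/1/2), matching a deletion-centric
analysis. Covariates default to age + sex + admixture for admixed cohorts.
The per-component fit is exact OLS, implemented by Frisch–Waugh–Lovell
residualization so the permutation loop can re-fit hundreds of components
thousands of times; the test suite verifies the fast path against
statsmodels and a normal-equations oracle to 10 decimals. Carrier-group
contrasts use Welch's unequal-variance t-test (group sizes of ~77 vs ~2,800
make the pooled-variance assumption unsafe) and are reported on the raw
pack-years scale by default, with the scan itself on log₁₀.

The permutation threshold is the empirical **(1 − α) quantile of the
per-replicate maxima of −log₁₀ p** (equivalently the α quantile of the
minimum p), with the quantile rule frozen to linear interpolation between
order statistics. Each replicate draws one uniform subject permutation and
applies it jointly to the dosage matrix and the admixture covariate,
leaving the phenotype and the remaining covariates fixed — the joint
permutation preserves inter-component dependence (required for max-T
validity) and keeps each subject's deletions attached to their ancestry
score. Replicates below 100 are refused and a seed is mandatory. Because
all per-component fits in a replicate share their residual degrees of
freedom, only the per-replicate maximum |t| needs converting to a p-value.

## Meta-analysis and power (`metapower`)

The default meta-analysis is fixed-effect inverse-variance weighting on
(β, se) pairs, with a sample-size-weighted Stouffer z alternative for
studies reported only as (p, n, direction); the method used is recorded in
the output. The power simulation draws carriers at a given frequency,
generates the outcome as β·carrier + Normal(0, σ) (σ default 0.25, α
default 0.05, both configurable and reported), and evaluates the slope
t-test across the effect grid (default 0 to 1 in steps of 0.005). Carriers
and noise are drawn once per sample size and shared across the grid
(common random numbers): the per-simulation sufficient statistics are
linear in β, which removes grid-to-grid Monte-Carlo jitter and makes the
curves monotone in β up to the shared-noise error.

## Pipeline (`cli_io`: io / table2 / pipeline / cli)

All randomness in a pipeline run flows from one root seed expanded per
stage with `numpy.random.SeedSequence`; stage seeds appear in the log and
the summary. The focal ~20 kb locus (with the deletion occupying its
1,691 bp tail) gets full probe-level intensity simulation (30 probes by
default) and HMM calling; the genome-wide panel components are materialized
as rawcnv-format calls from the generator's truth matrix, each on its own
interval of a cycling autosome, and pass through the same
component-construction and scan code as the focal calls — simulating probe
intensities at several hundred loci would multiply runtime without
exercising any additional code path. Artifacts are plain TSV/JSON plus the
whitespace-delimited rawcnv dialect; structured progress lines go to
standard error only.

## Problem sizes used in the checks

The calibration script uses 200 null cohorts of 600 subjects with 25
markers and 1,000 permutation replicates each — sizes at which the binomial
Monte-Carlo error of the family-wise rate (SE ≈ 1.5 points at 5%) is well
inside the ±2-point acceptance band while the whole computation stays in
the tens of seconds. Closed-form comparisons for the permutation threshold
use 10,000 replicates; oracle-equivalence checks enumerate all 4^P paths on
panels of up to 10 probes.

## Known limitations

- The HMM has no GC-wave model and distance-independent transitions; it is
  validated against exhaustive enumeration, not against a production caller.
- The component construction is a reconstruction of a method published only
  by citation; alternative constructions (e.g. clustering calls rather than
  breakpoint unions) could yield different component boundaries.
- The generator links ancestry to nothing: admixture is independent of
  carriership and of the phenotype, so the admixture covariate's role as a
  confounder control is structurally untested.
- The ordinal cigarettes/day category boundaries between 20 and 60 are
  successive decades by inference from the stated endpoints of the coding
  scheme (categories 1, 2 and 7 are stated; the middle is interpolated).
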