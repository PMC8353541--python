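# Methods

## The model

A CSF sample is modeled as a mixture of tumor-derived and normal cfDNA. Let
*tf* be the tumor fraction and c the integer copy number of the tumor genome
over a bin (capped at 5, floor 0; normal DNA is diploid). The expected
relative coverage of the bin is (tf·c + (1 − tf)·2)/2, so its expected log₂
coverage ratio against a diploid reference is

    μ(c, tf) = log₂((tf·c + (1 − tf)·2)/2),

floored at −3 (a homozygous deletion at tf = 1 is −∞ otherwise; the same
floor caps observed ratios, matching the bin-level cap [−3, +2]). Observed
log₂ ratios are Gaussian around μ(c, tf) with a single emission scale σ —
at 1 Mb bins and ~0.1× depth the negative-binomial counting noise on a few
hundred reads per bin is well approximated as Gaussian on the log scale.

Copy number evolves along each chromosome as a first-order Markov chain with
self-transition p_stay = 0.999 and the remaining mass spread uniformly over
the other five states. At 1 Mb bins this puts the expected segment length
near 1000 bins, far longer than a typical chromosome arm, encoding the prior
that somatic copy-number alterations are long and segmental. Chromosomes are
independent chains (no transition across a chromosome boundary). Bins
removed by quality filters are skipped with a single transition step across
the gap regardless of its width; a geometric decay in gap width would be
more faithful but makes no practical difference at the ~2–3% masked-bin
rates seen here.

Tumor fraction is estimated by profile likelihood on the grid
{0, 0.03, 0.05, 0.10, 0.15, …, 0.95}. At each grid point σ is profiled by a
robust residual scale: starting from the MAD of the ratios, the Viterbi path
is decoded and σ reset to the RMS residual around the path means, twice.
(A full EM M-step over posterior state weights is the textbook alternative;
the hard-assignment version is cheaper, deterministic, and adequate because
σ enters model comparison only weakly.) The estimate tf̂ is the grid argmax,
ties broken toward smaller tf; an optional golden-section refinement between
the neighbouring grid points is available (`refine=True`) but off by
default, so tf̂ is quantized at the grid step.

The binary diagnosis operationalizes "nonzero inferred cancer fraction",
which has no meaning at floating point, as: positive iff tf̂ ≥ 0.03 **and**
the fitted model beats the diploid (tf = 0) model by ≥ 2 log-likelihood
units. Both thresholds are exposed in configuration. The likelihood margin
is what provides specificity: on simulated tumor-free samples the tf > 0
models gain almost nothing over the diploid fit, and ≥ 49/50 null samples
are called negative in the calibration test.

Viterbi ties (which arise systematically at tf = 0, where every state has
the same mean) resolve toward copy 2, then lower copies — a null-leaning
decode. Segments are maximal runs of equal decoded copy number within a
chromosome; the fraction of genome altered (FGA) is the fraction of usable
bins decoded non-diploid.

### Known limitation: tumor-fraction aliasing

The mixture means are not globally identifiable: a genome altered only by
copy-1 losses and copy-3 gains at tumor fraction t produces exactly the same
means as copy-0/copy-4 alterations at t/2. Copy-4 (or copy-5) segments break
the degeneracy. At the study scale (2200 bins, ~25% of the genome altered in
several segments with copies drawn from {1, 3, 4}) profiles lacking a
degeneracy-breaking segment are rare and the estimator recovers tf = 0.6
within ±0.1 in ≥ 90% of replicates; on much smaller genomes (a few hundred
bins, 2–4 segments) the halved solution wins noticeably often. This is a
property of the model class, not of the optimizer, and is shared by
coverage-only tumor-fraction methods generally.

## Coverage correction

Fragments are assigned to the bin containing their midpoint after discarding
MAPQ < 20 and non-autosomal records. Counts are divided by mappability and
bin width, then by a smooth GC trend: median rate within ~20 GC quantile
bins, with a quadratic fitted through the binned medians and evaluated at
each bin's GC. (Plain linear interpolation of the binned medians
undercorrects the sparse GC extremes, where the bias curve is steepest; the
quadratic matches the unimodal shape the generator and real libraries
share.) Bins with mappability < 0.9 are masked. Corrected ratios are
median-centered to 1, divided by the panel-of-normals per-bin median,
log₂-transformed, re-centered to genome-wide median 0 and capped to
[−3, +2]. The panel is the per-bin median corrected coverage of diploid
replicates; the pipeline ships a synthetic panel of 20 simulated diploid
samples, and any user-supplied panel TSV is accepted.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure the analysis relies on,
under the study conditions:

- **Binned coverage.** Negative-binomial counts with mean
  depth·width/166 bp · gc_bias · mappability · mixture factor, variance
  μ(1 + α·μ) with dispersion α = 0.01 by default (Poisson at α = 0; ULP-WGS
  is mildly overdispersed). Mean depth defaults to 0.1×, i.e. ~600 fragments
  per full 1 Mb bin. The GC bias is a quadratic with peak efficiency at
  GC 0.45 (strength 8 → up to ~18% attenuation at the GC extremes);
  synthetic GC tracks are smooth and spatially autocorrelated in [0.3, 0.6],
  mappability in [0.7, 1.0].
- **Fragment lengths.** A two-component discretized Gaussian mixture at
  166 ± 10 bp (mono-nucleosome) and 332 ± 16 bp (di-nucleosome). The
  mono-nucleosomal weights — 0.808 for CSF, 0.915 for plasma — are
  calibrated so the simulated log₂ peak-ratio medians land at ~2.16 and
  ~3.51 respectively, the typical group medians for these fluids; the
  underlying mixture weights are not published anywhere and are this
  package's own calibration (w solves w·κ₁/((1−w)·κ₂) = 2^median, with κ the
  window capture fractions of each component). A contaminated CSF sample
  draws each fragment from plasma with probability p.
- **Cohorts.** Defaults mirror the emulated study: 43 LMD + 5 PT + 3 PTACSF
  samples; cytology positive with probability 0.72 for LMD samples and
  negative otherwise; LMD and PTACSF tumor fractions logit-normal
  (location 0.36, scale 1.48 — median ≈ 0.59, IQR ≈ 0.44–0.85); PT samples
  tf = 0. PTACSF samples are simulated identically to LMD at the coverage
  level — tumor DNA reaches the CSF in both — differing only in the group
  label, which is exactly why they confound the cfDNA call. cfDNA
  concentrations are log-normal per group (medians 0.804 / 0.0725 /
  0.0234 ng/µL for LMD / PTACSF / PT). CNA profiles are random
  non-overlapping segments of 20–80 bins with copies drawn from {1, 3, 4}
  until ~25% of the genome is altered.
- **Seeds.** Every stochastic operation takes an explicit seed. A cohort
  derives per-sample 31-bit sub-seeds from a master PCG64 stream seeded by
  the cohort seed; within a sample, counts, fragment lengths and clinical
  draws use distinct SeedSequence children ([seed, 0], [seed, 1], [seed, 2]).
  Runs are byte-identical given the same configuration.

Not emulated: read-level sequence (no FASTQ/alignment), replication-timing
or blacklist artifacts, subclonal heterogeneity, within-patient correlation
of repeated samples (each simulated sample is an independent patient, and
the paired tests assume independence, as the emulated design does), and any
association between contamination and the coverage signal beyond the
fragment-length mixture. Passing tests therefore demonstrate the statistical
machinery under the stated noise model — not performance on real libraries,
where bias removal is the harder part of the problem.

## Diagnostics conventions

- Confidence intervals are exact binomial (Clopper–Pearson, beta quantiles);
  every interval in the emulated results table matches this method,
  including the 5/5 specificity bound with closed form lower limit
  0.025^(1/5) = 0.478.
- The McNemar test is the exact binomial version — two-sided by doubling the
  upper tail at max(b, c) and capping at 1 — because discordant counts are
  small; b + c = 0 returns p = 1 by convention. The continuity-corrected
  asymptotic version is available for comparison.
- Fisher's exact test is two-sided by summing hypergeometric probabilities
  no larger than the observed table's (scipy's convention, cross-checked
  against enumeration in the tests).
- Group comparisons use Wilcoxon rank-sum on log₂-transformed values with
  Bonferroni correction over the group pairs; zeros map to −∞, which rank
  statistics tolerate. Identical groups short-circuit to p = 1. The
  repeated-measures mixed model used for this comparison in the full
  clinical analysis is out of scope here.
- Quantiles/IQRs use linear interpolation (type 7).
- Display rounding is half-up (0.625 → 0.63), since Python's banker's
  rounding would disagree with clinical-table convention; p-values render
  journal-style (".01", "<.001", ">.99"), and prose percentages round to
  whole percent.
- Cytology readings other than "positive for malignant cells" (atypical,
  suspicious) are treated as negative upstream of the sample record.

## Problem sizes in the test suite

Unit and property tests run on reduced genomes (6 × 10 Mb or 22 × 20 Mb)
where the checked property is scale-free. Statistical performance checks run
at the study scale of 2200 × 1 Mb bins: tumor-fraction recovery
(50 replicates at tf = 0.6, 0.1×, 25% altered), null calibration
(50 tumor-free replicates), and depth consistency (8 replicates each at
0.05×/0.2×/1×). The cohort-direction check (cfDNA sensitivity exceeding
cytology's) runs on 8 replicate cohorts of 21 samples over 220 bins, which
is sufficient for the direction of effect. The exhaustive-path HMM oracles
enumerate all 6ⁿ state paths up to n = 8.
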