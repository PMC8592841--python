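# Methods

## Scope and model

`rddmkit` analyses assays used to study the initiation of RNA-directed
DNA methylation (RdDM) in plants: bisulfite amplicon sequencing (BSAS)
of target loci, small RNA size-class profiles against a target sequence,
and ChIP-qPCR / fold-enrichment quantification. The central statistical
object is the per-read methylation call vector: one deeply sequenced
amplicon read reduced to an ordered vector of M / U / AMBIG calls over
the amplicon's cytosine sites. Two derived quantities summarize it:

1. **Pooled per-context methylation.** For each context (CG, CHG, CHH;
   H ∈ {A, C, T}) the estimate is 100·Σmc/Σcov over all sites of that
   context, with a Wilson score 95% interval on the pooled counts. The
   pooled-count estimator is used (not the mean of per-site fractions)
   because the interval's trial count is the summed read coverage over
   assayed cytosines; the per-site-average variant is available via
   `estimator="per_site"`.

2. **RdDM strength.** Per read, the length L of the longest stretch of
   consecutive methylated cytosines. Sporadic false positives from
   incomplete bisulfite conversion (rate ε, typically < 1%) produce
   mostly isolated M calls, whereas RdDM writes methylation in dense
   patches; L separates the two regimes even when the per-site averages
   are similar. Distributions of L are summarized by the 10/25/50/75/90th
   percentiles (inclusive linear interpolation, the default of the
   mainstream plotting stacks used for such box plots) and the mean.

### The stochastic non-conversion null

Under pure non-conversion, calls are i.i.d. Bernoulli(ε) per site. The
exact distribution of the longest success run L in n trials is computed
by dynamic programming on the trailing-run length: P(L ≤ l) equals the
survivor mass of a chain over states 0..l (current trailing run), where
a success from state l is absorbed into failure. The pmf is the first
difference of that CDF; cost O(n²) overall, negligible at amplicon scale
(n ≤ a few hundred). Each read's observed L is scored by its null tail
probability P(L_null ≥ L_obs) at that read's own n_assayed (pmf cached
per distinct n). The reported *null-exceedance fraction* (reads with
tail probability < α, default α = 0.05) is compared against the exact
achievable level computed from the pmf — because L is discrete, the
achievable level is below α and is reported exactly rather than assumed.
This comparison is this package's quantification of a contrast usually
made visually, and is labelled as such in output.

AMBIG calls break runs by default: an unreadable base cannot be evidence
of a consecutive methylated stretch. A bridging policy (AMBIG
transparent, never counted) is available behind `ambig_bridges=True`.
The statistic uses all assayed cytosines regardless of context; a
context-restricted variant can be obtained by masking calls upstream.

## Read calling

Reads are aligned semi-globally to the amplicon (free end-gaps on the
amplicon only) with bisulfite-aware scoring: on a forward-assayed
amplicon, read T against reference C scores as a match and is called U,
read C against reference C is called M; reverse-strand amplicons use
G/A symmetrically in forward coordinates. Scoring is match +1, mismatch
−1, gap open −3, gap extend −1 via Biopython's `PairwiseAligner` with an
asymmetric substitution matrix. Both read orientations are tried; ties
reject the read as ambiguous. Reads are rejected when the mismatch
fraction over aligned non-site bases exceeds 0.1 (default), when shorter
than 50 nt, or when the alignment's diagonal offset exceeds the `band`
parameter (default 10) anywhere — the band is enforced as a
post-alignment filter, so the accepted set matches a banded DP while the
full DP finds the optimum. Bases below Q20 (when qualities are given),
gaps at sites, unaligned sites and unexpected bases are AMBIG; AMBIG
never contributes to methylated or total counts. Full-length
substitution-only reads — the overwhelming case for amplicon data — take
a vectorized gap-free path with call-for-call identical semantics
(verified against the aligner in the test suite). Identical reads are
not deduplicated: amplicon libraries are expected to be duplicated.

Every cytosine on the assayed strand is a site. Context comes from the
two downstream bases on that strand; boundary cytosines with fewer than
two downstream bases, and any trinucleotide containing N, are UNDEFINED:
excluded from context-stratified summaries but still assayed per read,
since the per-read statistic uses every cytosine in the row. Coordinates
are 0-based internally and 1-based in all serialized output (allC
convention).

## Conversion rate

ε is estimated as pooled mc/cov over a biologically unmethylated control
amplicon sequenced alongside the targets. Values above 0.05 attach a
warning (the control may be methylated in some genotype) but never an
error. Methylation percentages are reported raw, with ε alongside; no
conversion-rate correction is applied.

## Synthetic data generator

The bisulfite generator is a two-component mixture emulating a T1
transgene population: with probability π a molecule is RdDM-methylated,
with per-context rates (m_cg, m_chg, m_chh) and first-order Markov
persistence ρ along consecutive sites; otherwise it is unmethylated.
Every unmethylated site — on either component — reads as methylated with
probability ε, because non-conversion is a property of the chemistry,
not the molecule class. The exact pooled expectation recorded in the
generator metadata is therefore

    E[mc/cov] = π·m + (1 − π·m)·ε      (per context, rate m)

adjusted for the uniform per-base miscall rate (default 0.001; the
recovery analyses below set it to 0). The Markov transitions are
P(M|prev M) = m + ρ(1−m) and P(M|prev U) = (1−ρ)m, which preserve the
per-site marginal m exactly when the rate is constant along the read;
with context-varying rates, marginals near context switches are pulled a
ρ-geometric step toward the neighbouring rates, so parameter-recovery
analyses use equal context rates. Reads are emitted full-length at
constant Q37 with strand-symmetric uniform substitution errors; the
generator does not emulate PCR duplication bias, primer mispriming, or
position-dependent error profiles, so passing tests say nothing about
robustness to those artifacts. All generators are pure functions of
(config, seed).

Small RNA libraries are uniform random substrings (random strand) of a
source sequence at a specified 18–28-nt size spectrum, plus a background
count that only inflates the normalization denominator. qPCR Ct pairs
are generated from a true percent input with additive Gaussian Ct noise;
inverting the percent-input formula under that noise yields a
log-normally distributed estimate whose mean carries a positive bias of
factor exp(σ²ln²2) (σ² the summed Ct noise variance) — reproduced, not
corrected, and covered by a test. Enrichment tables draw fold
enrichments uniformly within per-category ranges; ranges straddling a
decision boundary trigger a generation warning.

### Parameter-recovery calibration

The recovery check (simulate 20,000 reads at π = 0.5, m = 0.6, ρ = 0.5,
ε = 0.005; estimate pooled CHH methylation; repeat over 100 seeds) asks
whether the closed-form expectation falls inside a Wilson interval of
the estimate in ≥ 95 runs. The interval's trial unit is the **molecule
(read), not the pooled site count**: sites within a read are positively
correlated through the mixture component and ρ, so a site-pooled
interval would be anti-conservative by a large design effect (the
between-seed variance is dominated by the binomial draw of the realized
RdDM fraction). A per-read methylated fraction has at most Bernoulli
variance, so the read-level Wilson interval is conservative for any
within-read dependence structure.

## Small RNA and ChIP arithmetic

Mapping at transgene scale is exact substring matching on either strand
(zero-mismatch semantics); a read counts once per target regardless of
position or strand multiplicity. RPM = raw count × 10⁶ / genome-mapped
total. IP/mock enrichment per size class is the RPM ratio, NA when the
mock class has no mapped reads (distinct from a true 0 when the IP is
empty). Pol V-dependence of siRNA loci: not testable below 10 raw
wild-type reads; dependent at ≥ 2-fold RPM loss in the mutant (the
fold is applied to RPM, configurable). tRNA/rRNA/low-complexity
filtering is assumed done upstream; only the 18–28-nt length filter is
enforced here.

Percent input: Ct_100 = Ct_diluted − log₂(DF); percent =
100·2^−(Ct_IP − Ct_100). It is strictly decreasing in both Ct_IP and DF
(at Ct_IP = Ct_diluted it equals 100/DF). Null-mutant background is
averaged per PCR target and subtracted, clipping at 0 with a flag (the
unclipped value is retained for audit). Relative expression is 2^−ΔΔCt.
SUVH2/9-dependence of Pol V-occupied loci uses replicate-averaged
IP/mock fold enrichments: not occupied below fe_min (default 2);
occupied loci are fully dependent when the mutant falls to
background_max (default 1.5 — the "background level" threshold is not
canonical and is surfaced as a parameter in output metadata), partially
dependent when the mutant retains fe_min, and an explicit indeterminate
bucket covers the gray zone between the two thresholds.

## Numerical and design notes

- Wilson interval: closed form with z = 1.959964 by default; bounds
  pinned to exactly 0 at k = 0 and exactly 1 at k = n. Cross-checked
  against statsmodels in the test suite. k may be non-integral to
  support cluster-level effective counts.
- A context with zero pooled coverage is reported absent, never as 0%.
- The null pmf is clipped to [0, 1] and renormalized after differencing;
  deviation beyond 1e-9 from unit mass raises.
- Problem sizes in the shipped analyses (4,000–20,000 reads on a 300-nt
  amplicon with ~40 CHH sites; 10⁵ Monte-Carlo draws; 30–100 recovery
  seeds) were chosen to make Monte-Carlo error small relative to the
  effects under test.
- Known limitations: no paired-end merging or PCR-duplicate handling;
  no amplification-efficiency correction in qPCR; genome-scale mapping
  and peak calling are consumed as count tables, not reimplemented.
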