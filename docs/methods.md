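# Methods

## Abundance model

The unit observation is a mapped-read interval on a contig (0-based
half-open; strand is stored but never used, since the estimator depends only
on spans). Per-base depth is the number of intervals covering a base; the
abundance of a feature is the **median basepair coverage** over *every* base
of its span, zeros included. Including uncovered bases makes detection
strict — a feature more than half uncovered has median 0 regardless of how
deeply its covered half is piled — and keeps the statistic on one scale for
short and long features. Depths are exact integers and medians exact halves;
there is no floating accumulation in the pileup path.

MAG abundance is the **unweighted mean of its contigs' medians** (each
contig one vote); a length-weighted mean is available behind a flag and is
recorded in the output metadata, since the two differ when coverage varies
with contig length. ORF abundance is the median over the ORF span and is
the metatranscriptome unit.

## Normalization and filters

Sequencing depth varies by orders of magnitude between samples, so raw
medians are divided by a per-sample denominator: the sum of median coverages
of the single-copy housekeeping genes (HKGs) *detected* (median > 0) in that
sample. Including undetected HKGs would add zero terms; the retained-HKG
set is nevertheless restricted explicitly so the per-sample audit list is
meaningful. A sample with no detected HKG has no defined scale and is
excluded (reason `no_hkg_detected`) rather than normalized by zero. The
normalized values are exactly invariant to multiplying all depths in a
sample by any k > 0.

Gates, with deliberate boundary semantics:

* **MAG quality**: completeness strictly > 50% and contamination strictly
  < 10%; passing MAGs are tiered high (> 90%, < 5%) or medium, MIMAG-style.
* **Recruitment**: MAGs whose mean metaT read count across samples falls
  below `min_mean_reads` (default 100, configurable) are excluded — a
  genome averaging a few dozen mapped transcript reads carries no usable
  activity signal. Retention uses ≥, so the threshold itself passes.
* **ORF filter**: an ORF is kept when its mean normalized metaT abundance
  across retained samples (zeros included) is at or above the 25th
  percentile (linear interpolation) of the means of ORFs with any
  detection, AND it is detected in ≥ 10% of retained samples. The ORF is
  the ranked unit because it is the unit consumed downstream; an
  alternative mode pools positive ORF × sample values for the percentile
  and is recorded in the report metadata. Never-detected ORFs always fail.
* **Occupancy**: detection is strictly positive normalized abundance, with
  no epsilon floor — the full-span median already suppresses stray single
  reads on long features. Occupancy and mean abundance are computed over
  retained samples only.

## Seasonal statistics

The seasonal contrast is categorical by calendar month: May–June is early,
July–September late; dates outside that window are rejected loudly because
no statistic here is defined for them. Per MAG, the tested quantity is the
per-sample **cumulative** (summed) abundance of its retained ORFs. The test
is the two-group Kruskal–Wallis statistic with mid-ranks and tie
correction,

H = [12/(N(N+1))] Σ nᵢ(R̄ᵢ − (N+1)/2)² / [1 − Σ(t³−t)/(N³−N)],

referred to χ² with df = 1; the all-tied degenerate case is defined as
H = 0, p = 1. Direction (increase/decrease) is called from the group
medians at raw p < α (default 0.05); Benjamini–Hochberg adjusted p-values
are always written alongside so stricter calls can be applied, but they do
not drive the default call. Full enumeration of all untied configurations
with N ≤ 8 shows the χ² tail deviates from the exact permutation p by up to
0.446 (worst at N = 3, where the asymptotic reference is crudest; at the
design sizes used here, 8+8 and larger, the test's empirical size is within
Monte-Carlo error of α — the acceptance script measures it on 1000 null
communities). For exact small-sample inference the permutation distribution
should be enumerated instead; this package intentionally implements the
χ²-referenced test.

Role enrichment: per role, the per-sample cumulative abundance is the sum
over its retained ORFs across all MAGs; `ratio` is the late-season mean of
these sums over the early-season mean. A zero early mean yields an explicit
infinity flag by default; an epsilon policy (half the smallest nonzero
per-sample role abundance added to both means) is available when a finite
ranking is needed. The definition (means of per-sample sums) is recorded in
the output metadata. Multiplying all late-season abundances by k multiplies
every ratio by exactly k.

Subsystem trends: per-sample cumulative subsystem abundance is summarized
per date (mean and SEM with n−1 denominator) and regressed on day of year
by OLS with a two-sided t-test on the slope; when samples span multiple
years, year enters as an additive offset — the simplest structure
consistent with overlaying two seasons. Fewer than three distinct dates
omit the trend (with a warning) while means are still reported. An
essentially exact fit (residual variance at rounding level) reports p = 1
for a zero slope rather than a noise-driven t-ratio.

Pathway activity is deliberately minimal: *absent* (no member ORF in the
MAG), *detected_only* (members present, no member with positive metaT
median coverage in any sample), *active* (at least one member covered in at
least one sample). Activity is monotone in added reads. Pathway membership
arrives as input (pathway_id → ORF table); no annotation is re-derived.

## Clustering and support

MAG transcript profiles (rows = MAGs, columns = retained metaT samples in
chronological order) are clustered with Ward's minimum-variance method on
euclidean distances — the sum-of-squares ("Ward.D2"-style) formulation,
stated in the output metadata. Optional transforms: none (default),
log10(x + ε) with ε = half the minimum positive value, or per-row z-score
(zero-variance rows map to zero vectors). Edge support is a column
bootstrap: resample samples with replacement, recluster, and score each
original edge by the fraction of replicates in which its leaf set reappears
(bootstrap probability, BP). With multiple resample scales r, an
approximately-unbiased (AU) support is estimated from the weighted
least-squares fit of Φ⁻¹(1 − BP_r) = v√r + c/√r, AU = 1 − Φ(v − c); BP is
the mandatory statistic, AU optional. Degenerate resamples count with
whatever tree they produce — nothing is silently dropped. Grouping is
either a cut to k clusters or the maximal non-root edges with BP at or
above a threshold (remaining leaves become singletons); no automatic k
selection is pretended, and the chosen rule is recorded.

## Synthetic communities

The generator emulates the statistical structure the analysis assumes, not
sequence content (contig FASTA is uniform random ACGT and exists to
exercise I/O):

* **Geometry**: MAGs with 2–4 contigs of 3–6 kb, 4–8 non-overlapping ORFs
  of 400–900 bp per contig, two flagged single-copy HKGs per MAG. ORF
  counts and lengths are capped per contig so layouts always fit;
  infeasible configurations fail at validation with the offending range.
* **Design**: seven dates May–September over replicate plots, both assays —
  a single-crop season of leaf sampling; balanced n-early + n-late designs
  are available for calibration work.
* **Trajectories**: each MAG draws a log-normal base abundance (σ = 0.4)
  and one archetype — `early_peak` (geometric decay per date, default
  0.6), `late_rise` (geometric growth, default 1.7), or `flat`. ORF
  expression follows the MAG trajectory; HKGs follow it with factor exactly
  1.0 so the normalization denominator tracks genome abundance. Injected
  role fold changes multiply late-season expression of the role's
  non-housekeeping ORFs; housekeeping ORFs carry a reserved role so folds
  can never perturb the denominator. The default injected folds (53.2,
  29.7, 23.6) mirror the strongest late-season enrichments reported for
  real phyllosphere communities.
* **Reads**: fixed-length (150 bp) single-end intervals; per contig (metaG)
  or per ORF (metaT) counts are Poisson with mean
  abundance × depth_factor × length / read_length, uniform starts
  (within the ORF span for metaT), truncated at contig ends. The expected
  mean depth is abundance × depth_factor × (1 − (rl−1)/(2L)); the
  truncation term is the exact end-effect correction used by the tests.
  `depth_factor` (default 50) is chosen for statistical power at desk
  scale, not to mimic any particular sequencing depth.

What the generator does **not** emulate: sequencing error, host/chloroplast
contamination, rRNA carryover, paired-end structure, mapping ambiguity,
compositional coupling between MAGs. Passing tests therefore demonstrate
correctness of the estimators and calibration of the statistics under the
stated model, not robustness to those real-data artifacts.

## Verification set-up and problem sizes

The acceptance script and test suite use deliberately small, fast
conditions: 1000 random interval sets for the coverage oracle; 1000
independent single-MAG null communities (flat, fold-free, 8+8 samples,
depth 50) for the type-I rate; 50 seeded replicates of an 8-MAG flat
community with injected folds {5, 20, 50} for recovery (mean estimate
within ±20%); 100 random matrices with ≤ 6 rows for the Ward oracle; and a
12-MAG, 3-archetype community with 500 bootstrap resamples for
planted-cluster recovery. For the clustering recovery check the ORF filter
is run in detection-only mode (quantile 0): the global top-75% abundance
rule would otherwise strip low-abundance early-peaking genomes of their
ORFs and collapse their profiles to zero rows — worth knowing when
clustering real communities with strong abundance gradients.

## Known limitations

* The χ²-referenced Kruskal–Wallis p is approximate; at very small n use
  the enumerated permutation distribution.
* Median-of-Poisson abundances are quantized at low depth; ratios of
  single-sample abundances can deviate by several percent below ~50×
  depth even without biological noise.
* The recruitment-gate threshold is a policy choice (default 100 mean
  reads), not an estimated quantity.
* AU supports from the multiscale fit are unstable for edges with BP near
  0 or 1 at few usable scales; BP is the statistic to rely on.
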