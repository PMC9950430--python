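# magseason

Genome-centric quantification and seasonal-activity analysis for
metagenome-assembled genomes (MAGs) tracked across a growing season with
paired metagenome (metaG) and metatranscriptome (metaT) sequencing — the
kind of dataset produced by leaf-surface (phyllosphere) microbiome time
series on perennial crops, where the question is *which community members
are present, which are active, and when*.

## What it computes

Given per-sample read alignments to MAG contigs (BED intervals), ORF
annotations (GFF3 with functional role, subsystem and housekeeping-gene
flags), MAG quality estimates and sample metadata:

1. **Abundance** — the median basepair coverage of a feature: for a contig,
   the median over every base of the number of mapped reads covering it
   (zeros included); a MAG is the mean of its contigs' medians; an ORF is
   the median over its span. Per sample, abundances are normalized by the
   summed median coverage of the single-copy housekeeping genes (HKGs)
   detected in that sample, making values comparable across sequencing
   depths:

   `a(e, s) = median_cov(e, s) / Σ_{h ∈ HKG, cov>0} median_cov(h, s)`

   Samples with no detected HKG are excluded. MAGs are gated on
   completeness > 50% and contamination < 10%, and on mean metaT read
   recruitment; ORFs are kept when in the top 75% of mean observed
   abundances and detected in ≥ 10% of samples.
2. **Occupancy** — the fraction of retained samples in which a MAG is
   detected (normalized abundance > 0), alongside its mean abundance.
3. **Seasonal activity** — per MAG, the per-sample cumulative (summed)
   abundance of its retained ORFs is compared between the early (May–June)
   and late (July–September) season with a two-group Kruskal–Wallis test
   (tie-corrected H against χ² with df = 1); per functional role, the
   late:early ratio of season means of per-sample cumulative role
   abundances; per subsystem, mean ± SEM time series and an OLS trend
   against day of year; per pathway, an absent / detected-only / active
   call from transcript coverage of member ORFs.
4. **Transcript-dynamics clusters** — Ward (minimum-variance) hierarchical
   clustering of MAG × sample cumulative-transcript profiles on euclidean
   distances, with pvclust-style bootstrap support from resampling sample
   columns, and a k-cut or support-threshold grouping.

A fully seeded synthetic-community generator (`magseason.synthetic_community`)
produces datasets with known ground truth — seasonal trajectory archetypes
(early-peaking, late-rising, flat), injected role-level fold changes, and
Poisson read placement — so every stage is testable without external data.

## Worked example

`examples/` contains one narrative script per capability. For instance,
`python examples/03_seasonal_activity.py` simulates a flat 8-MAG community
whose roles `role_000/001/002` carry injected late:early transcript folds of
5×, 20× and 50×, then runs quantification → normalization → ORF filter →
seasonal tests → role enrichment, and prints:

```
ORF filter: 112/150 retained (top-75% abundance, >=10% detection)
MAGs with significant late-season increase: 8/8 (raw Kruskal-Wallis p < 0.05)

top roles by late:early transcript enrichment ratio:
 role_id  early_mean  late_mean     ratio  n_mags_detected
role_002    0.800560  40.792602 50.955064                6
role_001    1.100521  22.519221 20.462321                6
role_000    0.728850   3.714092  5.095825                7
role_004    1.291223   1.309433  1.014102                5
```

The ratio column recovers the injected folds (50.96 vs 50, 20.46 vs 20,
5.10 vs 5); roles without an injected fold sit near 1. Every MAG carries
fold-bearing ORFs, so all 8 show significantly increased late transcription.
`examples/04_cluster_dynamics.py` recovers three planted trajectory
archetypes with adjusted Rand index 1.0 and bootstrap probability 1.0 on
each planted group's edge.

## Command line

```bash
magseason run-all --config examples/demo_config.yaml --outdir out/
```

runs simulate → quantify → normalize → filter → seasonal → cluster and
writes TSV outputs plus `manifest.json` with a SHA-256 hash per file;
re-running with the same config and seed reproduces every hash. Stage
subcommands (`simulate`, `quantify`, `normalize`, `filter`, `seasonal`,
`cluster`) operate on the same file contract, and `validate-config` reports
every configuration problem at once.

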