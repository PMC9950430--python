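"""Generate a small synthetic phyllosphere dataset and write it to disk.

The generator lays out MAGs, contigs and ORFs (with flagged single-copy
housekeeping genes), assigns each MAG a seasonal trajectory archetype, and
places Poisson read intervals per sample.  Everything is seeded, so the
printed counts are reproducible.
"""

from magseason.synthetic_community import (
    SimConfig,
    build_community,
    default_sample_design,
    simulate_alignments,
    simulate_trajectories,
    write_dataset,
)

cfg = SimConfig(
    n_mags=8,
    sample_design=default_sample_design(plots=("p1", "p2")),
    depth_factor=30.0,
    seed=11,
)
model = build_community(cfg)
truth = simulate_trajectories(model, cfg)
alignments = simulate_alignments(model, truth, cfg)
paths = write_dataset(model, truth, alignments, cfg, "scratch/example_dataset")

n_reads = sum(a.n_intervals for a in alignments.values())
print(f"MAGs:        {len(model.mags)}")
print(f"contigs:     {len(model.contigs)}")
print(f"ORFs:        {len(model.orfs)} ({len(model.hkg_orfs())} housekeeping)")
print(f"samples:     {len(alignments)} (metaG + metaT over 7 dates, 2 plots)")
print(f"read spans:  {n_reads}")
print(f"archetypes:  {truth.cluster_membership}")
print(f"written to:  {paths['fasta'].parent}")
# Each MAG follows one archetype: 'early_peak' declines over the season,
# 'late_rise' increases, 'flat' stays constant; reads per contig/ORF are
# Poisson draws around abundance x depth_factor.
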