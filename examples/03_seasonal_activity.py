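"""Early-vs-late seasonal activity testing and role-level fold enrichment.

A flat community carries three functional roles with injected late:early
transcript fold changes (5x, 20x, 50x).  The pipeline recovers them: the
per-MAG Kruskal-Wallis test calls increased late transcription, and the role
enrichment ratio estimates each injected fold.
"""

import warnings

from magseason import coverage, normalize_filter as nf, seasonal_stats as ss
from magseason.synthetic_community import (
    SimConfig,
    balanced_design,
    build_community,
    simulate_alignments,
    simulate_trajectories,
)

folds = {"role_000": 5.0, "role_001": 20.0, "role_002": 50.0}
cfg = SimConfig(
    n_mags=8,
    n_roles=8,
    sample_design=balanced_design(n_early_dates=2, n_late_dates=2),  # 8+8 metaT
    trajectory_archetypes={"flat": {}},
    injected_role_foldchanges=folds,
    depth_factor=50.0,
    seed=2,
)
model = build_community(cfg)
truth = simulate_trajectories(model, cfg)
alignments = simulate_alignments(model, truth, cfg)
samples = cfg.samples()

_, orf_tab = coverage.coverage_tables(
    {s.sample_id: alignments[s.sample_id] for s in samples}, model
)
denoms, dropped = nf.hkg_denominators(orf_tab, model, [s.sample_id for s in samples])
abund = nf.normalize(orf_tab, denoms, dropped, assay="metaT")
report = nf.orf_filter(abund, orf_ids=sorted(model.orfs))
retained = set(report.loc[report.retained, "orf_id"])
print(f"ORF filter: {len(retained)}/{len(model.orfs)} retained "
      f"(top-75% abundance, >=10% detection)")

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    cumulative = ss.mag_cumulative_transcripts(abund, model, retained)
tests = ss.test_all_mags(cumulative, samples, alpha=0.05)
n_up = (tests["direction"] == "increase").sum()
print(f"MAGs with significant late-season increase: {n_up}/{len(tests)} "
      f"(raw Kruskal-Wallis p < 0.05)")

enrichment = ss.role_enrichment(abund, model, samples, retained)
print("\ntop roles by late:early transcript enrichment ratio:")
print(enrichment.head(4)[
    ["role_id", "early_mean", "late_mean", "ratio", "n_mags_detected"]
].to_string(index=False))
print("\ninjected folds were:", folds)
# The ratio column estimates each injected fold change; roles without
# injected folds sit near 1 (no seasonal signal beyond noise).
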