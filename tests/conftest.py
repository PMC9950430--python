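"""Shared fixtures: a tiny hand-built community and fast simulation helpers."""

from __future__ import annotations

import datetime as dt

import pytest

from magseason.model import (
    AlignmentSet,
    CommunityModel,
    MagRecord,
    OrfRecord,
    SampleRecord,
)
from magseason.synthetic_community import SimConfig, balanced_design


def build_tiny_model() -> CommunityModel:
    """Two MAGs, three contigs, hand-placed ORFs with known coordinates."""
    model = CommunityModel()
    model.mags = {
        "magA": MagRecord("magA", 95.0, 2.0),
        "magB": MagRecord("magB", 70.0, 5.0),
    }
    model.contigs = {
        "c1": ("magA", 100),
        "c2": ("magA", 50),
        "c3": ("magB", 80),
    }
    model.orfs = {
        "o1": OrfRecord("o1", "c1", 10, 40, "+", "roleX", "sub1", is_hkg=True),
        "o2": OrfRecord("o2", "c1", 50, 90, "-", "roleY", "sub1"),
        "o3": OrfRecord("o3", "c2", 0, 30, "+", "roleX", "sub1"),
        "o4": OrfRecord("o4", "c3", 20, 60, "+", "roleZ", "sub2", is_hkg=True),
    }
    model.validate()
    return model


@pytest.fixture
def tiny_model() -> CommunityModel:
    return build_tiny_model()


@pytest.fixture
def tiny_samples() -> list[SampleRecord]:
    return [
        SampleRecord("sE1", "switchgrass", dt.date(2017, 5, 20), "p1", "metaT"),
        SampleRecord("sE2", "switchgrass", dt.date(2017, 6, 10), "p1", "metaT"),
        SampleRecord("sL1", "switchgrass", dt.date(2017, 8, 1), "p1", "metaT"),
        SampleRecord("sL2", "switchgrass", dt.date(2017, 9, 5), "p1", "metaT"),
    ]


def make_alignments(sample_id: str, intervals) -> AlignmentSet:
    return AlignmentSet(sample_id, intervals)


def null_simconfig(seed: int, n_mags: int = 1) -> SimConfig:
    """A flat, fold-free community on an 8 early + 8 late metaT design."""
    return SimConfig(
        n_mags=n_mags,
        contigs_per_mag=(1, 1),
        contig_length=(1800, 2200),
        orfs_per_contig=(4, 4),
        orf_length=(300, 420),
        n_hkg_per_mag=1,
        n_roles=6,
        n_subsystems=3,
        sample_design=balanced_design(n_early_dates=2, n_late_dates=2),
        trajectory_archetypes={"flat": {}},
        injected_role_foldchanges={},
        read_length=150,
        depth_factor=50.0,
        seed=seed,
    )


def fold_simconfig(seed: int, folds: dict[str, float]) -> SimConfig:
    """Flat community with injected role fold changes, 8+8 metaT samples."""
    return SimConfig(
        n_mags=8,
        contigs_per_mag=(2, 3),
        contig_length=(2500, 4000),
        orfs_per_contig=(4, 6),
        orf_length=(350, 700),
        n_hkg_per_mag=2,
        n_roles=max(6, len(folds) + 3),
        n_subsystems=4,
        sample_design=balanced_design(n_early_dates=2, n_late_dates=2),
        trajectory_archetypes={"flat": {}},
        injected_role_foldchanges=folds,
        read_length=150,
        depth_factor=50.0,
        seed=seed,
    )


def run_metat_chain(cfg: SimConfig, abundance_quantile=0.25, min_detection_frac=0.10):
    """Simulate and run the metatranscriptome chain up to the ORF filter.

    Returns (model, truth, metaT samples, normalized ORF abundances,
    retained ORF ids).
    """
    from magseason import coverage, normalize_filter as nf
    from magseason.synthetic_community import (
        build_community,
        simulate_alignments,
        simulate_trajectories,
    )

    model = build_community(cfg)
    truth = simulate_trajectories(model, cfg)
    alns = simulate_alignments(model, truth, cfg)
    samples = [s for s in cfg.samples() if s.assay == "metaT"]
    _, orf_tab = coverage.coverage_tables(
        {s.sample_id: alns[s.sample_id] for s in samples}, model
    )
    dens, dropped = nf.hkg_denominators(orf_tab, model, [s.sample_id for s in samples])
    abund = nf.normalize(orf_tab, dens, dropped, "metaT")
    report = nf.orf_filter(
        abund,
        abundance_quantile=abundance_quantile,
        min_detection_frac=min_detection_frac,
        orf_ids=sorted(model.orfs),
    )
    retained = set(report.loc[report.retained, "orf_id"])
    return model, truth, samples, abund, retained


def archetype_simconfig(seed: int, n_mags: int = 12) -> SimConfig:
    """Three planted archetypes with strong shape separation, metaT-only."""
    return SimConfig(
        n_mags=n_mags,
        contigs_per_mag=(2, 3),
        contig_length=(2500, 4000),
        orfs_per_contig=(4, 6),
        orf_length=(350, 700),
        n_hkg_per_mag=2,
        n_roles=12,
        n_subsystems=4,
        sample_design=balanced_design(
            n_early_dates=3, n_late_dates=4, plots=("p1", "p2")
        ),
        trajectory_archetypes={
            "early_peak": {"decay": 0.55},
            "late_rise": {"growth": 1.8},
            "flat": {},
        },
        injected_role_foldchanges={},
        read_length=150,
        depth_factor=50.0,
        seed=seed,
    )
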