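"""Generator contracts: geometry, determinism, trajectories, read placement."""

from __future__ import annotations

import datetime as dt

import numpy as np
import pytest

from magseason.model import ConfigurationError, season_of
from magseason.synthetic_community import (
    SimConfig,
    balanced_design,
    build_community,
    default_sample_design,
    simulate_alignments,
    simulate_trajectories,
    write_dataset,
)
from conftest import null_simconfig


def small_cfg(**overrides) -> SimConfig:
    base = dict(
        n_mags=2,
        contigs_per_mag=(1, 1),
        contig_length=(2000, 2500),
        orfs_per_contig=(3, 3),
        orf_length=(300, 500),
        n_hkg_per_mag=1,
        n_roles=4,
        n_subsystems=2,
        sample_design=balanced_design(plots=("p1",), assays=("metaG", "metaT")),
        injected_role_foldchanges={},
        seed=5,
    )
    base.update(overrides)
    return SimConfig(**base)


class TestBuildCommunity:
    def test_counts_forced_by_config(self):
        model = build_community(small_cfg())
        assert len(model.mags) == 2
        assert len(model.contigs) == 2
        assert len(model.orfs) == 6
        for mag_id in model.mags:
            assert len(model.hkg_orfs(mag_id)) == 1

    def test_determinism_same_seed(self):
        m1 = build_community(small_cfg())
        m2 = build_community(small_cfg())
        assert m1.orfs == m2.orfs and m1.contigs == m2.contigs and m1.mags == m2.mags

    def test_infeasible_orf_length_raises(self):
        cfg = small_cfg(orf_length=(3000, 4000))
        with pytest.raises(ConfigurationError, match="orf_length"):
            build_community(cfg)

    def test_orfs_fit_without_overlap(self):
        model = build_community(
            small_cfg(n_mags=5, contigs_per_mag=(1, 3), orfs_per_contig=(2, 6))
        )
        by_contig: dict[str, list] = {}
        for orf in model.orfs.values():
            by_contig.setdefault(orf.contig_id, []).append(orf)
        for contig_id, orfs in by_contig.items():
            orfs.sort(key=lambda o: o.start)
            length = model.contig_length(contig_id)
            for a, b in zip(orfs, orfs[1:]):
                assert a.end <= b.start
            assert orfs[-1].end <= length

    def test_every_orf_has_one_role_and_subsystem(self):
        model = build_community(small_cfg())
        assert all(o.role_id and o.subsystem_id for o in model.orfs.values())


class TestTrajectories:
    def test_flat_archetype_constant(self):
        cfg = small_cfg(trajectory_archetypes={"flat": {}})
        model = build_community(cfg)
        truth = simulate_trajectories(model, cfg)
        dates = sorted({d for d, *_ in cfg.sample_design})
        for mag_id in model.mags:
            vals = [truth.mag_trajectory[(mag_id, d.isoformat())] for d in dates]
            assert vals == pytest.approx([vals[0]] * len(vals))

    def test_late_rise_monotone_increase(self):
        cfg = small_cfg(trajectory_archetypes={"late_rise": {"growth": 1.5}})
        model = build_community(cfg)
        truth = simulate_trajectories(model, cfg)
        dates = sorted({d for d, *_ in cfg.sample_design})
        for mag_id in model.mags:
            vals = [truth.mag_trajectory[(mag_id, d.isoformat())] for d in dates]
            assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_early_peak_declines_after_peak(self):
        cfg = small_cfg(trajectory_archetypes={"early_peak": {"decay": 0.5}})
        model = build_community(cfg)
        truth = simulate_trajectories(model, cfg)
        dates = sorted({d for d, *_ in cfg.sample_design})
        for mag_id in model.mags:
            vals = [truth.mag_trajectory[(mag_id, d.isoformat())] for d in dates]
            assert all(b < a for a, b in zip(vals, vals[1:]))

    def test_injected_fold_exact_in_truth(self):
        cfg = small_cfg(
            trajectory_archetypes={"flat": {}},
            injected_role_foldchanges={"role_000": 20.0},
        )
        model = build_community(cfg)
        truth = simulate_trajectories(model, cfg)
        dates = sorted({d for d, *_ in cfg.sample_design})
        early = [d.isoformat() for d in dates if season_of(d) == "early"]
        late = [d.isoformat() for d in dates if season_of(d) == "late"]
        targets = [
            o for o in model.orfs.values() if o.role_id == "role_000" and not o.is_hkg
        ]
        assert targets, "generator placed no ORF of the injected role"
        for orf in targets:
            e = np.mean([truth.orf_expression[(orf.orf_id, d)] for d in early])
            l = np.mean([truth.orf_expression[(orf.orf_id, d)] for d in late])
            assert l / e == pytest.approx(20.0)

    def test_hkg_expression_tracks_mag_trajectory(self):
        cfg = small_cfg(injected_role_foldchanges={"role_000": 50.0})
        model = build_community(cfg)
        truth = simulate_trajectories(model, cfg)
        for orf in model.hkg_orfs():
            mag_id = model.mag_of_contig(orf.contig_id)
            for d in sorted({d for d, *_ in cfg.sample_design}):
                key = d.isoformat()
                assert truth.orf_expression[(orf.orf_id, key)] == pytest.approx(
                    truth.mag_trajectory[(mag_id, key)]
                )

    def test_single_season_design_rejected(self):
        cfg = small_cfg(
            sample_design=[
                (dt.date(2017, 5, 15), "p1", "switchgrass", "metaT"),
                (dt.date(2017, 6, 20), "p1", "switchgrass", "metaT"),
            ]
        )
        model = build_community(cfg)
        with pytest.raises(ConfigurationError, match="both early"):
            simulate_trajectories(model, cfg)


class TestAlignments:
    def test_zero_depth_factor_gives_no_reads(self):
        cfg = small_cfg(depth_factor=0.0)
        model = build_community(cfg)
        truth = simulate_trajectories(model, cfg)
        alns = simulate_alignments(model, truth, cfg)
        assert all(a.n_intervals == 0 for a in alns.values())

    def test_metag_mean_depth_matches_poisson_expectation(self):
        """Observed mean depth across seeds sits within 3 SE of the exact
        expectation a*depth_factor*(1 - (read_length-1)/(2L)) (end truncation
        accounted for)."""
        depths = []
        expected = None
        for seed in range(50):
            cfg = small_cfg(
                trajectory_archetypes={"flat": {}},
                base_abundance_sigma=0.0,  # abundance exactly 1.0
                depth_factor=20.0,
                seed=seed,
            )
            model = build_community(cfg)
            truth = simulate_trajectories(model, cfg)
            alns = simulate_alignments(model, truth, cfg)
            sample = next(
                s for s in cfg.samples() if s.assay == "metaG"
            )
            contig_id = sorted(model.contigs)[0]
            length = model.contig_length(contig_id)
            if expected is None:
                expected = 20.0 * (1 - (cfg.read_length - 1) / (2 * length))
            arr = alns[sample.sample_id].arrays().get(contig_id)
            total = int((arr[:, 1] - arr[:, 0]).sum()) if arr is not None else 0
            depths.append(total / length)
        depths = np.array(depths)
        se = depths.std(ddof=1) / np.sqrt(len(depths))
        assert abs(depths.mean() - expected) < 3 * se + 1e-9

    def test_metat_reads_start_inside_orfs(self):
        cfg = small_cfg()
        model = build_community(cfg)
        truth = simulate_trajectories(model, cfg)
        alns = simulate_alignments(model, truth, cfg)
        spans = {
            c: [(o.start, o.end) for o in model.orfs.values() if o.contig_id == c]
            for c in model.contigs
        }
        for sample in cfg.samples():
            if sample.assay != "metaT":
                continue
            for contig_id, start, end in alns[sample.sample_id].intervals:
                assert any(s <= start < e for s, e in spans[contig_id])
                assert end - start <= cfg.read_length

    def test_reads_truncated_at_contig_end(self):
        cfg = small_cfg()
        model = build_community(cfg)
        truth = simulate_trajectories(model, cfg)
        alns = simulate_alignments(model, truth, cfg)
        for alns_set in alns.values():
            for contig_id, start, end in alns_set.intervals:
                length = model.contig_length(contig_id)
                assert end <= length
                assert end - start == min(cfg.read_length, length - start)


class TestWriteDataset:
    def test_written_files_are_byte_deterministic(self, tmp_path):
        cfg = small_cfg()
        model = build_community(cfg)
        truth = simulate_trajectories(model, cfg)
        alns = simulate_alignments(model, truth, cfg)
        p1 = write_dataset(model, truth, alns, cfg, tmp_path / "a")
        p2 = write_dataset(model, truth, alns, cfg, tmp_path / "b")
        for key in ("fasta", "gff3", "samples", "quality", "pathways", "truth"):
            assert p1[key].read_bytes() == p2[key].read_bytes()

    def test_bed_span_equals_read_length_unless_truncated(self, tmp_path):
        cfg = small_cfg()
        model = build_community(cfg)
        truth = simulate_trajectories(model, cfg)
        alns = simulate_alignments(model, truth, cfg)
        paths = write_dataset(model, truth, alns, cfg, tmp_path / "ds")
        some_bed = next(iter(sorted(paths["bed_dir"].glob("*.bed"))))
        for line in some_bed.read_text().splitlines():
            contig_id, start, end = line.split("\t")
            length = model.contig_length(contig_id)
            span = int(end) - int(start)
            assert span == cfg.read_length or int(end) == length
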