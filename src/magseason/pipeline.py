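"""End-to-end orchestration: simulate/load -> quantify -> normalize ->
filter -> seasonal statistics -> clustering, with a hash-stable manifest.

Stages communicate through plain TSV files in the output directory so that
each is independently scriptable; :func:`run_pipeline` wires them together
and writes ``manifest.json`` listing every output with a SHA-256 content hash
and the fully materialized configuration.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import cluster_support, coverage, normalize_filter, seasonal_stats
from .model import CommunityModel, ConfigurationError, SampleRecord
from .synthetic_community import (
    GroundTruth,
    SimConfig,
    balanced_design,
    build_community,
    default_sample_design,
    read_dataset,
    simulate_alignments,
    simulate_trajectories,
    write_dataset,
)

__all__ = ["RunConfig", "validate_config", "run_pipeline", "simconfig_from_dict"]

log = logging.getLogger("magseason")


@dataclass
class RunConfig:
    """Declarative pipeline configuration with all thresholds materialized."""

    simulate: dict | None = None
    input_dir: str | None = None
    alpha: float = 0.05
    abundance_quantile: float = 0.25
    min_detection_frac: float = 0.10
    min_completeness: float = 50.0
    max_contamination: float = 10.0
    min_mean_reads: float = 100.0
    n_boot: int = 200
    k: int = 5
    transform: str = "none"
    pseudo_policy: str = "flag"
    length_weighted: bool = False
    seed: int = 0

    def effective(self) -> dict:
        return asdict(self)


def simconfig_from_dict(block: dict) -> SimConfig:
    """Build a :class:`SimConfig` from a YAML ``simulate`` block.

    ``sample_design`` may be given explicitly as rows of
    ``[iso_date, plot, crop, assay]`` or via ``design_preset``
    (``default`` or ``balanced``) with optional preset kwargs.
    """
    block = dict(block)
    preset = block.pop("design_preset", None)
    preset_kwargs = block.pop("design_kwargs", {})
    design = block.pop("sample_design", None)
    kwargs: dict = {}
    for key in (
        "n_mags",
        "n_hkg_per_mag",
        "n_roles",
        "n_subsystems",
        "read_length",
        "seed",
    ):
        if key in block:
            kwargs[key] = int(block.pop(key))
    for key in ("depth_factor", "base_abundance_sigma"):
        if key in block:
            kwargs[key] = float(block.pop(key))
    for key in ("contigs_per_mag", "contig_length", "orfs_per_contig", "orf_length"):
        if key in block:
            lo, hi = block.pop(key)
            kwargs[key] = (int(lo), int(hi))
    for key in ("trajectory_archetypes", "injected_role_foldchanges"):
        if key in block:
            kwargs[key] = block.pop(key)
    if block:
        raise ConfigurationError(f"unknown simulate keys: {sorted(block)}")
    if design is not None:
        kwargs["sample_design"] = [
            (_dt.date.fromisoformat(d), p, c, a) for d, p, c, a in design
        ]
    elif preset == "balanced":
        kwargs["sample_design"] = balanced_design(**preset_kwargs)
    elif preset in (None, "default"):
        kwargs["sample_design"] = default_sample_design(**preset_kwargs)
    else:
        raise ConfigurationError(f"unknown design_preset {preset!r}")
    return SimConfig(**kwargs)


def validate_config(raw: dict) -> tuple[RunConfig | None, list[str]]:
    """Normalize a raw config dict; report ALL problems, not the first."""
    errors: list[str] = []
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        errors.append(f"unknown config keys: {sorted(unknown)}")
    merged = {k: v for k, v in raw.items() if k in known}
    cfg = RunConfig(**merged)
    if cfg.simulate is None and cfg.input_dir is None:
        errors.append("either a 'simulate' block or 'input_dir' is required")
    if cfg.simulate is not None and cfg.input_dir is not None:
        errors.append("'simulate' and 'input_dir' are mutually exclusive")
    if cfg.input_dir is not None and not Path(cfg.input_dir).is_dir():
        errors.append(f"input_dir {cfg.input_dir} does not exist")
    if not (0 < cfg.alpha < 1):
        errors.append(f"alpha must be in (0, 1), got {cfg.alpha}")
    if not (0 <= cfg.abundance_quantile < 1):
        errors.append(f"abundance_quantile must be in [0, 1), got {cfg.abundance_quantile}")
    if not (0 <= cfg.min_detection_frac <= 1):
        errors.append(f"min_detection_frac must be in [0, 1], got {cfg.min_detection_frac}")
    if not (0 <= cfg.min_completeness <= 100):
        errors.append(f"min_completeness must be in [0, 100], got {cfg.min_completeness}")
    if cfg.max_contamination < 0:
        errors.append(f"max_contamination must be >= 0, got {cfg.max_contamination}")
    if cfg.min_mean_reads < 0:
        errors.append(f"min_mean_reads must be >= 0, got {cfg.min_mean_reads}")
    if cfg.n_boot < 100:
        errors.append(f"n_boot must be >= 100, got {cfg.n_boot}")
    if cfg.k < 1:
        errors.append(f"k must be >= 1, got {cfg.k}")
    if cfg.transform not in ("none", "log10", "zscore"):
        errors.append(f"transform must be none/log10/zscore, got {cfg.transform}")
    if cfg.pseudo_policy not in ("flag", "epsilon"):
        errors.append(f"pseudo_policy must be flag/epsilon, got {cfg.pseudo_policy}")
    if cfg.simulate is not None:
        try:
            simconfig_from_dict(cfg.simulate).validate()
        except (ConfigurationError, TypeError, ValueError) as exc:
            errors.append(f"simulate block invalid: {exc}")
    return (cfg if not errors else None), errors


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg, errors = validate_config(raw)
    if errors:
        raise ConfigurationError("; ".join(errors))
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


_STAGE_ORDER = ["dataset", "quantify", "normalize", "filter", "seasonal", "cluster"]


def run_pipeline(
    cfg: RunConfig, outdir: str | Path, stop_after: str = "cluster"
) -> dict:
    """Execute stages in dependency order and return the manifest.

    ``stop_after`` truncates the chain after the named stage; earlier stages
    always run (they are deterministic and cheap at desk scale, so rerunning
    is equivalent to resuming from their TSV outputs).
    """
    if stop_after not in _STAGE_ORDER:
        raise ConfigurationError(f"unknown stage {stop_after!r}")
    stop_idx = _STAGE_ORDER.index(stop_after)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    t0 = time.monotonic()

    def stage(name: str) -> None:
        log.info("stage %-10s %6.1fs", name, time.monotonic() - t0)

    def done(name: str) -> bool:
        return _STAGE_ORDER.index(name) >= stop_idx

    def finish(extra: dict) -> dict:
        manifest = {
            "config": cfg.effective(),
            "stop_after": stop_after,
            "outputs": {
                str(p.relative_to(outdir)): _sha256(p) for p in sorted(set(outputs))
            },
            **extra,
        }
        with open(outdir / "manifest.json", "w", newline="\n") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
            fh.write("\n")
        stage("manifest")
        return manifest

    # -- simulate / load ---------------------------------------------------
    if cfg.simulate is not None:
        sim = simconfig_from_dict(cfg.simulate)
        model = build_community(sim)
        truth = simulate_trajectories(model, sim)
        alignments = simulate_alignments(model, truth, sim)
        dataset_dir = outdir / "dataset"
        paths = write_dataset(model, truth, alignments, sim, dataset_dir)
        samples = sim.samples()
        outputs.extend(
            p for p in sorted(dataset_dir.rglob("*")) if p.is_file()
        )
        pathway_defs = _read_pathways(paths["pathways"])
    else:
        dataset_dir = Path(cfg.input_dir)
        required = ["contigs.fasta", "orfs.gff3", "samples.tsv", "mag_quality.tsv"]
        missing = [f for f in required if not (dataset_dir / f).exists()]
        if missing:
            raise ConfigurationError(
                f"input_dir {dataset_dir} is missing required files: {missing}"
            )
        model, samples, alignments, truth = read_dataset(dataset_dir)
        pathways_path = dataset_dir / "pathways.tsv"
        pathway_defs = _read_pathways(pathways_path) if pathways_path.exists() else None
    stage("dataset")
    if done("dataset"):
        return finish({"n_samples": len(samples)})

    metaG = [s for s in samples if s.assay == "metaG"]
    metaT = [s for s in samples if s.assay == "metaT"]

    # -- quantify ----------------------------------------------------------
    covG_contig, covG_orf = coverage.coverage_tables(
        {s.sample_id: alignments[s.sample_id] for s in metaG}, model
    )
    covT_contig, covT_orf = coverage.coverage_tables(
        {s.sample_id: alignments[s.sample_id] for s in metaT}, model
    )
    mag_cov = coverage.mag_coverage(
        covG_contig,
        model,
        sample_ids=[s.sample_id for s in metaG],
        length_weighted=cfg.length_weighted,
    )
    counts, mean_reads = coverage.recruitment_counts(
        alignments, model, sample_ids=[s.sample_id for s in metaT]
    )
    covG_contig.to_tsv(outdir / "coverage_contig_metaG.tsv")
    covG_orf.to_tsv(outdir / "coverage_orf_metaG.tsv")
    covT_orf.to_tsv(outdir / "coverage_orf_metaT.tsv")
    mag_cov.to_tsv(outdir / "coverage_mag_metaG.tsv")
    _write_tsv(
        pd.DataFrame(
            [
                {"mag_id": m, "sample_id": s, "reads": n}
                for (m, s), n in sorted(counts.items())
            ],
            columns=["mag_id", "sample_id", "reads"],
        ),
        outdir / "recruitment_metaT.tsv",
    )
    outputs += [
        outdir / "coverage_contig_metaG.tsv",
        outdir / "coverage_orf_metaG.tsv",
        outdir / "coverage_orf_metaT.tsv",
        outdir / "coverage_mag_metaG.tsv",
        outdir / "recruitment_metaT.tsv",
    ]
    stage("quantify")
    if done("quantify"):
        return finish({"n_samples": len(samples)})

    # -- normalize ---------------------------------------------------------
    denG, dropG = normalize_filter.hkg_denominators(
        covG_orf, model, [s.sample_id for s in metaG]
    )
    denT, dropT = normalize_filter.hkg_denominators(
        covT_orf, model, [s.sample_id for s in metaT]
    )
    abund_mag_G = normalize_filter.normalize(mag_cov, denG, dropG, assay="metaG")
    abund_orf_T = normalize_filter.normalize(covT_orf, denT, dropT, assay="metaT")
    abund_mag_G.to_tsv(outdir / "abundance_mag_metaG.tsv")
    abund_orf_T.to_tsv(outdir / "abundance_orf_metaT.tsv")
    _write_tsv(
        pd.DataFrame(
            [
                {"sample_id": s, "assay": a, "denominator": d}
                for a, dens in (("metaG", denG), ("metaT", denT))
                for s, d in sorted(dens.items())
            ],
            columns=["sample_id", "assay", "denominator"],
        ),
        outdir / "hkg_denominators.tsv",
    )
    _write_tsv(
        pd.DataFrame(
            [
                {"sample_id": s, "assay": a, "reason": r}
                for a, drop in (("metaG", dropG), ("metaT", dropT))
                for s, r in sorted(drop.items())
            ],
            columns=["sample_id", "assay", "reason"],
        ),
        outdir / "dropped_samples.tsv",
    )
    outputs += [
        outdir / "abundance_mag_metaG.tsv",
        outdir / "abundance_orf_metaT.tsv",
        outdir / "hkg_denominators.tsv",
        outdir / "dropped_samples.tsv",
    ]
    stage("normalize")
    if done("normalize"):
        return finish({"n_samples": len(samples)})

    # -- gates, occupancy, ORF filter --------------------------------------
    gate = normalize_filter.mag_quality_gate(
        list(model.mags.values()),
        min_completeness=cfg.min_completeness,
        max_contamination=cfg.max_contamination,
    )
    rgate = normalize_filter.recruitment_gate(mean_reads, cfg.min_mean_reads)
    focal = sorted(
        set(gate.loc[gate["passed"], "mag_id"]) & set(rgate.loc[rgate["passed"], "mag_id"])
    )
    occupancy = normalize_filter.detect_and_occupancy(
        abund_mag_G, entity_ids=sorted(model.mags)
    )
    focal_orfs = [
        o.orf_id
        for o in model.orfs.values()
        if model.mag_of_contig(o.contig_id) in set(focal)
    ]
    orf_report = normalize_filter.orf_filter(
        abund_orf_T,
        abundance_quantile=cfg.abundance_quantile,
        min_detection_frac=cfg.min_detection_frac,
        orf_ids=sorted(focal_orfs),
    )
    retained_orfs = set(orf_report.loc[orf_report["retained"], "orf_id"])
    _write_tsv(gate, outdir / "mag_gate.tsv")
    _write_tsv(rgate, outdir / "recruitment_gate.tsv")
    _write_tsv(occupancy, outdir / "occupancy_abundance.tsv")
    _write_tsv(orf_report, outdir / "orf_filter.tsv")
    (outdir / "focal_mags.txt").write_text("\n".join(focal) + "\n")
    outputs += [
        outdir / "mag_gate.tsv",
        outdir / "recruitment_gate.tsv",
        outdir / "occupancy_abundance.tsv",
        outdir / "orf_filter.tsv",
        outdir / "focal_mags.txt",
    ]
    stage("filter")
    summary = {
        "n_samples": len(samples),
        "n_focal_mags": len(focal),
        "n_retained_orfs": len(retained_orfs),
    }
    if done("filter"):
        return finish(summary)

    # -- seasonal statistics -------------------------------------------------
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        cumulative = seasonal_stats.mag_cumulative_transcripts(
            abund_orf_T, model, retained_orfs, mag_ids=focal
        )
    retained_metaT = [s for s in metaT if s.sample_id in set(abund_orf_T.sample_ids)]
    tests = seasonal_stats.test_all_mags(cumulative, retained_metaT, alpha=cfg.alpha)
    enrichment = seasonal_stats.role_enrichment(
        abund_orf_T, model, retained_metaT, retained_orfs, pseudo_policy=cfg.pseudo_policy
    )
    ts, trend = seasonal_stats.subsystem_timeseries(
        abund_orf_T, model, retained_metaT, retained_orfs
    )
    prevalence = seasonal_stats.role_prevalence(model, retained_orfs)
    _write_tsv(
        pd.DataFrame(
            [
                {"mag_id": m, "sample_id": s, "cumulative_abundance": v}
                for (m, s), v in sorted(cumulative.items())
            ],
            columns=["mag_id", "sample_id", "cumulative_abundance"],
        ),
        outdir / "cumulative_transcripts.tsv",
    )
    _write_tsv(tests, outdir / "seasonal_tests.tsv")
    _write_tsv(enrichment, outdir / "role_enrichment.tsv")
    _write_tsv(ts, outdir / "subsystem_timeseries.tsv")
    _write_tsv(trend, outdir / "subsystem_trend.tsv")
    _write_tsv(
        pd.DataFrame(
            [{"role_id": r, "n_mags": n} for r, n in prevalence.items()],
            columns=["role_id", "n_mags"],
        ),
        outdir / "role_prevalence.tsv",
    )
    outputs += [
        outdir / "cumulative_transcripts.tsv",
        outdir / "seasonal_tests.tsv",
        outdir / "role_enrichment.tsv",
        outdir / "subsystem_timeseries.tsv",
        outdir / "subsystem_trend.tsv",
        outdir / "role_prevalence.tsv",
    ]
    if pathway_defs is not None:
        activity = seasonal_stats.pathway_activity(model, pathway_defs, covT_orf)
        _write_tsv(activity, outdir / "pathway_activity.tsv")
        outputs.append(outdir / "pathway_activity.tsv")
    stage("seasonal")
    if done("seasonal"):
        return finish(summary)

    # -- clustering --------------------------------------------------------
    matrix = cluster_support.profile_matrix(
        cumulative, retained_metaT, transform=cfg.transform
    )
    linkage = cluster_support.ward_cluster(matrix)
    support = cluster_support.bootstrap_support(
        matrix, n_boot=cfg.n_boot, seed=cfg.seed
    )
    k = min(cfg.k, matrix.shape[0])
    labels = cluster_support.cut_groups(linkage, k=k)
    report = cluster_support.ClusterReport(
        linkage=linkage,
        mag_ids=list(matrix.index),
        assignments={m: int(l) for m, l in zip(matrix.index, labels)},
        edge_support=support,
        n_boot=cfg.n_boot,
        seed=cfg.seed,
        cut=f"k={k}",
    )
    _write_tsv(report.assignments_frame(), outdir / "clusters.tsv")
    _write_tsv(report.linkage_frame(), outdir / "linkage.tsv")
    _write_tsv(report.support_frame(), outdir / "edge_support.tsv")
    (outdir / "dendrogram.nwk").write_text(
        cluster_support.to_newick(linkage, list(matrix.index), support) + "\n"
    )
    outputs += [
        outdir / "clusters.tsv",
        outdir / "linkage.tsv",
        outdir / "edge_support.tsv",
        outdir / "dendrogram.nwk",
    ]
    stage("cluster")
    return finish(summary)


def _read_pathways(path: Path) -> dict[str, list[str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    defs: dict[str, list[str]] = {}
    for row in df.itertuples():
        defs.setdefault(row.pathway_id, []).append(row.orf_id)
    return defs
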