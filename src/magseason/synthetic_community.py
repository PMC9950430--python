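"""Synthetic phyllosphere community generator.

Builds a fully specified dataset — a community model of MAGs/contigs/ORFs with
flagged single-copy housekeeping genes, per-sample read-alignment intervals,
sample metadata and a ground-truth record — with the statistical structure the
downstream analysis assumes:

* MAG relative-abundance trajectories follow one of three seasonal archetypes
  (``early_peak`` declining after an early maximum, ``late_rise`` increasing
  monotonically, ``flat`` constant), mirroring the early/late/consistent
  detection patterns seen in leaf-surface communities over a growing season.
* Functional roles can carry injected late:early transcript fold changes.
* Reads are fixed-length single-end intervals placed with Poisson counts —
  contig-wide for metagenomes, within ORF spans for metatranscriptomes.

Everything is seeded and byte-reproducible, so downstream stages are testable
against known truth without any external data.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io_formats
from .model import (
    AlignmentSet,
    CommunityModel,
    ConfigurationError,
    MagRecord,
    OrfRecord,
    SampleRecord,
    season_of,
)

__all__ = [
    "SimConfig",
    "GroundTruth",
    "default_sample_design",
    "balanced_design",
    "build_community",
    "simulate_trajectories",
    "simulate_alignments",
    "write_dataset",
    "read_dataset",
]

#: Role and subsystem labels reserved for housekeeping ORFs, so injected role
#: fold changes never touch the normalization denominator.
HKG_ROLE = "housekeeping"
HKG_SUBSYSTEM = "core"


def default_sample_design(
    year: int = 2017,
    plots: tuple[str, ...] = ("p1", "p2", "p3", "p4"),
    assays: tuple[str, ...] = ("metaG", "metaT"),
    crop: str = "switchgrass",
) -> list[tuple[_dt.date, str, str, str]]:
    """Seven sampling dates spanning May-September over replicated field plots.

    This emulates a single-crop season of leaf sampling: three early-season
    dates (May-June) and four late-season dates (July-September), each
    collected on every replicate plot for both assays.
    """
    dates = [
        _dt.date(year, 5, 15),
        _dt.date(year, 6, 5),
        _dt.date(year, 6, 26),
        _dt.date(year, 7, 17),
        _dt.date(year, 8, 7),
        _dt.date(year, 8, 28),
        _dt.date(year, 9, 18),
    ]
    return [(d, p, crop, a) for d in dates for p in plots for a in assays]


def balanced_design(
    n_early_dates: int = 2,
    n_late_dates: int = 2,
    plots: tuple[str, ...] = ("p1", "p2", "p3", "p4"),
    assays: tuple[str, ...] = ("metaT",),
    year: int = 2017,
    crop: str = "switchgrass",
) -> list[tuple[_dt.date, str, str, str]]:
    """A balanced early/late design, e.g. 2+2 dates x 4 plots = 8+8 samples."""
    early_pool = [_dt.date(year, 5, 15), _dt.date(year, 6, 5), _dt.date(year, 6, 26)]
    late_pool = [
        _dt.date(year, 7, 17),
        _dt.date(year, 8, 7),
        _dt.date(year, 8, 28),
        _dt.date(year, 9, 18),
    ]
    if n_early_dates > len(early_pool) or n_late_dates > len(late_pool):
        raise ConfigurationError("requested more dates than the seasonal pools hold")
    dates = early_pool[:n_early_dates] + late_pool[:n_late_dates]
    return [(d, p, crop, a) for d in dates for p in plots for a in assays]


@dataclass
class SimConfig:
    """Parameters of the synthetic community and sampling design.

    Ranges are inclusive ``(low, high)`` tuples.  ``depth_factor`` is the
    expected per-base read depth of a feature at relative abundance /
    expression 1.0; ``injected_role_foldchanges`` multiplies late-season
    expression of every non-housekeeping ORF of the given role.
    """

    n_mags: int = 12
    contigs_per_mag: tuple[int, int] = (2, 4)
    contig_length: tuple[int, int] = (3000, 6000)
    orfs_per_contig: tuple[int, int] = (4, 8)
    orf_length: tuple[int, int] = (400, 900)
    n_hkg_per_mag: int = 2
    n_roles: int = 24
    n_subsystems: int = 6
    sample_design: list[tuple[_dt.date, str, str, str]] = field(
        default_factory=default_sample_design
    )
    trajectory_archetypes: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "early_peak": {"decay": 0.6},
            "late_rise": {"growth": 1.7},
            "flat": {},
        }
    )
    injected_role_foldchanges: dict[str, float] = field(
        default_factory=lambda: {"role_000": 53.2, "role_001": 29.7, "role_002": 23.6}
    )
    base_abundance_sigma: float = 0.4
    read_length: int = 150
    depth_factor: float = 50.0
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_mags": self.n_mags,
            "n_hkg_per_mag": self.n_hkg_per_mag,
            "n_roles": self.n_roles,
            "n_subsystems": self.n_subsystems,
            "read_length": self.read_length,
        }
        for name, val in counts.items():
            if val < 1:
                raise ConfigurationError(f"{name} must be >= 1, got {val}")
        for name, rng in (
            ("contigs_per_mag", self.contigs_per_mag),
            ("contig_length", self.contig_length),
            ("orfs_per_contig", self.orfs_per_contig),
            ("orf_length", self.orf_length),
        ):
            lo, hi = rng
            if lo < 1 or hi < lo:
                raise ConfigurationError(f"{name} range {rng} invalid")
        if self.orf_length[0] > self.contig_length[1]:
            raise ConfigurationError(
                f"orf_length min {self.orf_length[0]} exceeds contig_length max "
                f"{self.contig_length[1]}: ORFs cannot fit in any contig"
            )
        if self.orfs_per_contig[0] * self.orf_length[0] > self.contig_length[1]:
            raise ConfigurationError(
                f"orfs_per_contig min {self.orfs_per_contig[0]} x orf_length min "
                f"{self.orf_length[0]} exceeds contig_length max "
                f"{self.contig_length[1]}: ORFs cannot fit without overlap"
            )
        if self.read_length > self.contig_length[0]:
            raise ConfigurationError(
                f"read_length {self.read_length} exceeds minimum contig length "
                f"{self.contig_length[0]}"
            )
        if self.n_hkg_per_mag > self.contigs_per_mag[0] * self.orfs_per_contig[0]:
            raise ConfigurationError(
                "n_hkg_per_mag exceeds the guaranteed minimum ORF count per MAG"
            )
        if self.depth_factor < 0:
            raise ConfigurationError("depth_factor must be >= 0")
        unknown = set(self.trajectory_archetypes) - {"early_peak", "late_rise", "flat"}
        if unknown:
            raise ConfigurationError(f"unknown trajectory archetypes: {sorted(unknown)}")
        if not self.trajectory_archetypes:
            raise ConfigurationError("at least one trajectory archetype required")
        role_names = {f"role_{i:03d}" for i in range(self.n_roles)}
        bad = set(self.injected_role_foldchanges) - role_names
        if bad:
            raise ConfigurationError(
                f"injected_role_foldchanges references unknown roles: {sorted(bad)}"
            )

    def samples(self) -> list[SampleRecord]:
        out = []
        for i, (day, plot, crop, assay) in enumerate(self.sample_design):
            out.append(
                SampleRecord(
                    sample_id=f"s{i:03d}_{assay}_{day.isoformat()}_{plot}",
                    crop=crop,
                    collection_date=day,
                    plot_id=plot,
                    assay=assay,
                )
            )
        return out


@dataclass
class GroundTruth:
    """What the generator actually planted, keyed for direct comparison.

    ``mag_trajectory`` maps (mag_id, ISO date) to true relative abundance,
    ``orf_expression`` maps (orf_id, ISO date) to true expected transcript
    depth in units of ``depth_factor``, ``role_foldchange`` records the
    injected late:early factors, and ``cluster_membership`` gives each MAG's
    archetype label.
    """

    mag_trajectory: dict[tuple[str, str], float]
    orf_expression: dict[tuple[str, str], float]
    role_foldchange: dict[str, float]
    cluster_membership: dict[str, str]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "mag_trajectory": {f"{m}|{d}": v for (m, d), v in self.mag_trajectory.items()},
            "orf_expression": {f"{o}|{d}": v for (o, d), v in self.orf_expression.items()},
            "role_foldchange": self.role_foldchange,
            "cluster_membership": self.cluster_membership,
        }
        with open(path, "w", newline="\n") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)

        def unkey(d: dict[str, float]) -> dict[tuple[str, str], float]:
            return {tuple(k.split("|", 1)): v for k, v in d.items()}

        return cls(
            mag_trajectory=unkey(payload["mag_trajectory"]),
            orf_expression=unkey(payload["orf_expression"]),
            role_foldchange=payload["role_foldchange"],
            cluster_membership=payload["cluster_membership"],
        )


def build_community(cfg: SimConfig) -> CommunityModel:
    """Deterministically lay out MAGs, contigs and non-overlapping ORFs.

    Each non-housekeeping ORF gets exactly one functional role (roles map to
    subsystems round-robin); the first ``n_hkg_per_mag`` ORFs of each MAG are
    flagged as single-copy housekeeping genes and carry the reserved
    housekeeping role so that injected fold changes never perturb the
    normalization denominator.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    model = CommunityModel()
    role_names = [f"role_{i:03d}" for i in range(cfg.n_roles)]
    role_subsystem = {
        r: f"subsystem_{i % cfg.n_subsystems:02d}" for i, r in enumerate(role_names)
    }

    for mi in range(cfg.n_mags):
        mag_id = f"mag_{mi:02d}"
        # completeness/contamination drawn inside the focal-quality region
        completeness = round(float(rng.uniform(60, 99)), 1)
        contamination = round(float(rng.uniform(0, 8)), 1)
        model.mags[mag_id] = MagRecord(mag_id, completeness, contamination)
        n_contigs = int(rng.integers(cfg.contigs_per_mag[0], cfg.contigs_per_mag[1] + 1))
        mag_orf_records: list[OrfRecord] = []
        for ci in range(n_contigs):
            contig_id = f"{mag_id}_c{ci:02d}"
            length = int(rng.integers(cfg.contig_length[0], cfg.contig_length[1] + 1))
            n_orfs = int(rng.integers(cfg.orfs_per_contig[0], cfg.orfs_per_contig[1] + 1))
            # cap the count and per-ORF length so the layout always fits
            n_orfs = min(n_orfs, length // cfg.orf_length[0])
            if n_orfs < cfg.orfs_per_contig[0]:
                raise ConfigurationError(
                    f"cannot fit {cfg.orfs_per_contig[0]} ORFs of length range "
                    f"{cfg.orf_length} into contig of length {length} "
                    f"(contig_length={cfg.contig_length}, orf_length={cfg.orf_length})"
                )
            hi = min(cfg.orf_length[1], length // n_orfs)
            lengths = rng.integers(cfg.orf_length[0], hi + 1, size=n_orfs)
            slack = int(length - lengths.sum())
            # distribute the slack as n_orfs+1 non-negative gaps
            cuts = np.sort(rng.integers(0, slack + 1, size=n_orfs))
            gaps = np.diff(np.concatenate([[0], cuts, [slack]]))
            model.contigs[contig_id] = (mag_id, length)
            pos = 0
            for oi in range(n_orfs):
                pos += int(gaps[oi])
                start, end = pos, pos + int(lengths[oi])
                pos = end
                orf_id = f"{contig_id}_o{oi:02d}"
                role = role_names[int(rng.integers(0, cfg.n_roles))]
                rec = OrfRecord(
                    orf_id=orf_id,
                    contig_id=contig_id,
                    start=start,
                    end=end,
                    strand="+" if rng.random() < 0.5 else "-",
                    role_id=role,
                    subsystem_id=role_subsystem[role],
                    is_hkg=False,
                )
                model.orfs[orf_id] = rec
                mag_orf_records.append(rec)
        # flag housekeeping genes, spread across the MAG's ORFs
        hkg_idx = np.linspace(0, len(mag_orf_records) - 1, cfg.n_hkg_per_mag).astype(int)
        for idx in sorted(set(int(i) for i in hkg_idx)):
            old = mag_orf_records[idx]
            model.orfs[old.orf_id] = OrfRecord(
                orf_id=old.orf_id,
                contig_id=old.contig_id,
                start=old.start,
                end=old.end,
                strand=old.strand,
                role_id=HKG_ROLE,
                subsystem_id=HKG_SUBSYSTEM,
                is_hkg=True,
            )
    model.validate()
    return model


def _archetype_shape(name: str, params: dict[str, float], n_dates: int) -> np.ndarray:
    idx = np.arange(n_dates, dtype=float)
    if name == "flat":
        return np.ones(n_dates)
    if name == "early_peak":
        decay = float(params.get("decay", 0.6))
        if not (0 < decay < 1):
            raise ConfigurationError("early_peak decay must lie in (0, 1)")
        return decay**idx
    if name == "late_rise":
        growth = float(params.get("growth", 1.7))
        if growth <= 1:
            raise ConfigurationError("late_rise growth must exceed 1")
        return growth**idx
    raise ConfigurationError(f"unknown archetype {name}")


def simulate_trajectories(model: CommunityModel, cfg: SimConfig) -> GroundTruth:
    """Assign archetypes and compute true abundance / expression trajectories.

    Requires a design spanning both seasons.  Each MAG draws a log-normal base
    abundance and an archetype; ORF expression follows the MAG trajectory
    (housekeeping ORFs with factor exactly 1.0, so the denominator tracks
    genome abundance) with injected role fold changes applied multiplicatively
    on late-season dates.
    """
    cfg.validate()
    dates = sorted({d for d, _, _, _ in cfg.sample_design})
    seasons = {season_of(d) for d in dates}
    if seasons != {"early", "late"}:
        raise ConfigurationError(
            "sample design must include both early (May-June) and late "
            f"(July-September) dates; got seasons {sorted(seasons)}"
        )
    rng = np.random.default_rng(cfg.seed + 1)
    archetypes = sorted(cfg.trajectory_archetypes)
    weights = np.array(
        [cfg.trajectory_archetypes[a].get("weight", 1.0) for a in archetypes], dtype=float
    )
    weights = weights / weights.sum()

    mag_ids = sorted(model.mags)
    # deterministic round-robin proportional assignment keeps groups balanced
    counts = np.floor(weights * len(mag_ids)).astype(int)
    while counts.sum() < len(mag_ids):
        counts[int(rng.integers(0, len(archetypes)))] += 1
    labels: list[str] = []
    for a, c in zip(archetypes, counts):
        labels.extend([a] * int(c))
    rng.shuffle(labels)

    mag_trajectory: dict[tuple[str, str], float] = {}
    membership: dict[str, str] = {}
    base: dict[str, float] = {}
    for mag_id, label in zip(mag_ids, labels):
        membership[mag_id] = label
        base[mag_id] = float(rng.lognormal(mean=0.0, sigma=cfg.base_abundance_sigma))
        shape = _archetype_shape(label, cfg.trajectory_archetypes[label], len(dates))
        for d, s in zip(dates, shape):
            mag_trajectory[(mag_id, d.isoformat())] = base[mag_id] * float(s)

    orf_expression: dict[tuple[str, str], float] = {}
    for orf in model.orfs.values():
        mag_id = model.mag_of_contig(orf.contig_id)
        fold = cfg.injected_role_foldchanges.get(orf.role_id)
        for d in dates:
            expr = mag_trajectory[(mag_id, d.isoformat())]
            if fold is not None and not orf.is_hkg and season_of(d) == "late":
                expr *= fold
            orf_expression[(orf.orf_id, d.isoformat())] = expr

    return GroundTruth(
        mag_trajectory=mag_trajectory,
        orf_expression=orf_expression,
        role_foldchange=dict(cfg.injected_role_foldchanges),
        cluster_membership=membership,
    )


def simulate_alignments(
    model: CommunityModel, truth: GroundTruth, cfg: SimConfig
) -> dict[str, AlignmentSet]:
    """Place Poisson read intervals for every sample in the design.

    Metagenome samples place reads uniformly along each contig with expected
    count ``abundance * depth_factor * contig_length / read_length``;
    metatranscriptome reads start only within ORF spans at a rate proportional
    to true expression.  Reads are truncated at contig ends.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + 2)
    rl = cfg.read_length
    out: dict[str, AlignmentSet] = {}
    contig_items = sorted(model.contigs.items())
    orf_items = sorted(model.orfs.items())
    for sample in cfg.samples():
        day = sample.collection_date.isoformat()
        by_contig: dict[str, list[np.ndarray]] = {}
        if sample.assay == "metaG":
            for contig_id, (mag_id, length) in contig_items:
                abundance = truth.mag_trajectory[(mag_id, day)]
                lam = abundance * cfg.depth_factor * length / rl
                n = int(rng.poisson(lam))
                if n == 0:
                    continue
                starts = rng.integers(0, length, size=n)
                ends = np.minimum(starts + rl, length)
                by_contig.setdefault(contig_id, []).append(
                    np.column_stack([starts, ends])
                )
        else:
            for orf_id, orf in orf_items:
                expr = truth.orf_expression[(orf_id, day)]
                lam = expr * cfg.depth_factor * orf.length / rl
                n = int(rng.poisson(lam))
                if n == 0:
                    continue
                length = model.contig_length(orf.contig_id)
                starts = rng.integers(orf.start, orf.end, size=n)
                ends = np.minimum(starts + rl, length)
                by_contig.setdefault(orf.contig_id, []).append(
                    np.column_stack([starts, ends])
                )
        arrays = {c: np.vstack(chunks) for c, chunks in by_contig.items()}
        out[sample.sample_id] = AlignmentSet.from_arrays(sample.sample_id, arrays)
    return out


_BASES = np.frombuffer(b"ACGT", dtype="S1")


def write_dataset(
    model: CommunityModel,
    truth: GroundTruth,
    alignments: dict[str, AlignmentSet],
    cfg: SimConfig,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write the dataset as plain-text files and return the path map.

    Emits contig FASTA (random uniform ACGT; content is irrelevant to the
    pipeline and exists to exercise I/O), ORF GFF3, per-sample BED files,
    sample/quality TSVs, a role->ORF pathway table (each role doubling as a
    toy pathway so activity calling is exercised), and the ground-truth JSON.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bed_dir = outdir / "alignments"
    bed_dir.mkdir(exist_ok=True)
    rng = np.random.default_rng(cfg.seed + 3)
    sequences = {
        contig_id: rng.choice(_BASES, size=length).tobytes().decode("ascii")
        for contig_id, (_, length) in sorted(model.contigs.items())
    }
    paths = {
        "fasta": outdir / "contigs.fasta",
        "gff3": outdir / "orfs.gff3",
        "samples": outdir / "samples.tsv",
        "quality": outdir / "mag_quality.tsv",
        "pathways": outdir / "pathways.tsv",
        "truth": outdir / "truth.json",
        "bed_dir": bed_dir,
    }
    io_formats.write_fasta(
        paths["fasta"], sequences, {c: m for c, (m, _) in model.contigs.items()}
    )
    io_formats.write_gff3(paths["gff3"], model)
    samples = cfg.samples()
    io_formats.write_tables(
        paths["samples"], paths["quality"], samples, list(model.mags.values())
    )
    with open(paths["pathways"], "w", newline="\n") as fh:
        fh.write("pathway_id\torf_id\n")
        for orf_id, orf in sorted(model.orfs.items()):
            fh.write(f"pw_{orf.role_id}\t{orf_id}\n")
    for sample in samples:
        io_formats.write_bed(
            bed_dir / f"{sample.sample_id}.bed", alignments[sample.sample_id]
        )
    truth.to_json(paths["truth"])
    return paths


def read_dataset(
    datadir: str | Path,
) -> tuple[CommunityModel, list[SampleRecord], dict[str, AlignmentSet], GroundTruth | None]:
    """Round-trip reader for a directory produced by :func:`write_dataset`."""
    datadir = Path(datadir)
    samples, mags = io_formats.read_tables(
        datadir / "samples.tsv", datadir / "mag_quality.tsv"
    )
    stub = io_formats.read_fasta_stub(datadir / "contigs.fasta")
    model = io_formats.read_gff3(
        datadir / "orfs.gff3", stub, mags={m.mag_id: m for m in mags}
    )
    alignments = {
        s.sample_id: io_formats.read_bed(
            datadir / "alignments" / f"{s.sample_id}.bed", s.sample_id
        )
        for s in samples
    }
    truth_path = datadir / "truth.json"
    truth = GroundTruth.from_json(truth_path) if truth_path.exists() else None
    return model, samples, alignments, truth
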