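"""Readers and writers for the formats the pipeline touches.

External conventions: GFF3 is 1-based inclusive, BED is 0-based half-open,
sample/quality tables are tab-separated with ISO-8601 dates.  All coordinate
conversion happens here; the rest of the library is strictly 0-based
half-open.  Writers emit UTF-8 with UNIX line endings.
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    AlignmentSet,
    CommunityModel,
    FormatError,
    MagRecord,
    OrfRecord,
    SampleRecord,
)

__all__ = [
    "read_fasta_stub",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_bed",
    "write_bed",
    "read_tables",
    "write_tables",
]


def read_fasta_stub(path: str | Path) -> dict[str, tuple[str | None, int]]:
    """Read contig FASTA, returning ``contig_id -> (mag_id or None, length)``.

    The MAG assignment is taken from a ``mag_id=...`` token in the record
    description when present (the synthetic writer emits one); sequences are
    not retained, only lengths.
    """
    stub: dict[str, tuple[str | None, int]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        mag_id = None
        for token in rec.description.split():
            if token.startswith("mag_id="):
                mag_id = token.split("=", 1)[1]
        if rec.id in stub:
            raise FormatError(f"{path}: duplicate contig {rec.id}")
        stub[rec.id] = (mag_id, len(rec.seq))
    return stub


def write_fasta(path: str | Path, sequences: dict[str, str], contig_mags: dict[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=contig_id, description=f"mag_id={contig_mags[contig_id]}")
        for contig_id, seq in sequences.items()
    ]
    with open(path, "w", newline="\n") as fh:
        SeqIO.write(records, fh, "fasta")


def read_gff3(
    path: str | Path,
    contig_stub: dict[str, tuple[str | None, int]],
    mags: dict[str, MagRecord] | None = None,
) -> CommunityModel:
    """Parse an ORF GFF3 into a :class:`CommunityModel`.

    ``contig_stub`` supplies contig lengths (and optionally MAG membership)
    from FASTA; GFF features carry ``ID``, ``mag_id``, ``role``, ``subsystem``
    and ``is_hkg`` attributes.  GFF's 1-based inclusive coordinates become
    0-based half-open internally.  Unknown attributes are preserved by
    gffutils but ignored here; strand is stored verbatim.
    """
    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            merge_strategy="error",
            keep_order=True,
        )
    except Exception as exc:  # gffutils raises ValueError subclasses on duplicates
        raise FormatError(f"{path}: {exc}") from exc

    model = CommunityModel()
    contig_mag: dict[str, str] = {}
    orfs: dict[str, OrfRecord] = {}
    for feat in db.all_features():
        ids = feat.attributes.get("ID")
        if not ids:
            raise FormatError(f"{path}: feature without ID on {feat.seqid}")
        orf_id = ids[0]
        if orf_id in orfs:
            raise FormatError(f"{path}: duplicate ORF ID {orf_id}")
        if feat.seqid not in contig_stub:
            raise FormatError(f"{path}: ORF {orf_id} on unknown contig {feat.seqid}")
        mag_id = feat.attributes.get("mag_id", [None])[0]
        stub_mag, length = contig_stub[feat.seqid]
        if mag_id is None:
            mag_id = stub_mag
        if mag_id is None:
            raise FormatError(f"{path}: ORF {orf_id} has no mag_id and FASTA gives none")
        start = feat.start - 1  # GFF3 1-based inclusive -> 0-based half-open
        end = feat.end
        if start < 0 or end > length:
            raise FormatError(
                f"{path}: ORF {orf_id} span [{feat.start}, {feat.end}] outside contig "
                f"{feat.seqid} (length {length})"
            )
        is_hkg = feat.attributes.get("is_hkg", ["false"])[0].lower() == "true"
        orfs[orf_id] = OrfRecord(
            orf_id=orf_id,
            contig_id=feat.seqid,
            start=start,
            end=end,
            strand=feat.strand if feat.strand in ("+", "-") else "+",
            role_id=feat.attributes.get("role", ["unassigned"])[0],
            subsystem_id=feat.attributes.get("subsystem", ["unassigned"])[0],
            is_hkg=is_hkg,
        )
        prev = contig_mag.get(feat.seqid)
        if prev is not None and prev != mag_id:
            raise FormatError(
                f"{path}: contig {feat.seqid} assigned to both {prev} and {mag_id}"
            )
        contig_mag[feat.seqid] = mag_id

    for contig_id, (stub_mag, length) in contig_stub.items():
        mag_id = contig_mag.get(contig_id, stub_mag)
        if mag_id is None:
            raise FormatError(f"contig {contig_id} has no MAG assignment")
        model.contigs[contig_id] = (mag_id, length)
    model.orfs = orfs
    mag_ids = {m for m, _ in model.contigs.values()}
    if mags is not None:
        model.mags = dict(mags)
        missing = mag_ids - set(model.mags)
        if missing:
            raise FormatError(f"MAG quality table missing entries: {sorted(missing)}")
    else:
        # placeholder quality when no table supplied
        model.mags = {m: MagRecord(m, 100.0, 0.0) for m in sorted(mag_ids)}
    model.validate()
    return model


def write_gff3(path: str | Path, model: CommunityModel) -> None:
    """Write ORFs as GFF3 (1-based inclusive coordinates)."""
    with open(path, "w", newline="\n") as fh:
        fh.write("##gff-version 3\n")
        for contig_id, (_, length) in model.contigs.items():
            fh.write(f"##sequence-region {contig_id} 1 {length}\n")
        for orf in model.orfs.values():
            mag_id = model.mag_of_contig(orf.contig_id)
            attrs = (
                f"ID={orf.orf_id};mag_id={mag_id};role={orf.role_id};"
                f"subsystem={orf.subsystem_id};is_hkg={'true' if orf.is_hkg else 'false'}"
            )
            fh.write(
                f"{orf.contig_id}\tmagseason\tCDS\t{orf.start + 1}\t{orf.end}\t.\t"
                f"{orf.strand}\t0\t{attrs}\n"
            )


def read_bed(path: str | Path, sample_id: str | None = None) -> AlignmentSet:
    """Read a BED3(+) file of mapped-read intervals into an :class:`AlignmentSet`.

    BED is already 0-based half-open so intervals are stored as given; extra
    columns are ignored.  An empty file is a valid, zero-coverage sample.
    """
    path = Path(path)
    if sample_id is None:
        sample_id = path.stem
    intervals: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 tab-separated fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 0 or start >= end:
                raise FormatError(
                    f"{path}:{lineno}: invalid interval [{start}, {end})"
                )
            intervals.append((fields[0], start, end))
    return AlignmentSet(sample_id, intervals)


def write_bed(path: str | Path, alns: AlignmentSet) -> None:
    with open(path, "w", newline="\n") as fh:
        for contig_id, start, end in alns.intervals:
            fh.write(f"{contig_id}\t{start}\t{end}\n")


_SAMPLE_COLUMNS = ["sample_id", "crop", "date", "plot", "assay"]
_QUALITY_COLUMNS = ["mag_id", "completeness_pct", "contamination_pct"]


def read_tables(
    samples_path: str | Path, quality_path: str | Path
) -> tuple[list[SampleRecord], list[MagRecord]]:
    """Read the sample-metadata and MAG-quality TSVs.

    Dates are ISO-8601; seasons derive from the month and any row dated
    outside May-September is rejected with an error rather than silently
    mislabelled.
    """
    samples_df = pd.read_csv(samples_path, sep="\t", dtype=str)
    for col in _SAMPLE_COLUMNS:
        if col not in samples_df.columns:
            raise FormatError(f"{samples_path}: missing required column '{col}'")
    samples = []
    for _, row in samples_df.iterrows():
        try:
            day = _dt.date.fromisoformat(row["date"])
        except ValueError as exc:
            raise FormatError(
                f"{samples_path}: sample {row['sample_id']}: bad date {row['date']!r}"
            ) from exc
        samples.append(
            SampleRecord(
                sample_id=row["sample_id"],
                crop=row["crop"],
                collection_date=day,
                plot_id=row["plot"],
                assay=row["assay"],
            )
        )

    quality_df = pd.read_csv(quality_path, sep="\t")
    for col in _QUALITY_COLUMNS:
        if col not in quality_df.columns:
            raise FormatError(f"{quality_path}: missing required column '{col}'")
    mags = [
        MagRecord(
            mag_id=str(row["mag_id"]),
            completeness_pct=float(row["completeness_pct"]),
            contamination_pct=float(row["contamination_pct"]),
            taxonomy_label=(
                str(row["taxonomy"]) if "taxonomy" in quality_df.columns else None
            ),
        )
        for _, row in quality_df.iterrows()
    ]
    return samples, mags


def write_tables(
    samples_path: str | Path,
    quality_path: str | Path,
    samples: list[SampleRecord],
    mags: list[MagRecord],
) -> None:
    sdf = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "crop": [s.crop for s in samples],
            "date": [s.collection_date.isoformat() for s in samples],
            "plot": [s.plot_id for s in samples],
            "assay": [s.assay for s in samples],
        }
    )
    sdf.to_csv(samples_path, sep="\t", index=False, lineterminator="\n")
    qdf = pd.DataFrame(
        {
            "mag_id": [m.mag_id for m in mags],
            "completeness_pct": [m.completeness_pct for m in mags],
            "contamination_pct": [m.contamination_pct for m in mags],
        }
    )
    qdf.to_csv(quality_path, sep="\t", index=False, lineterminator="\n")
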