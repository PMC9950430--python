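"""Per-base depth and median-basepair-coverage abundance estimation.

The abundance estimator is the median, over every base of a feature's span
(zeros included), of the number of mapped-read intervals covering that base:

* contig abundance = median basepair coverage of the contig;
* MAG abundance = unweighted arithmetic mean of its contigs' medians
  (a length-weighted mode is available for sensitivity analysis);
* ORF abundance = median basepair coverage of the ORF span (the
  metatranscriptome unit).

Depths are exact integers and medians are exact halves (x.0 or x.5), so there
is no floating-point accumulation in the hot path.  Raw read-recruitment
counts per MAG are also provided; their per-MAG mean across samples is the
detection statistic used to drop MAGs with insufficient transcript
recruitment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import AlignmentSet, CommunityModel, FormatError

__all__ = [
    "DepthProfile",
    "CoverageTable",
    "pileup",
    "median_depth",
    "contig_medians",
    "orf_medians",
    "coverage_tables",
    "mag_coverage",
    "recruitment_counts",
]

#: A per-base depth vector for one contig (non-negative integers).
DepthProfile = np.ndarray


@dataclass
class CoverageTable:
    """Sparse (entity, sample) -> median-depth table; absent entries are 0."""

    kind: str  # 'contig' | 'orf' | 'mag'
    values: dict[tuple[str, str], float] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def get(self, entity_id: str, sample_id: str) -> float:
        return self.values.get((entity_id, sample_id), 0.0)

    def entities(self) -> list[str]:
        return sorted({e for e, _ in self.values})

    def samples(self) -> list[str]:
        return sorted({s for _, s in self.values})

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"entity_id": e, "sample_id": s, "median_depth": v}
            for (e, s), v in sorted(self.values.items())
        ]
        return pd.DataFrame(rows, columns=["entity_id", "sample_id", "median_depth"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, lineterminator="\n")

    @classmethod
    def from_tsv(cls, path: str | Path, kind: str) -> "CoverageTable":
        df = pd.read_csv(path, sep="\t", dtype={"entity_id": str, "sample_id": str})
        values = {
            (row.entity_id, row.sample_id): float(row.median_depth)
            for row in df.itertuples()
        }
        return cls(kind=kind, values=values)


def pileup(alns: AlignmentSet, model: CommunityModel) -> dict[str, DepthProfile]:
    """Per-base depth for every contig of the model (zeros where unmapped).

    depth[b] = number of intervals containing base b.  Duplicate intervals
    each count (multiset semantics).  Implemented as a difference array +
    cumulative sum, O(n_intervals + contig_length) per contig.
    """
    arrays = alns.arrays()
    for contig_id in arrays:
        if contig_id not in model.contigs:
            raise FormatError(
                f"sample {alns.sample_id}: alignment references unknown contig {contig_id}"
            )
    profiles: dict[str, DepthProfile] = {}
    for contig_id, (_, length) in model.contigs.items():
        arr = arrays.get(contig_id)
        if arr is None or arr.size == 0:
            profiles[contig_id] = np.zeros(length, dtype=np.int64)
            continue
        if np.any(arr[:, 1] > length):
            raise FormatError(
                f"sample {alns.sample_id}: interval beyond end of {contig_id}"
            )
        diff = np.zeros(length + 1, dtype=np.int64)
        np.add.at(diff, arr[:, 0], 1)
        np.add.at(diff, arr[:, 1], -1)
        profiles[contig_id] = np.cumsum(diff[:-1])
    return profiles


def median_depth(
    profile: DepthProfile, span: tuple[int, int] | None = None
) -> float:
    """Median depth over all bases of the span (zeros included).

    Even-length spans take the mean of the two central values, so results are
    exact halves.  An empty span is an error.
    """
    if span is None:
        window = profile
    else:
        start, end = span
        if not (0 <= start < end <= len(profile)):
            raise ValueError(f"span [{start}, {end}) outside profile of length {len(profile)}")
        window = profile[start:end]
    if window.size == 0:
        raise ValueError("median over an empty span is undefined")
    return float(np.median(window))


def contig_medians(
    alns: AlignmentSet, model: CommunityModel
) -> dict[str, float]:
    """Median basepair coverage of every contig for one sample."""
    return {
        contig_id: median_depth(profile)
        for contig_id, profile in pileup(alns, model).items()
    }


def orf_medians(alns: AlignmentSet, model: CommunityModel) -> dict[str, float]:
    """Median basepair coverage of every ORF span for one sample."""
    profiles = pileup(alns, model)
    return {
        orf.orf_id: median_depth(profiles[orf.contig_id], (orf.start, orf.end))
        for orf in model.orfs.values()
    }


def coverage_tables(
    alns_by_sample: dict[str, AlignmentSet], model: CommunityModel
) -> tuple[CoverageTable, CoverageTable]:
    """Contig and ORF median-coverage tables over a set of samples.

    Zero medians are stored sparsely (absent = 0).  One pileup per
    (sample, contig) serves both tables.
    """
    contig_tab = CoverageTable(kind="contig")
    orf_tab = CoverageTable(kind="orf")
    orfs_by_contig: dict[str, list] = {}
    for orf in model.orfs.values():
        orfs_by_contig.setdefault(orf.contig_id, []).append(orf)
    for sample_id, alns in alns_by_sample.items():
        profiles = pileup(alns, model)
        for contig_id, profile in profiles.items():
            med = median_depth(profile)
            if med > 0:
                contig_tab.values[(contig_id, sample_id)] = med
            for orf in orfs_by_contig.get(contig_id, ()):
                med_o = median_depth(profile, (orf.start, orf.end))
                if med_o > 0:
                    orf_tab.values[(orf.orf_id, sample_id)] = med_o
    return contig_tab, orf_tab


def mag_coverage(
    contig_table: CoverageTable,
    model: CommunityModel,
    sample_ids: list[str] | None = None,
    length_weighted: bool = False,
) -> CoverageTable:
    """Aggregate contig medians to MAG abundances.

    Default is the unweighted arithmetic mean of the MAG's contig medians
    (contigs absent from the table contribute 0); ``length_weighted=True``
    weights each contig by its length instead, recorded in the table metadata.
    """
    if sample_ids is None:
        sample_ids = contig_table.samples()
    out = CoverageTable(
        kind="mag",
        meta={"aggregation": "length_weighted_mean" if length_weighted else "mean"},
    )
    contigs_by_mag: dict[str, list[tuple[str, int]]] = {}
    for contig_id, (mag_id, length) in model.contigs.items():
        contigs_by_mag.setdefault(mag_id, []).append((contig_id, length))
    for mag_id in model.mags:
        contigs = contigs_by_mag.get(mag_id, [])
        if not contigs:
            raise ValueError(f"MAG {mag_id} has zero contigs; abundance undefined")
        for sample_id in sample_ids:
            meds = np.array([contig_table.get(c, sample_id) for c, _ in contigs])
            if length_weighted:
                weights = np.array([l for _, l in contigs], dtype=float)
                value = float(np.average(meds, weights=weights))
            else:
                value = float(meds.mean())
            if value > 0:
                out.values[(mag_id, sample_id)] = value
    return out


def recruitment_counts(
    alns_by_sample: dict[str, AlignmentSet],
    model: CommunityModel,
    sample_ids: list[str] | None = None,
) -> tuple[dict[tuple[str, str], int], dict[str, float]]:
    """Reads recruited per (MAG, sample) and the per-MAG mean across samples.

    The count is simply the number of intervals landing on the MAG's contigs.
    The mean over samples (of one assay, as selected by ``sample_ids``) is the
    statistic used to exclude MAGs with insufficient recruitment.
    """
    if sample_ids is None:
        sample_ids = sorted(alns_by_sample)
    counts: dict[tuple[str, str], int] = {}
    for sample_id in sample_ids:
        alns = alns_by_sample[sample_id]
        per_mag: dict[str, int] = {m: 0 for m in model.mags}
        for contig_id, arr in alns.arrays().items():
            if contig_id not in model.contigs:
                raise FormatError(
                    f"sample {sample_id}: alignment references unknown contig {contig_id}"
                )
            per_mag[model.mag_of_contig(contig_id)] += int(arr.shape[0])
        for mag_id, n in per_mag.items():
            counts[(mag_id, sample_id)] = n
    means = {
        mag_id: float(np.mean([counts[(mag_id, s)] for s in sample_ids]))
        if sample_ids
        else 0.0
        for mag_id in model.mags
    }
    return counts, means
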