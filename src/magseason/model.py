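"""Core in-memory model: MAGs, contigs, ORFs, samples, and alignment intervals.

All coordinates inside the library are 0-based half-open; conversion to the
1-based inclusive convention of GFF3 happens only at file boundaries
(:mod:`magseason.io_formats`).  Identifiers are opaque, case-sensitive strings.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

__all__ = [
    "ConfigurationError",
    "FormatError",
    "EARLY_MONTHS",
    "LATE_MONTHS",
    "season_of",
    "MagRecord",
    "OrfRecord",
    "SampleRecord",
    "CommunityModel",
    "AlignmentSet",
]


class ConfigurationError(ValueError):
    """Raised for infeasible or inconsistent configuration values."""


class FormatError(ValueError):
    """Raised for malformed input files (carries location context in the message)."""


#: Calendar months defining the early growing season (May, June).
EARLY_MONTHS = frozenset({5, 6})
#: Calendar months defining the late growing season (July-September).
LATE_MONTHS = frozenset({7, 8, 9})


def season_of(day: _dt.date) -> str:
    """Return ``'early'`` or ``'late'`` for a sampling date.

    The seasonal split is by calendar month: May-June is early, July-September
    is late.  Dates outside the May-September sampling window are rejected
    loudly rather than silently assigned a third season, because all seasonal
    statistics in this package are defined only on the early/late contrast.
    """
    if day.month in EARLY_MONTHS:
        return "early"
    if day.month in LATE_MONTHS:
        return "late"
    raise ConfigurationError(
        f"date {day.isoformat()} falls outside the May-September sampling window; "
        "no season is defined for it"
    )


@dataclass(frozen=True)
class MagRecord:
    """Quality metadata for one metagenome-assembled genome (MAG)."""

    mag_id: str
    completeness_pct: float
    contamination_pct: float
    taxonomy_label: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.completeness_pct <= 100.0):
            raise ConfigurationError(
                f"MAG {self.mag_id}: completeness {self.completeness_pct} outside [0, 100]"
            )
        if self.contamination_pct < 0.0:
            raise ConfigurationError(
                f"MAG {self.mag_id}: contamination {self.contamination_pct} negative"
            )


@dataclass(frozen=True)
class OrfRecord:
    """One open reading frame on a contig.

    ``start``/``end`` are 0-based half-open.  ``is_hkg`` flags single-copy
    housekeeping genes, whose summed median coverage per sample is the
    normalization denominator downstream.
    """

    orf_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    role_id: str
    subsystem_id: str
    is_hkg: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ConfigurationError(
                f"ORF {self.orf_id}: invalid span [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ConfigurationError(f"ORF {self.orf_id}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SampleRecord:
    """One sequencing observation: a (crop, date, plot, assay) combination."""

    sample_id: str
    crop: str
    collection_date: _dt.date
    plot_id: str
    assay: str

    def __post_init__(self) -> None:
        if self.assay not in ("metaG", "metaT"):
            raise ConfigurationError(
                f"sample {self.sample_id}: assay must be 'metaG' or 'metaT', got {self.assay!r}"
            )
        season_of(self.collection_date)  # validates the month eagerly

    @property
    def season(self) -> str:
        return season_of(self.collection_date)

    @property
    def day_of_year(self) -> int:
        return self.collection_date.timetuple().tm_yday


@dataclass
class CommunityModel:
    """The coordinate frame everything maps to: MAGs > contigs > ORFs.

    ``contigs`` maps contig_id -> (mag_id, length_bp).  Every contig belongs to
    exactly one MAG and every ORF lies within its contig.
    """

    mags: dict[str, MagRecord] = field(default_factory=dict)
    contigs: dict[str, tuple[str, int]] = field(default_factory=dict)
    orfs: dict[str, OrfRecord] = field(default_factory=dict)

    def validate(self) -> None:
        for contig_id, (mag_id, length) in self.contigs.items():
            if mag_id not in self.mags:
                raise ConfigurationError(
                    f"contig {contig_id} references unknown MAG {mag_id}"
                )
            if length <= 0:
                raise ConfigurationError(f"contig {contig_id} has non-positive length")
        for orf in self.orfs.values():
            if orf.contig_id not in self.contigs:
                raise ConfigurationError(
                    f"ORF {orf.orf_id} references unknown contig {orf.contig_id}"
                )
            length = self.contigs[orf.contig_id][1]
            if orf.end > length:
                raise ConfigurationError(
                    f"ORF {orf.orf_id} ends at {orf.end} beyond contig "
                    f"{orf.contig_id} length {length}"
                )

    # -- convenience views -------------------------------------------------

    def contig_length(self, contig_id: str) -> int:
        return self.contigs[contig_id][1]

    def mag_of_contig(self, contig_id: str) -> str:
        return self.contigs[contig_id][0]

    def contigs_of(self, mag_id: str) -> list[str]:
        return [c for c, (m, _) in self.contigs.items() if m == mag_id]

    def orfs_of_mag(self, mag_id: str) -> list[OrfRecord]:
        return [
            o for o in self.orfs.values() if self.contigs[o.contig_id][0] == mag_id
        ]

    def mag_of_orf(self, orf_id: str) -> str:
        return self.contigs[self.orfs[orf_id].contig_id][0]

    def hkg_orfs(self, mag_id: str | None = None) -> list[OrfRecord]:
        out = [o for o in self.orfs.values() if o.is_hkg]
        if mag_id is not None:
            out = [o for o in out if self.mag_of_contig(o.contig_id) == mag_id]
        return out

    def roles(self) -> set[str]:
        return {o.role_id for o in self.orfs.values()}

    def subsystems(self) -> set[str]:
        return {o.subsystem_id for o in self.orfs.values()}


class AlignmentSet:
    """Per-sample collection of mapped-read intervals on contigs.

    Intervals are 0-based half-open and strandless: the quantification below
    uses only the spans.  Internally intervals are grouped by contig into
    ``(n, 2)`` integer arrays, which keeps pileup vectorized; the ``intervals``
    property exposes the flat tuple view.
    """

    def __init__(
        self,
        sample_id: str,
        intervals: Iterable[tuple[str, int, int]] = (),
    ) -> None:
        self.sample_id = sample_id
        self._by_contig: dict[str, np.ndarray] = {}
        buf: dict[str, list[tuple[int, int]]] = {}
        for contig_id, start, end in intervals:
            buf.setdefault(contig_id, []).append((int(start), int(end)))
        for contig_id, pairs in buf.items():
            self._by_contig[contig_id] = np.asarray(pairs, dtype=np.int64)
        self._check()

    @classmethod
    def from_arrays(
        cls, sample_id: str, by_contig: dict[str, np.ndarray]
    ) -> "AlignmentSet":
        obj = cls.__new__(cls)
        obj.sample_id = sample_id
        obj._by_contig = {
            c: np.asarray(a, dtype=np.int64).reshape(-1, 2) for c, a in by_contig.items()
        }
        obj._check()
        return obj

    def _check(self) -> None:
        for contig_id, arr in self._by_contig.items():
            if arr.size and np.any(arr[:, 0] >= arr[:, 1]):
                raise FormatError(
                    f"sample {self.sample_id}: empty or inverted interval on {contig_id}"
                )
            if arr.size and np.any(arr[:, 0] < 0):
                raise FormatError(
                    f"sample {self.sample_id}: negative coordinate on {contig_id}"
                )

    def arrays(self) -> dict[str, np.ndarray]:
        return self._by_contig

    @property
    def intervals(self) -> list[tuple[str, int, int]]:
        out: list[tuple[str, int, int]] = []
        for contig_id, arr in self._by_contig.items():
            out.extend((contig_id, int(s), int(e)) for s, e in arr)
        return out

    @property
    def n_intervals(self) -> int:
        return sum(arr.shape[0] for arr in self._by_contig.values())

    def validate_against(self, model: CommunityModel) -> None:
        for contig_id, arr in self._by_contig.items():
            if contig_id not in model.contigs:
                raise FormatError(
                    f"sample {self.sample_id}: unknown contig {contig_id}"
                )
            length = model.contig_length(contig_id)
            if arr.size and np.any(arr[:, 1] > length):
                raise FormatError(
                    f"sample {self.sample_id}: interval beyond end of {contig_id} "
                    f"(length {length})"
                )

    def __iter__(self) -> Iterator[tuple[str, int, int]]:
        return iter(self.intervals)

    def __len__(self) -> int:
        return self.n_intervals

    def concat(self, other: "AlignmentSet") -> "AlignmentSet":
        merged: dict[str, np.ndarray] = {c: a.copy() for c, a in self._by_contig.items()}
        for c, a in other._by_contig.items():
            merged[c] = np.vstack([merged[c], a]) if c in merged else a.copy()
        return AlignmentSet.from_arrays(self.sample_id, merged)
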