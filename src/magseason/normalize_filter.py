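"""Housekeeping-gene normalization, sample exclusion, detection and filters.

Sequencing depth varies wildly between samples, so raw median coverages are
divided by a per-sample denominator: the summed median basepair coverage of
the single-copy housekeeping genes (HKGs) identified (median > 0) in that
sample.  Samples in which no housekeeping gene is detected are excluded from
further analysis rather than normalized by zero.  The resulting normalized
abundances are invariant to rescaling all depths in a sample.

Also implemented here: the MAG quality gate (completeness > 50%,
contamination < 10%, with a high/medium tier split at 90%/5%), the
metatranscriptome recruitment gate (mean mapped reads per MAG), MAG
detection/occupancy summaries, and the ORF retention filter (top 75% of mean
observed abundances and detected in at least 10% of samples).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .coverage import CoverageTable
from .model import CommunityModel, MagRecord

__all__ = [
    "AbundanceMatrix",
    "hkg_denominators",
    "normalize",
    "mag_quality_gate",
    "recruitment_gate",
    "detect_and_occupancy",
    "orf_filter",
]

REASON_NO_HKG = "no_hkg_detected"
REASON_LOW_RECRUITMENT = "insufficient_metaT_recruitment"


@dataclass
class AbundanceMatrix:
    """HKG-normalized (entity, sample) abundances; the pipeline's currency.

    ``values`` holds raw median coverage / hkg_denominator for retained
    samples only (absent entries mean 0); ``sample_ids`` lists retained
    samples so that zeros participate in means and occupancy;
    ``dropped_samples`` records exclusions with reason codes.
    """

    kind: str  # 'mag' | 'orf'
    assay: str  # 'metaG' | 'metaT'
    values: dict[tuple[str, str], float] = field(default_factory=dict)
    hkg_denominator: dict[str, float] = field(default_factory=dict)
    dropped_samples: dict[str, str] = field(default_factory=dict)
    sample_ids: list[str] = field(default_factory=list)

    def get(self, entity_id: str, sample_id: str) -> float:
        if sample_id in self.dropped_samples:
            raise KeyError(
                f"sample {sample_id} was dropped "
                f"({self.dropped_samples[sample_id]}); no abundance is defined"
            )
        return self.values.get((entity_id, sample_id), 0.0)

    def entities(self) -> list[str]:
        return sorted({e for e, _ in self.values})

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"entity_id": e, "sample_id": s, "abundance": v}
            for (e, s), v in sorted(self.values.items())
        ]
        return pd.DataFrame(rows, columns=["entity_id", "sample_id", "abundance"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, lineterminator="\n")


def hkg_denominators(
    orf_table: CoverageTable,
    model: CommunityModel,
    sample_ids: list[str],
) -> tuple[dict[str, float], dict[str, str]]:
    """Per-sample normalization denominators and exclusions.

    The denominator is the sum of median coverages over housekeeping-flagged
    ORFs with median > 0 in that sample ("identified" HKGs).  A sample with no
    identified housekeeping gene is excluded with reason ``no_hkg_detected``
    — a recorded outcome, not an error.
    """
    hkg_ids = [o.orf_id for o in model.orfs.values() if o.is_hkg]
    denominators: dict[str, float] = {}
    dropped: dict[str, str] = {}
    for sample_id in sample_ids:
        total = sum(
            v for o in hkg_ids if (v := orf_table.get(o, sample_id)) > 0
        )
        if total > 0:
            denominators[sample_id] = float(total)
        else:
            dropped[sample_id] = REASON_NO_HKG
    return denominators, dropped


def normalize(
    raw: CoverageTable,
    denominators: dict[str, float],
    dropped: dict[str, str],
    assay: str,
) -> AbundanceMatrix:
    """Divide raw median coverages by the per-sample HKG denominator.

    Multiplying every depth in a sample by k > 0 scales numerator and
    denominator alike, leaving normalized values unchanged.
    """
    out = AbundanceMatrix(
        kind=raw.kind,
        assay=assay,
        hkg_denominator=dict(denominators),
        dropped_samples=dict(dropped),
        sample_ids=sorted(denominators),
    )
    for (entity_id, sample_id), value in raw.values.items():
        if sample_id in dropped:
            continue
        if sample_id not in denominators:
            continue
        if value > 0:
            out.values[(entity_id, sample_id)] = value / denominators[sample_id]
    return out


def mag_quality_gate(
    mags: list[MagRecord],
    min_completeness: float = 50.0,
    max_contamination: float = 10.0,
) -> pd.DataFrame:
    """Partition MAGs by the quality gate (strict inequalities).

    Pass requires completeness strictly greater than ``min_completeness`` AND
    contamination strictly less than ``max_contamination``.  Passing MAGs are
    tiered MIMAG-style: high if completeness > 90 and contamination < 5,
    otherwise medium.
    """
    rows = []
    for mag in mags:
        passed = (
            mag.completeness_pct > min_completeness
            and mag.contamination_pct < max_contamination
        )
        if passed:
            tier = (
                "high"
                if mag.completeness_pct > 90 and mag.contamination_pct < 5
                else "medium"
            )
        else:
            tier = "fail"
        rows.append(
            {
                "mag_id": mag.mag_id,
                "completeness_pct": mag.completeness_pct,
                "contamination_pct": mag.contamination_pct,
                "tier": tier,
                "passed": passed,
            }
        )
    return pd.DataFrame(
        rows, columns=["mag_id", "completeness_pct", "contamination_pct", "tier", "passed"]
    )


def recruitment_gate(
    mean_reads: dict[str, float], min_mean_reads: float = 100.0
) -> pd.DataFrame:
    """Exclude MAGs whose mean read recruitment falls below the threshold.

    Retention uses >= so a MAG exactly at the threshold passes.  The default
    of 100 mean metatranscriptome reads excludes marginally recruited genomes
    (a genome averaging a few dozen mapped transcript reads carries no usable
    activity signal) and is configurable.
    """
    rows = [
        {
            "mag_id": mag_id,
            "mean_reads": mean,
            "passed": mean >= min_mean_reads,
            "reason": "" if mean >= min_mean_reads else REASON_LOW_RECRUITMENT,
        }
        for mag_id, mean in sorted(mean_reads.items())
    ]
    return pd.DataFrame(rows, columns=["mag_id", "mean_reads", "passed", "reason"])


def detect_and_occupancy(
    abund: AbundanceMatrix, entity_ids: list[str] | None = None
) -> pd.DataFrame:
    """Occupancy (fraction of retained samples with detection) and mean abundance.

    Detection is strictly positive normalized abundance; the mean is over ALL
    retained samples, zeros included.
    """
    samples = abund.sample_ids
    if not samples:
        raise ValueError("no retained samples; occupancy is undefined")
    if entity_ids is None:
        entity_ids = abund.entities()
    n = len(samples)
    rows = []
    for entity_id in entity_ids:
        vals = np.array([abund.values.get((entity_id, s), 0.0) for s in samples])
        rows.append(
            {
                "entity_id": entity_id,
                "occupancy": float((vals > 0).sum()) / n,
                "mean_abundance": float(vals.mean()),
                "n_samples": n,
            }
        )
    return pd.DataFrame(rows, columns=["entity_id", "occupancy", "mean_abundance", "n_samples"])


def orf_filter(
    abund: AbundanceMatrix,
    abundance_quantile: float = 0.25,
    min_detection_frac: float = 0.10,
    orf_ids: list[str] | None = None,
    mode: str = "orf_mean",
) -> pd.DataFrame:
    """Retain ORFs in the top 75% of observed abundances, detected in >= 10% of samples.

    Default (``mode='orf_mean'``): rank ORFs by their mean normalized
    abundance across retained samples (zeros included) and drop those below
    the 25th percentile of the means of ORFs with any detection (percentile
    by linear interpolation).  ``mode='pooled'`` instead thresholds each
    ORF's mean against the 25th percentile of all positive (ORF, sample)
    values pooled.  In both modes an ORF must additionally be detected in at
    least ``min_detection_frac`` of retained samples (compared with >=), and
    ORFs never detected always fail.
    """
    if mode not in ("orf_mean", "pooled"):
        raise ValueError(f"unknown mode {mode!r}")
    samples = abund.sample_ids
    if not samples:
        raise ValueError("no retained samples; the ORF filter is undefined")
    if orf_ids is None:
        orf_ids = abund.entities()
    n = len(samples)
    means = {}
    det_frac = {}
    for orf_id in orf_ids:
        vals = np.array([abund.values.get((orf_id, s), 0.0) for s in samples])
        means[orf_id] = float(vals.mean())
        det_frac[orf_id] = float((vals > 0).sum()) / n
    detected = [o for o in orf_ids if det_frac[o] > 0]
    if detected:
        if mode == "orf_mean":
            pool = np.array([means[o] for o in detected])
        else:
            pool = np.array(
                [v for (o, s), v in abund.values.items() if o in set(orf_ids) and v > 0]
            )
        threshold = float(np.quantile(pool, abundance_quantile))
    else:
        threshold = float("inf")
    rows = [
        {
            "orf_id": o,
            "mean_abundance": means[o],
            "detection_frac": det_frac[o],
            "retained": (
                det_frac[o] > 0
                and means[o] >= threshold
                and det_frac[o] >= min_detection_frac
            ),
        }
        for o in orf_ids
    ]
    df = pd.DataFrame(rows, columns=["orf_id", "mean_abundance", "detection_frac", "retained"])
    df.attrs["threshold"] = threshold
    df.attrs["mode"] = mode
    return df
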