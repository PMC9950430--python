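"""Seasonal activity statistics on normalized transcript abundances.

The seasonal contrast compares per-sample cumulative (summed) retained-ORF
transcript abundances between the early (May-June) and late (July-September)
season, per MAG, with a two-group Kruskal-Wallis test evaluated against the
chi-squared distribution with 1 degree of freedom.  Functional roles are
compared via the late:early ratio of season means of per-sample cumulative
role abundances; KEGG-style subsystems get per-date mean +/- SEM time series
and an ordinary-least-squares trend against day of year.  Pathway activity is
a presence/activity call: a pathway is *detected* when the MAG carries member
ORFs and *active* when any member recruits transcripts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .coverage import CoverageTable
from .model import CommunityModel, SampleRecord
from .normalize_filter import AbundanceMatrix

__all__ = [
    "mag_cumulative_transcripts",
    "kruskal_wallis_two_group",
    "test_all_mags",
    "role_enrichment",
    "subsystem_timeseries",
    "pathway_activity",
    "role_prevalence",
]


def mag_cumulative_transcripts(
    abund: AbundanceMatrix,
    model: CommunityModel,
    retained_orfs: set[str],
    mag_ids: list[str] | None = None,
) -> dict[tuple[str, str], float]:
    """Per-(MAG, sample) cumulative abundance: sum over retained ORFs of the MAG."""
    if mag_ids is None:
        mag_ids = sorted(model.mags)
    orfs_by_mag: dict[str, list[str]] = {m: [] for m in mag_ids}
    for orf_id in retained_orfs:
        mag_id = model.mag_of_orf(orf_id)
        if mag_id in orfs_by_mag:
            orfs_by_mag[mag_id].append(orf_id)
    out: dict[tuple[str, str], float] = {}
    for mag_id in mag_ids:
        if not orfs_by_mag[mag_id]:
            warnings.warn(
                f"MAG {mag_id} has no retained ORFs; cumulative abundance is 0",
                stacklevel=2,
            )
        for sample_id in abund.sample_ids:
            out[(mag_id, sample_id)] = sum(
                abund.values.get((o, sample_id), 0.0) for o in orfs_by_mag[mag_id]
            )
    return out


def kruskal_wallis_two_group(
    early: np.ndarray, late: np.ndarray
) -> tuple[float, float]:
    """Tie-corrected two-group Kruskal-Wallis H and its chi-squared (df=1) p.

    Mid-ranks are used for ties; H = [12/(N(N+1))] * sum n_i (Rbar_i - (N+1)/2)^2,
    divided by the tie-correction factor 1 - sum(t^3 - t)/(N^3 - N).  When all
    observations are identical the statistic is defined as 0 with p = 1.
    """
    early = np.asarray(early, dtype=float)
    late = np.asarray(late, dtype=float)
    if early.size == 0 or late.size == 0:
        raise ValueError("both groups must be non-empty")
    if early.size + late.size < 3:
        raise ValueError("need at least 3 observations in total")
    pooled = np.concatenate([early, late])
    n = pooled.size
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    ranks = stats.rankdata(pooled)
    r_early = ranks[: early.size]
    r_late = ranks[early.size :]
    grand = (n + 1) / 2.0
    h = (12.0 / (n * (n + 1))) * (
        early.size * (r_early.mean() - grand) ** 2
        + late.size * (r_late.mean() - grand) ** 2
    )
    _, counts = np.unique(pooled, return_counts=True)
    tie_correction = 1.0 - float(np.sum(counts**3 - counts)) / (n**3 - n)
    h /= tie_correction
    p = float(stats.chi2.sf(h, df=1))
    return float(h), p


def test_all_mags(
    cumulative: dict[tuple[str, str], float],
    samples: list[SampleRecord],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Early-vs-late Kruskal-Wallis test of cumulative transcripts per MAG.

    Direction is called from the comparison of group medians at raw p < alpha;
    Benjamini-Hochberg adjusted p-values are reported alongside as a
    supplementary column and do not drive the call.
    """
    early_ids = [s.sample_id for s in samples if s.season == "early"]
    late_ids = [s.sample_id for s in samples if s.season == "late"]
    if not early_ids or not late_ids:
        raise ValueError(
            "both seasons must be represented among the samples under test"
        )
    mag_ids = sorted({m for m, _ in cumulative})
    rows = []
    for mag_id in mag_ids:
        early = np.array([cumulative[(mag_id, s)] for s in early_ids])
        late = np.array([cumulative[(mag_id, s)] for s in late_ids])
        h, p = kruskal_wallis_two_group(early, late)
        if p < alpha:
            med_e, med_l = np.median(early), np.median(late)
            if med_l > med_e:
                direction = "increase"
            elif med_l < med_e:
                direction = "decrease"
            else:
                direction = "none"
        else:
            direction = "none"
        rows.append(
            {
                "mag_id": mag_id,
                "H": h,
                "p_value": p,
                "direction": direction,
                "n_early": early.size,
                "n_late": late.size,
            }
        )
    df = pd.DataFrame(rows, columns=["mag_id", "H", "p_value", "direction", "n_early", "n_late"])
    if len(df):
        df["p_adj"] = multipletests(df["p_value"].to_numpy(), method="fdr_bh")[1]
    else:
        df["p_adj"] = []
    return df[["mag_id", "H", "p_value", "p_adj", "direction", "n_early", "n_late"]]


def role_enrichment(
    abund: AbundanceMatrix,
    model: CommunityModel,
    samples: list[SampleRecord],
    retained_orfs: set[str],
    pseudo_policy: str = "flag",
) -> pd.DataFrame:
    """Late:early enrichment ratio per functional role.

    Per role, the per-sample cumulative abundance is the sum over retained
    ORFs annotated to the role (across MAGs); ``early_mean``/``late_mean``
    average these per-sample sums within each season and the ratio is their
    quotient.  When the early mean is zero the ratio is flagged infinite
    (``pseudo_policy='flag'``) or, with ``pseudo_policy='epsilon'``, computed
    after adding half the smallest nonzero per-sample role abundance to both
    means.  ``n_mags_detected`` counts MAGs carrying >= 1 retained ORF of the
    role.  Rows are ranked by ratio, infinities first.
    """
    if pseudo_policy not in ("flag", "epsilon"):
        raise ValueError(f"unknown pseudo_policy {pseudo_policy!r}")
    retained = [s for s in samples if s.sample_id in set(abund.sample_ids)]
    early_ids = [s.sample_id for s in retained if s.season == "early"]
    late_ids = [s.sample_id for s in retained if s.season == "late"]
    orfs_by_role: dict[str, list[str]] = {}
    mags_by_role: dict[str, set[str]] = {}
    for orf_id in retained_orfs:
        orf = model.orfs[orf_id]
        orfs_by_role.setdefault(orf.role_id, []).append(orf_id)
        mags_by_role.setdefault(orf.role_id, set()).add(model.mag_of_orf(orf_id))
    rows = []
    for role_id in sorted(orfs_by_role):
        orfs = orfs_by_role[role_id]
        sums = {
            sid: sum(abund.values.get((o, sid), 0.0) for o in orfs)
            for sid in abund.sample_ids
        }
        early_mean = float(np.mean([sums[s] for s in early_ids])) if early_ids else 0.0
        late_mean = float(np.mean([sums[s] for s in late_ids])) if late_ids else 0.0
        infinite = False
        if early_mean > 0:
            ratio = late_mean / early_mean
        elif pseudo_policy == "epsilon":
            positives = [v for v in sums.values() if v > 0]
            eps = min(positives) / 2 if positives else 1.0
            ratio = (late_mean + eps) / (early_mean + eps)
        else:
            ratio = float("inf") if late_mean > 0 else float("nan")
            infinite = late_mean > 0
        rows.append(
            {
                "role_id": role_id,
                "early_mean": early_mean,
                "late_mean": late_mean,
                "ratio": ratio,
                "infinite": infinite,
                "n_mags_detected": len(mags_by_role[role_id]),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["role_id", "early_mean", "late_mean", "ratio", "infinite", "n_mags_detected"],
    )
    if len(df):
        df = df.sort_values(
            ["infinite", "ratio"], ascending=[False, False], kind="mergesort"
        ).reset_index(drop=True)
    df.attrs["ratio_definition"] = (
        "late_mean/early_mean of per-sample cumulative role abundances "
        "(sums over retained ORFs across MAGs)"
    )
    df.attrs["pseudo_policy"] = pseudo_policy
    return df


def _trend_fit(y: np.ndarray, day: np.ndarray, year: np.ndarray) -> tuple[float, float, float]:
    """OLS slope per day with an additive year offset when multiple years occur.

    Returns (slope, intercept, two-sided t-test p on the slope).
    """
    years = np.unique(year)
    cols = [np.ones_like(day, dtype=float), day.astype(float)]
    for extra in years[1:]:
        cols.append((year == extra).astype(float))
    x = np.column_stack(cols)
    n, k = x.shape
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    dof = n - k
    if dof <= 0:
        return float(beta[1]), float(beta[0]), float("nan")
    sigma2 = float(resid @ resid) / dof
    # an (essentially) exact fit: the t-ratio is pure rounding noise
    if sigma2 <= 1e-20 * max(1.0, float(np.mean(y * y))):
        return float(beta[1]), float(beta[0]), (1.0 if abs(beta[1]) < 1e-12 else 0.0)
    cov = sigma2 * np.linalg.inv(x.T @ x)
    se = float(np.sqrt(cov[1, 1]))
    if se == 0:
        p = 1.0 if abs(beta[1]) < 1e-12 else 0.0
    else:
        t = beta[1] / se
        p = float(2 * stats.t.sf(abs(t), dof))
    return float(beta[1]), float(beta[0]), p


def subsystem_timeseries(
    abund: AbundanceMatrix,
    model: CommunityModel,
    samples: list[SampleRecord],
    retained_orfs: set[str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subsystem per-date mean +/- SEM and an OLS seasonal trend.

    The per-sample cumulative subsystem abundance (sum over retained ORFs of
    the subsystem) is summarized per date (SEM with n-1 denominator) and
    regressed on day of year; with fewer than 3 distinct dates the trend is
    omitted with a warning while the means are still reported.
    """
    retained = [s for s in samples if s.sample_id in set(abund.sample_ids)]
    orfs_by_subsystem: dict[str, list[str]] = {}
    for orf_id in retained_orfs:
        orf = model.orfs[orf_id]
        orfs_by_subsystem.setdefault(orf.subsystem_id, []).append(orf_id)
    ts_rows = []
    trend_rows = []
    dates = sorted({s.collection_date for s in retained})
    for subsystem in sorted(orfs_by_subsystem):
        orfs = orfs_by_subsystem[subsystem]
        per_sample = {
            s.sample_id: sum(abund.values.get((o, s.sample_id), 0.0) for o in orfs)
            for s in retained
        }
        for date in dates:
            vals = np.array(
                [per_sample[s.sample_id] for s in retained if s.collection_date == date]
            )
            sem = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else float("nan")
            ts_rows.append(
                {
                    "subsystem_id": subsystem,
                    "date": date.isoformat(),
                    "mean": float(vals.mean()),
                    "sem": sem,
                    "n": int(vals.size),
                }
            )
        if len(dates) < 3:
            warnings.warn(
                f"subsystem {subsystem}: fewer than 3 distinct dates; trend omitted",
                stacklevel=2,
            )
            continue
        y = np.array([per_sample[s.sample_id] for s in retained])
        day = np.array([s.day_of_year for s in retained])
        year = np.array([s.collection_date.year for s in retained])
        slope, intercept, p = _trend_fit(y, day, year)
        trend_rows.append(
            {
                "subsystem_id": subsystem,
                "slope_per_day": slope,
                "intercept": intercept,
                "p_value": p,
                "n_points": int(y.size),
            }
        )
    ts = pd.DataFrame(ts_rows, columns=["subsystem_id", "date", "mean", "sem", "n"])
    trend = pd.DataFrame(
        trend_rows, columns=["subsystem_id", "slope_per_day", "intercept", "p_value", "n_points"]
    )
    return ts, trend


def pathway_activity(
    model: CommunityModel,
    pathway_defs: dict[str, list[str]],
    orf_metaT_raw: CoverageTable,
) -> pd.DataFrame:
    """Per-(MAG, pathway) status: absent, detected_only, or active.

    A pathway is *absent* from a MAG with no member ORF, *detected_only* when
    members exist but none recruits transcripts (positive metatranscriptome
    median coverage) in any sample, and *active* as soon as one member ORF is
    covered in one sample — presence always precedes activity.
    """
    for pathway_id, members in pathway_defs.items():
        for orf_id in members:
            if orf_id not in model.orfs:
                raise KeyError(
                    f"pathway {pathway_id} references unknown ORF {orf_id}"
                )
    sample_ids = orf_metaT_raw.samples()
    rows = []
    for mag_id in sorted(model.mags):
        mag_orf_ids = {o.orf_id for o in model.orfs_of_mag(mag_id)}
        for pathway_id in sorted(pathway_defs):
            members = [o for o in pathway_defs[pathway_id] if o in mag_orf_ids]
            if not members:
                status = "absent"
            elif any(
                orf_metaT_raw.get(o, s) > 0 for o in members for s in sample_ids
            ):
                status = "active"
            else:
                status = "detected_only"
            rows.append({"mag_id": mag_id, "pathway_id": pathway_id, "status": status})
    return pd.DataFrame(rows, columns=["mag_id", "pathway_id", "status"])


def role_prevalence(
    model: CommunityModel, retained_orfs: set[str]
) -> dict[str, int]:
    """Number of MAGs carrying >= 1 retained ORF per functional role."""
    mags_by_role: dict[str, set[str]] = {}
    for orf_id in retained_orfs:
        orf = model.orfs[orf_id]
        mags_by_role.setdefault(orf.role_id, set()).add(model.mag_of_orf(orf_id))
    return {role: len(mags) for role, mags in sorted(mags_by_role.items())}
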