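"""Ward clustering of MAG transcript dynamics with bootstrap edge support.

MAG-by-sample profiles of cumulative transcript abundance are clustered with
Ward's minimum-variance method on euclidean distances (the sum-of-squares
"Ward.D2"-style criterion: each merge minimizes the increase in total
within-cluster sum of squares).  Edge support follows the multiscale
column-resampling scheme of pvclust: samples (columns) are resampled with
replacement, the tree is rebuilt, and the bootstrap probability (BP) of an
edge is the fraction of replicates in which its leaf set reappears.  When
multiple resample scales are given, approximately-unbiased (AU) supports are
additionally estimated from a weighted signed-distance/curvature fit on
inverse-normal-transformed frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy import stats

from .model import SampleRecord

__all__ = [
    "ClusterReport",
    "profile_matrix",
    "ward_cluster",
    "linkage_edges",
    "bootstrap_support",
    "cut_groups",
    "to_newick",
]


def profile_matrix(
    cumulative: dict[tuple[str, str], float],
    samples: list[SampleRecord],
    transform: str = "none",
) -> pd.DataFrame:
    """MAG x sample matrix of cumulative transcript abundances.

    Rows are MAGs (sorted), columns are samples in chronological (date, then
    sample_id) order.  ``transform``: ``'none'`` (default, matching the raw
    euclidean treatment), ``'log10'`` (log10(x + eps) with eps = half the
    minimum positive value), or ``'zscore'`` (per-row standardization;
    zero-variance rows map to all-zero).
    """
    mag_ids = sorted({m for m, _ in cumulative})
    sample_in = {s for _, s in cumulative}
    ordered = [
        s.sample_id
        for s in sorted(samples, key=lambda s: (s.collection_date, s.sample_id))
        if s.sample_id in sample_in
    ]
    if not mag_ids or not ordered:
        raise ValueError("profile matrix is empty")
    if len(mag_ids) < 2 or len(ordered) < 2:
        raise ValueError("need >= 2 MAGs and >= 2 samples to cluster")
    mat = np.array(
        [[cumulative[(m, s)] for s in ordered] for m in mag_ids], dtype=float
    )
    if transform == "none":
        pass
    elif transform == "log10":
        positive = mat[mat > 0]
        eps = positive.min() / 2 if positive.size else 1.0
        mat = np.log10(mat + eps)
    elif transform == "zscore":
        mean = mat.mean(axis=1, keepdims=True)
        sd = mat.std(axis=1, ddof=0, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            mat = np.where(sd > 0, (mat - mean) / sd, 0.0)
    else:
        raise ValueError(f"unknown transform {transform!r}")
    return pd.DataFrame(mat, index=mag_ids, columns=ordered)


def ward_cluster(matrix: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Ward linkage (scipy encoding) over the rows of the profile matrix."""
    values = matrix.to_numpy() if isinstance(matrix, pd.DataFrame) else np.asarray(matrix)
    if values.ndim != 2 or values.shape[0] < 2:
        raise ValueError("need a 2-D matrix with >= 2 rows")
    if not np.all(np.isfinite(values)):
        raise ValueError("profile matrix contains non-finite values")
    return hierarchy.linkage(values, method="ward")


def linkage_edges(linkage: np.ndarray) -> list[frozenset[int]]:
    """Leaf sets of every internal node, in merge order (last = root)."""
    n = linkage.shape[0] + 1
    sets: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n)}
    edges: list[frozenset[int]] = []
    for step, (a, b, *_rest) in enumerate(linkage):
        merged = sets[int(a)] | sets[int(b)]
        sets[n + step] = merged
        edges.append(merged)
    return edges


def bootstrap_support(
    matrix: pd.DataFrame | np.ndarray,
    n_boot: int = 1000,
    scales: tuple[float, ...] | None = None,
    seed: int = 0,
    linkage_fn=ward_cluster,
) -> dict[frozenset[int], dict[str, float]]:
    """Column-resampling bootstrap probabilities (and optional AU) per edge.

    For each replicate, ``round(r * m)`` columns are drawn with replacement
    (r = 1 when no scales are given), the tree is rebuilt with ``linkage_fn``
    and each original edge scores a hit when its leaf set reappears.  BP is
    the hit fraction at scale 1 (or the scale closest to 1).  With multiple
    scales, AU is estimated pvclust-style from the weighted least-squares fit
    of z(r) = qnorm(1 - BP_r) = v*sqrt(r) + c/sqrt(r); AU = 1 - Phi(v - c).
    Degenerate replicates (e.g. all-identical columns) count with whatever
    tree results; nothing is silently dropped.
    """
    values = matrix.to_numpy() if isinstance(matrix, pd.DataFrame) else np.asarray(matrix)
    n_rows, n_cols = values.shape
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100 for usable support estimates")
    if n_cols < 3:
        raise ValueError("need >= 3 columns to resample")
    use_scales = tuple(scales) if scales else (1.0,)
    rng = np.random.default_rng(seed)
    base_edges = linkage_edges(linkage_fn(values))
    hit_counts = {r: {e: 0 for e in base_edges} for r in use_scales}
    for r in use_scales:
        size = max(3, int(round(r * n_cols)))
        for _ in range(n_boot):
            cols = rng.integers(0, n_cols, size=size)
            replicate_edges = set(linkage_edges(linkage_fn(values[:, cols])))
            for edge in base_edges:
                if edge in replicate_edges:
                    hit_counts[r][edge] += 1
    anchor = min(use_scales, key=lambda r: abs(r - 1.0))
    support: dict[frozenset[int], dict[str, float]] = {}
    for edge in base_edges:
        bp = hit_counts[anchor][edge] / n_boot
        entry: dict[str, float] = {"bp": bp}
        if len(use_scales) > 1:
            entry["au"] = _au_from_multiscale(
                np.array(use_scales),
                np.array([hit_counts[r][edge] for r in use_scales], dtype=float),
                n_boot,
            )
        support[edge] = entry
    return support


def _au_from_multiscale(scales: np.ndarray, hits: np.ndarray, n_boot: int) -> float:
    """Approximately-unbiased support from per-scale hit counts.

    Uses the signed-distance / curvature decomposition: the inverse-normal
    transform of the per-scale non-hit frequency is modelled as
    v*sqrt(r) + c/sqrt(r), fitted by WLS with binomial weights; AU is
    1 - Phi(v - c).  Edges at the frequency boundary in every usable scale
    return their plain bootstrap frequency.
    """
    bp = hits / n_boot
    usable = (bp > 0) & (bp < 1)
    if usable.sum() < 2:
        return float(bp[np.argmin(np.abs(scales - 1.0))])
    r = scales[usable]
    freq = bp[usable]
    z = stats.norm.ppf(1 - freq)
    # binomial delta-method weights on the probit scale
    dens = stats.norm.pdf(z)
    var = freq * (1 - freq) / n_boot / np.maximum(dens**2, 1e-12)
    w = 1.0 / np.maximum(var, 1e-12)
    x = np.column_stack([np.sqrt(r), 1.0 / np.sqrt(r)])
    wx = x * w[:, None]
    beta = np.linalg.solve(x.T @ wx, wx.T @ z)
    v, c = beta
    return float(1 - stats.norm.cdf(v - c))


def cut_groups(
    linkage: np.ndarray,
    k: int | None = None,
    support: dict[frozenset[int], dict[str, float]] | None = None,
    support_threshold: float | None = None,
) -> np.ndarray:
    """Cluster assignments, either to exactly ``k`` groups or by edge support.

    With ``k``, the tree is cut at the height yielding k clusters.  With a
    ``support_threshold``, maximal (largest, non-root) edges whose bootstrap
    probability meets the threshold become groups and all remaining leaves
    are singletons.  Labels are consecutive integers from 1.
    """
    n = linkage.shape[0] + 1
    if k is not None:
        if k > n:
            raise ValueError(f"k={k} exceeds number of leaves {n}")
        return hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    if support is None or support_threshold is None:
        raise ValueError("provide either k or (support, support_threshold)")
    edges = linkage_edges(linkage)
    root = edges[-1]
    candidates = [
        e
        for e in edges
        if e != root and support[e]["bp"] >= support_threshold
    ]
    candidates.sort(key=len, reverse=True)
    labels = np.zeros(n, dtype=int)
    next_label = 1
    for edge in candidates:
        if all(labels[i] == 0 for i in edge):
            for i in edge:
                labels[i] = next_label
            next_label += 1
    for i in range(n):
        if labels[i] == 0:
            labels[i] = next_label
            next_label += 1
    return labels


@dataclass
class ClusterReport:
    """Everything the clustering stage decided, in one bundle."""

    linkage: np.ndarray
    mag_ids: list[str]
    assignments: dict[str, int]
    edge_support: dict[frozenset[int], dict[str, float]]
    n_boot: int
    seed: int
    method: str = "ward.D2-style (squared euclidean sum-of-squares criterion)"
    cut: str = ""

    def linkage_frame(self) -> pd.DataFrame:
        rows = [
            {
                "step": i,
                "child_a": int(a),
                "child_b": int(b),
                "height": float(h),
                "size": int(s),
            }
            for i, (a, b, h, s) in enumerate(self.linkage)
        ]
        return pd.DataFrame(rows, columns=["step", "child_a", "child_b", "height", "size"])

    def support_frame(self) -> pd.DataFrame:
        rows = []
        for edge, entry in self.edge_support.items():
            leaves = sorted(self.mag_ids[i] for i in edge)
            rows.append(
                {
                    "leafset": "|".join(leaves),
                    "n_leaves": len(leaves),
                    "bp": entry["bp"],
                    "au": entry.get("au", float("nan")),
                    "n_boot": self.n_boot,
                    "seed": self.seed,
                }
            )
        return pd.DataFrame(
            rows, columns=["leafset", "n_leaves", "bp", "au", "n_boot", "seed"]
        ).sort_values(["n_leaves", "leafset"]).reset_index(drop=True)

    def assignments_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"mag_id": list(self.assignments), "cluster": list(self.assignments.values())}
        )


def to_newick(
    linkage: np.ndarray,
    labels: list[str],
    support: dict[frozenset[int], dict[str, float]] | None = None,
) -> str:
    """Newick string of the dendrogram, BP supports as internal node labels."""
    n = linkage.shape[0] + 1
    edges = linkage_edges(linkage)
    heights = {n + i: float(linkage[i, 2]) for i in range(linkage.shape[0])}

    def height(node: int) -> float:
        return heights.get(node, 0.0)

    def render(node: int) -> str:
        if node < n:
            return labels[node]
        step = node - n
        a, b = int(linkage[step, 0]), int(linkage[step, 1])
        branch_a = height(node) - height(a)
        branch_b = height(node) - height(b)
        label = ""
        if support is not None:
            label = f"{support[edges[step]]['bp']:.3f}"
        return f"({render(a)}:{branch_a:.6g},{render(b)}:{branch_b:.6g}){label}"

    return render(2 * n - 2) + ";"
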