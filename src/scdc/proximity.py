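"""Distance from genes to dosage-compensation-complex binding sites.

The distance between a gene and a binding site is the minimum over the four
endpoint pairs of |site endpoint - gene endpoint|, which for non-overlapping
intervals equals the gap between their closest edges; a site overlapping the
transcriptional unit gives distance zero. Distances are defined only on the
X chromosome, where the sites live.

High-affinity sites (HAS) — the initial DCC entry points — are derived
operationally as the colocalization (>= 1 bp overlap, intersection span) of
MLE and MSL-2 binding intervals.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import BindingSiteSet, GeneModel
from .sexbias import BiasCall, MagnitudeBin, magnitude_bin

__all__ = [
    "min_distance",
    "distances_to_nearest",
    "distance_table",
    "colocalize_has",
    "spearman",
    "wilcoxon_rank_sum",
    "ProximityResult",
    "proximity_summary",
    "magnitude_distance_profile",
]


def min_distance(gene: GeneModel, sites: BindingSiteSet) -> int:
    """Distance in bp from one gene to its nearest site (0 on overlap)."""
    intervals = sites.on_chrom(gene.chrom)
    if not intervals:
        raise ValueError(
            f"no {sites.component} sites on chromosome {gene.chrom}; "
            "distance undefined"
        )
    best = None
    for s, e in intervals:
        if s <= gene.end and e >= gene.start:
            return 0
        gap = min(
            abs(p - q)
            for p in (s, e)
            for q in (gene.start, gene.end)
        )
        best = gap if best is None else min(best, gap)
    return int(best)


def distances_to_nearest(
    genes: Sequence[GeneModel], sites: BindingSiteSet
) -> np.ndarray:
    """Vectorised nearest-site distance for many genes on one chromosome.

    All genes must share one chromosome and the site set must be nonempty
    there. O((n + m) log m) via sorted site edges; equals the per-gene
    endpoint-minimum rule.
    """
    if len(genes) == 0:
        return np.zeros(0, dtype=np.int64)
    chroms = {g.chrom for g in genes}
    if len(chroms) != 1:
        raise ValueError("genes span multiple chromosomes")
    chrom = chroms.pop()
    intervals = sites.on_chrom(chrom)
    if not intervals:
        raise ValueError(
            f"no {sites.component} sites on chromosome {chrom}; distance undefined"
        )
    starts = np.array([s for s, _ in intervals], dtype=np.int64)
    ends = np.array([e for _, e in intervals], dtype=np.int64)
    # sites are sorted by start; running max of ends handles contained intervals
    cummax_end = np.maximum.accumulate(ends)

    gs = np.array([g.start for g in genes], dtype=np.int64)
    ge = np.array([g.end for g in genes], dtype=np.int64)

    idx = np.searchsorted(starts, ge, side="right")  # sites with start <= gene end
    out = np.empty(len(genes), dtype=np.int64)
    for i in range(len(genes)):
        k = idx[i]
        if k > 0 and cummax_end[k - 1] >= gs[i]:
            out[i] = 0
            continue
        left = gs[i] - cummax_end[k - 1] if k > 0 else None
        right = starts[k] - ge[i] if k < len(starts) else None
        out[i] = min(d for d in (left, right) if d is not None)
    return out


def distance_table(
    genes: Sequence[GeneModel], site_sets: Iterable[BindingSiteSet]
) -> pd.DataFrame:
    """Long table of nearest-site distances: gene_id, component, distance_bp."""
    rows = []
    for sites in site_sets:
        d = distances_to_nearest(genes, sites)
        for g, dist in zip(genes, d):
            rows.append((g.gene_id, sites.component, int(dist)))
    return pd.DataFrame(rows, columns=["gene_id", "component", "distance_bp"])


def colocalize_has(mle: BindingSiteSet, msl2: BindingSiteSet) -> BindingSiteSet:
    """Derive high-affinity sites as MLE ∩ MSL-2 colocalised intervals.

    One HAS per pair of overlapping (>= 1 bp) MLE and MSL-2 intervals, with
    span equal to their intersection; overlapping or book-ended HAS are
    merged.
    """
    import logging

    if len(mle) == 0 or len(msl2) == 0:
        logging.getLogger(__name__).warning(
            "empty %s input; HAS set is empty",
            "MLE" if len(mle) == 0 else "MSL2",
        )
        return BindingSiteSet(component="HAS", intervals=[])

    pieces: list[tuple[str, int, int]] = []
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in msl2.intervals:
        by_chrom.setdefault(chrom, []).append((s, e))
    for chrom, s1, e1 in mle.intervals:
        for s2, e2 in by_chrom.get(chrom, []):
            lo, hi = max(s1, s2), min(e1, e2)
            if lo <= hi:
                pieces.append((chrom, lo, hi))

    pieces.sort()
    merged: list[tuple[str, int, int]] = []
    for chrom, s, e in pieces:
        if merged and merged[-1][0] == chrom and s <= merged[-1][2] + 1:
            merged[-1] = (chrom, merged[-1][1], max(merged[-1][2], e))
        else:
            merged.append((chrom, s, e))
    return BindingSiteSet(component="HAS", intervals=merged)


# ---------------------------------------------------------------------------
# Rank statistics
# ---------------------------------------------------------------------------


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for Spearman's rho (full enumeration)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = len(rx)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = math.sqrt((rxc**2).sum() * (ryc**2).sum())
    if denom == 0:
        return 1.0
    target = abs(rho_obs) * denom - 1e-12
    count = 0
    total = 0
    perm_iter = itertools.permutations(ryc)
    while True:
        batch = np.array(list(itertools.islice(perm_iter, 200_000)))
        if batch.size == 0:
            break
        dots = batch @ rxc
        count += int(np.sum(np.abs(dots) >= target))
        total += batch.shape[0]
    return count / total


def spearman(pairs: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """Spearman rank correlation with tie-averaged ranks.

    Returns (rho, two_sided_p). The p-value comes from exact permutation
    enumeration for n <= 10 and from the t-distribution approximation
    otherwise. Zero variance in either variable gives (NaN, 1.0).
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need >= 3 (value, distance) pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return math.nan, 1.0
    rho, p = stats.spearmanr(x, y)
    if len(x) <= 10:
        p = _exact_spearman_p(x, y, rho)
    return float(rho), float(p)


def wilcoxon_rank_sum(
    group_a: Sequence[float], group_b: Sequence[float]
) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact enumeration when the combined sample size is <= 12 and tie-free;
    otherwise the tie-corrected normal approximation with continuity
    correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return 1.0
    tie_free = len(np.unique(pooled)) == pooled.size
    method = "exact" if (a.size + b.size <= 12 and tie_free) else "asymptotic"
    p = stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
    return float(min(p, 1.0))


# ---------------------------------------------------------------------------
# Per-data-set summaries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProximityResult:
    """Correlation and distance comparison for one site component."""

    component: str
    n_genes: int
    rho: float
    rho_p: float
    median_distance_by_class: Mapping[str, float]
    wilcoxon_p_mbg_vs_ubg: float


def proximity_summary(records: pd.DataFrame, component: str) -> ProximityResult:
    """Fig. 2-style summary over expressed X-linked genes.

    ``records`` must have call, log2_ratio and distance_bp columns,
    restricted to expressed X-linked genes. Computes the Spearman
    correlation of log2(male/female) with nearest-site distance over all
    genes, the per-class median distances, and the Wilcoxon comparison of
    MBG against UBG distances.
    """
    rec = records[records["call"] != BiasCall.NOT_EXPRESSED.value]
    finite = np.isfinite(rec["log2_ratio"].to_numpy(dtype=float))
    rec = rec[finite]
    rho, rho_p = spearman(list(zip(rec["log2_ratio"], rec["distance_bp"])))
    medians = {
        c: float(rec.loc[rec["call"] == c, "distance_bp"].median())
        for c in ("MBG", "FBG", "UBG")
    }
    mbg_d = rec.loc[rec["call"] == "MBG", "distance_bp"].to_numpy(dtype=float)
    ubg_d = rec.loc[rec["call"] == "UBG", "distance_bp"].to_numpy(dtype=float)
    wil_p = (
        wilcoxon_rank_sum(mbg_d, ubg_d) if mbg_d.size and ubg_d.size else math.nan
    )
    return ProximityResult(
        component=component,
        n_genes=int(len(rec)),
        rho=rho,
        rho_p=rho_p,
        median_distance_by_class=medians,
        wilcoxon_p_mbg_vs_ubg=wil_p,
    )


def magnitude_distance_profile(records: pd.DataFrame) -> pd.DataFrame:
    """Distance distribution of MBG by fold-change bin (Fig. 4 style).

    Returns one row per magnitude bin with n, median and quartiles of the
    nearest-site distance; empty bins are reported with n = 0.
    """
    mbg = records[records["call"] == BiasCall.MBG.value]
    bins = [magnitude_bin(r).value for r in mbg["log2_ratio"]]
    rows = []
    for b in MagnitudeBin:
        d = mbg.loc[[x == b.value for x in bins], "distance_bp"].to_numpy(dtype=float)
        if d.size:
            q1, med, q3 = np.percentile(d, [25, 50, 75])
        else:
            q1 = med = q3 = math.nan
        rows.append(
            {
                "bin": b.value,
                "n": int(d.size),
                "q1_distance_bp": float(q1),
                "median_distance_bp": float(med),
                "q3_distance_bp": float(q3),
            }
        )
    return pd.DataFrame(rows)
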