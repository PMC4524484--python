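"""RPKM, X:autosome male expression ratios, gene age, and set overlaps.

Covers the bookkeeping analyses around the enrichment core: RPKM
normalisation, the X:A median-expression comparison under housekeeping
filters (RPKM > 1, tau < 0.4), per-tissue expression of the DCC components
themselves, mean gene-age of gene sets, hypergeometric overlap tests
between data sets, and the remove-and-recompute sensitivity analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import ChromClass
from .enrichment import ClassCounts, EnrichmentResult, class_counts, enrich_class
from .proximity import wilcoxon_rank_sum

__all__ = [
    "rpkm",
    "rpkm_matrix",
    "xa_expression_ratio",
    "component_expression_summary",
    "mean_age",
    "OverlapResult",
    "overlap_test",
    "remove_and_recompute",
]


def rpkm(read_count: float, exonic_length: int, total_mapped: int) -> float:
    """Reads per kilobase of exonic model per million mapped reads."""
    if exonic_length < 1:
        raise ValueError("exonic_length must be >= 1 bp")
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    return 1e9 * read_count / (exonic_length * total_mapped)


def rpkm_matrix(
    counts: pd.DataFrame,
    exonic_lengths: Mapping[str, int],
    library_sizes: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """RPKM-normalise a genes x samples count matrix.

    ``exonic_lengths`` maps gene id -> exonic bp. Library sizes default to
    the column sums of the count matrix.
    """
    lengths = pd.Series(
        [exonic_lengths[str(g)] for g in counts.index],
        index=counts.index,
        dtype=float,
    )
    if (lengths < 1).any():
        raise ValueError("exonic lengths must be >= 1 bp")
    if library_sizes is None:
        totals = counts.sum(axis=0).astype(float)
    else:
        totals = pd.Series({s: float(library_sizes[s]) for s in counts.columns})
    if (totals <= 0).any():
        raise ValueError("library sizes must be positive")
    return 1e9 * counts.div(lengths, axis=0).div(totals, axis=1)


def xa_expression_ratio(
    male_rpkm: Mapping[str, float],
    classes: Mapping[str, ChromClass],
    min_rpkm: float = 1.0,
    max_tau: float | None = None,
    tau_by_gene: Mapping[str, float] | None = None,
) -> dict:
    """Autosome-to-X ratio of median male expression (Fig. 6 style).

    Filters genes to RPKM >= ``min_rpkm`` and, when ``max_tau`` is given,
    to broadly expressed "housekeeping" genes with tau < max_tau. Returns
    a dict with median_autosome, median_x, ratio_a_over_x, wilcoxon_p and
    the per-class gene counts. An empty class after filtering raises,
    naming the filter.
    """
    if max_tau is not None and tau_by_gene is None:
        raise ValueError("tau_by_gene required when max_tau filter is active")
    x_vals: list[float] = []
    a_vals: list[float] = []
    for gene, value in male_rpkm.items():
        cls = classes.get(gene)
        if cls not in (ChromClass.X, ChromClass.AUTOSOME):
            continue
        if value < min_rpkm:
            continue
        if max_tau is not None:
            t = tau_by_gene.get(gene)
            if t is None or t >= max_tau:
                continue
        (x_vals if cls is ChromClass.X else a_vals).append(float(value))
    filters = f"min_rpkm={min_rpkm}" + (
        f", max_tau={max_tau}" if max_tau is not None else ""
    )
    if not x_vals:
        raise ValueError(f"no X-linked genes pass filters ({filters})")
    if not a_vals:
        raise ValueError(f"no autosomal genes pass filters ({filters})")
    med_a = float(np.median(a_vals))
    med_x = float(np.median(x_vals))
    return {
        "median_autosome": med_a,
        "median_x": med_x,
        "ratio_a_over_x": med_a / med_x,
        "wilcoxon_p": wilcoxon_rank_sum(a_vals, x_vals),
        "n_autosome": len(a_vals),
        "n_x": len(x_vals),
    }


def component_expression_summary(
    rpkm_by_sample: pd.DataFrame, component_genes: Mapping[str, str]
) -> pd.DataFrame:
    """Mean ± SEM of DCC-component expression across replicates.

    ``rpkm_by_sample`` is genes x samples (replicates of one data set);
    ``component_genes`` maps component name -> gene id. Components whose
    gene id is absent are reported with ``present = False``. A single
    replicate leaves the SEM undefined; it is reported as 0 with
    ``sem_defined = False``.
    """
    rows = []
    for component, gene_id in component_genes.items():
        if gene_id not in rpkm_by_sample.index:
            rows.append(
                {
                    "component": component,
                    "gene_id": gene_id,
                    "present": False,
                    "mean_rpkm": math.nan,
                    "sem_rpkm": math.nan,
                    "n_replicates": 0,
                    "sem_defined": False,
                }
            )
            continue
        vals = rpkm_by_sample.loc[gene_id].to_numpy(dtype=float)
        n = vals.size
        sem_defined = n > 1
        sem = float(np.std(vals, ddof=1) / math.sqrt(n)) if sem_defined else 0.0
        rows.append(
            {
                "component": component,
                "gene_id": gene_id,
                "present": True,
                "mean_rpkm": float(vals.mean()),
                "sem_rpkm": sem,
                "n_replicates": int(n),
                "sem_defined": sem_defined,
            }
        )
    return pd.DataFrame(rows)


def mean_age(
    gene_set: Iterable[str], ages: Mapping[str, int]
) -> tuple[float, float]:
    """Mean age class of a gene set; returns (mean_age, coverage).

    Age classes run from 0 (species-specific) to 6 (present across the
    whole genus). Genes absent from the age table are excluded from both
    numerator and denominator; coverage is the fraction with a known age.
    """
    genes = list(gene_set)
    known = [ages[g] for g in genes if g in ages]
    if not known:
        raise ValueError("no genes in the set have a known age")
    for a in known:
        if not 0 <= a <= 6:
            raise ValueError(f"age class {a} outside 0..6")
    return float(np.mean(known)), len(known) / len(genes)


@dataclass(frozen=True)
class OverlapResult:
    """Hypergeometric overlap between two gene sets in a shared universe."""

    set_a_name: str
    set_b_name: str
    n_a: int
    n_b: int
    n_overlap: int
    universe_size: int
    hypergeometric_p: float


def overlap_test(
    set_a: Iterable[str],
    set_b: Iterable[str],
    universe: Iterable[str],
    name_a: str = "A",
    name_b: str = "B",
) -> OverlapResult:
    """Upper-tail hypergeometric test of |A ∩ B| given a gene universe.

    p = P(X >= n_overlap) with X ~ Hypergeom(|universe|, |A|, |B|). Both
    sets must be subsets of the universe (use the genes expressed in both
    data sets being compared).
    """
    a, b, u = set(set_a), set(set_b), set(universe)
    if not a <= u or not b <= u:
        raise ValueError("sets must be subsets of the universe")
    k = len(a & b)
    p = float(stats.hypergeom.sf(k - 1, len(u), len(a), len(b)))
    return OverlapResult(
        set_a_name=name_a,
        set_b_name=name_b,
        n_a=len(a),
        n_b=len(b),
        n_overlap=k,
        universe_size=len(u),
        hypergeometric_p=min(p, 1.0),
    )


def remove_and_recompute(
    records: pd.DataFrame,
    classes: Mapping[str, ChromClass],
    removal_set: Iterable[str],
    bias_class: str = "MBG",
) -> tuple[ClassCounts, EnrichmentResult]:
    """Drop a gene set from a data set and recompute enrichment.

    Removed genes leave the focal class AND the totals, so the X-proportion
    baseline shifts accordingly — equivalent to a from-scratch run on the
    reduced gene universe.
    """
    removal = {str(g) for g in removal_set}
    kept = records[~records["gene_id"].astype(str).isin(removal)]
    counts = class_counts(kept, classes)
    return counts, enrich_class(counts, bias_class)
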