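"""X chromosome versus autosome enrichment of sex-biased gene classes.

For each bias class (MBG, FBG, UBG) in a data set the module tabulates
autosomal and X-linked counts, computes the expected number of X-linked
genes under random placement (class size times the data set's overall
X-linked fraction), the observed/expected ratio, and a Fisher exact test of
the 2x2 table [class_X, class_A; rest_X, rest_A] over all expressed genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _conditional_odds_ratio

from .annotation import ChromClass
from .sexbias import BiasCall

__all__ = [
    "ClassCounts",
    "EnrichmentResult",
    "class_counts",
    "expected_x",
    "fisher_exact",
    "enrich_class",
    "enrichment_table",
    "significance_stars",
]

_BIAS_CLASSES = (BiasCall.MBG, BiasCall.FBG, BiasCall.UBG)


def _pct_round_half_up(x: int, total: int) -> int:
    """Integer percentage with ties rounded up (0.5 -> 1)."""
    if total == 0:
        return 0
    return int(math.floor(100.0 * x / total + 0.5))


@dataclass(frozen=True)
class ClassCounts:
    """Autosome/X tabulation of MBG, FBG and UBG for one data set."""

    counts: Mapping[str, tuple[int, int]]  # class -> (count_autosome, count_x)
    n_dropped: int = 0  # genes without an annotation / EXCLUDED

    def count_autosome(self, bias_class: str | BiasCall) -> int:
        return self.counts[BiasCall(bias_class).value][0]

    def count_x(self, bias_class: str | BiasCall) -> int:
        return self.counts[BiasCall(bias_class).value][1]

    def class_total(self, bias_class: str | BiasCall) -> int:
        a, x = self.counts[BiasCall(bias_class).value]
        return a + x

    def pct_x(self, bias_class: str | BiasCall) -> int:
        """X-linked percentage of one class, rounded half-up to an integer."""
        a, x = self.counts[BiasCall(bias_class).value]
        return _pct_round_half_up(x, a + x)

    @property
    def n_x_total(self) -> int:
        return sum(x for _a, x in self.counts.values())

    @property
    def n_total(self) -> int:
        return sum(a + x for a, x in self.counts.values())

    @classmethod
    def from_counts(
        cls,
        mbg_a: int,
        mbg_x: int,
        fbg_a: int,
        fbg_x: int,
        ubg_a: int,
        ubg_x: int,
    ) -> "ClassCounts":
        return cls(
            counts={
                "MBG": (int(mbg_a), int(mbg_x)),
                "FBG": (int(fbg_a), int(fbg_x)),
                "UBG": (int(ubg_a), int(ubg_x)),
            }
        )


def class_counts(
    records: pd.DataFrame, classes: Mapping[str, ChromClass]
) -> ClassCounts:
    """Tabulate bias calls by chromosome class.

    ``records`` must carry gene_id and call columns (as produced by
    :func:`scdc.sexbias.classify_table`). Genes missing from ``classes`` or
    mapped to EXCLUDED are dropped (and counted in ``n_dropped``);
    NOT_EXPRESSED genes never enter the tabulation.
    """
    tab = {c.value: [0, 0] for c in _BIAS_CLASSES}
    dropped = 0
    for gene_id, call in zip(records["gene_id"], records["call"]):
        call = BiasCall(call)
        if call is BiasCall.NOT_EXPRESSED:
            continue
        chrom_class = classes.get(str(gene_id))
        if chrom_class is None or chrom_class is ChromClass.EXCLUDED:
            dropped += 1
            continue
        tab[call.value][ChromClass(chrom_class) is ChromClass.X] += 1
    return ClassCounts(
        counts={k: (v[0], v[1]) for k, v in tab.items()}, n_dropped=dropped
    )


def expected_x(n_class: int, n_x_total: int, n_total: int) -> float:
    """Expected X-linked count of a class under random placement.

    The class size multiplied by the proportion of all expressed genes in
    the data set that are X-linked.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not (0 <= n_x_total <= n_total and 0 <= n_class <= n_total):
        raise ValueError("counts out of range")
    return n_class * n_x_total / n_total


def fisher_exact(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Fisher exact test on the 2x2 table [[a, b], [c, d]].

    Returns (odds_ratio, two_sided_p). The odds ratio is the conditional
    maximum-likelihood estimate (the convention of R's fisher.test); the
    two-sided p sums hypergeometric probabilities no larger than that of the
    observed table. Degenerate tables (a zero row or column margin) return
    (NaN, 1.0).
    """
    table = np.array([[a, b], [c, d]], dtype=np.int64)
    if np.any(table < 0):
        raise ValueError("table entries must be nonnegative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        return math.nan, 1.0
    p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    orr = float(_conditional_odds_ratio(table, kind="conditional").statistic)
    return orr, min(p, 1.0)


@dataclass(frozen=True)
class EnrichmentResult:
    """Observed/expected X-linkage of one bias class in one data set."""

    bias_class: str
    observed_x: int
    expected_x: float
    oe_ratio: float
    odds_ratio: float
    p_value: float

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)


def significance_stars(p: float) -> str:
    """'*' p<0.05, '**' p<0.01, '***' p<0.001, else ''."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def enrich_class(
    counts: ClassCounts, bias_class: str | BiasCall, versus_ubg_only: bool = False
) -> EnrichmentResult:
    """Enrichment of one bias class on the X.

    The 2x2 table contrasts the focal class against all other expressed
    genes in the data set (or against UBG only when ``versus_ubg_only``, a
    sensitivity variant).
    """
    bias_class = BiasCall(bias_class).value
    cls_a = counts.count_autosome(bias_class)
    cls_x = counts.count_x(bias_class)
    if versus_ubg_only:
        rest_a = counts.count_autosome("UBG")
        rest_x = counts.count_x("UBG")
        if bias_class == "UBG":
            raise ValueError("UBG cannot be contrasted against itself")
    else:
        rest_a = counts.n_total - counts.n_x_total - cls_a
        rest_x = counts.n_x_total - cls_x
    exp = expected_x(cls_a + cls_x, counts.n_x_total, counts.n_total)
    orr, p = fisher_exact(cls_x, cls_a, rest_x, rest_a)
    return EnrichmentResult(
        bias_class=bias_class,
        observed_x=cls_x,
        expected_x=exp,
        oe_ratio=cls_x / exp if exp > 0 else math.nan,
        odds_ratio=orr,
        p_value=p,
    )


def enrichment_table(counts: ClassCounts, versus_ubg_only: bool = False) -> pd.DataFrame:
    """Per-class summary table: counts, percentages, O/E, Fisher test."""
    rows = []
    for bias_class in ("MBG", "FBG", "UBG"):
        row: dict = {
            "class": bias_class,
            "count_autosome": counts.count_autosome(bias_class),
            "count_x": counts.count_x(bias_class),
            "pct_x": counts.pct_x(bias_class),
        }
        if bias_class != "UBG":
            res = enrich_class(counts, bias_class, versus_ubg_only=versus_ubg_only)
            row.update(
                expected_x=res.expected_x,
                oe_ratio=res.oe_ratio,
                odds_ratio=res.odds_ratio,
                p_value=res.p_value,
                significance=res.stars,
            )
        rows.append(row)
    return pd.DataFrame(rows)
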