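"""Classification of genes as male-biased, female-biased, or unbiased.

Two significance dialects are supported, mirroring how mixed RNA-seq and
microarray compendia are usually standardised: an FDR dialect (genes are
sex-biased when the Benjamini–Hochberg adjusted p-value is below alpha,
default 0.05) and a nominal-p dialect for platforms where FDR estimates are
unavailable (raw p below alpha, typically 0.05, relaxed to 0.10 for
low-power microarray sets). The direction of bias is the sign of
log2(male expression / female expression).

The built-in differential-expression test (`standin_de_test`) is a
simulation-only surrogate — a Welch t-test on log2(count + 1) — so the
synthetic pipeline can run end to end. It is not a negative-binomial GLM;
real analyses should feed this module the per-gene output of a dedicated DE
tool.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "BiasCall",
    "MagnitudeBin",
    "ThresholdConfig",
    "bh_adjust",
    "log2_ratio",
    "classify",
    "classify_table",
    "magnitude_bin",
    "standin_de_test",
    "de_table_from_counts",
]


class BiasCall(str, Enum):
    MBG = "MBG"              # male-biased
    FBG = "FBG"              # female-biased
    UBG = "UBG"              # unbiased
    NOT_EXPRESSED = "NOT_EXPRESSED"


class MagnitudeBin(str, Enum):
    """Fold-change categories for the degree of sex bias."""

    UP_TO_2 = "<=2-fold"
    FROM_2_TO_4 = "2-4-fold"
    FROM_4_TO_6 = "4-6-fold"
    ABOVE_6 = ">6-fold"


class ThresholdMode(str, Enum):
    FDR = "FDR"
    NOMINAL_P = "NOMINAL_P"


@dataclass(frozen=True)
class ThresholdConfig:
    """Significance dialect for bias calls.

    mode
        ``FDR``: compare the BH-adjusted p-value against ``alpha``.
        ``NOMINAL_P``: compare the raw p-value against ``alpha``.
    alpha
        Significance cutoff, default 0.05.
    pseudocount
        Added to both sexes before the log2 ratio. Use 1 for count-scale
        inputs, 0 for pre-normalised expression.
    min_expression
        Genes with both sexes below this level are flagged NOT_EXPRESSED
        and excluded from all downstream totals. Default 0 (off), matching
        the main analysis; an RPKM > 1 style filter is a robustness option.
    """

    mode: ThresholdMode = ThresholdMode.FDR
    alpha: float = 0.05
    pseudocount: float = 0.0
    min_expression: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be nonnegative")


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j >= i} p_(j) * n / j over the ascending-sorted p's,
    capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1] with no missing values")
    # statsmodels implements the same step-up procedure
    return multipletests(p, method="fdr_bh")[1]


def log2_ratio(expr_male: float, expr_female: float, pseudocount: float = 0.0) -> float:
    """log2((male + pseudocount) / (female + pseudocount)).

    Returns NaN when both sexes are zero and the pseudocount is zero (the
    ratio is undefined; such genes are flagged NOT_EXPRESSED upstream).
    """
    if expr_male < 0 or expr_female < 0:
        raise ValueError("expression values must be nonnegative")
    num = expr_male + pseudocount
    den = expr_female + pseudocount
    if num == 0 and den == 0:
        return math.nan
    if num == 0:
        return -math.inf
    if den == 0:
        return math.inf
    return math.log2(num / den)


def classify(
    expr_male: float,
    expr_female: float,
    p_raw: float | None,
    p_adj: float | None,
    cfg: ThresholdConfig,
) -> tuple[BiasCall, float]:
    """Call one gene's bias class; returns (call, log2_ratio).

    A gene is significant when the p-value selected by ``cfg.mode`` is below
    ``cfg.alpha``; the call is then MBG or FBG by the sign of the log2
    male/female ratio. Significant genes with a ratio of exactly zero have
    no direction and are kept UBG (with a warning). Genes below
    ``min_expression`` in both sexes are NOT_EXPRESSED.
    """
    ratio = log2_ratio(expr_male, expr_female, cfg.pseudocount)
    if math.isnan(ratio) or (
        cfg.min_expression > 0
        and expr_male < cfg.min_expression
        and expr_female < cfg.min_expression
    ):
        return BiasCall.NOT_EXPRESSED, ratio

    if cfg.mode is ThresholdMode.FDR:
        p = p_adj
        which = "adjusted"
    else:
        p = p_raw
        which = "raw"
    if p is None or (isinstance(p, float) and math.isnan(p)):
        raise ValueError(f"{which} p-value required for mode {cfg.mode.value}")

    if p < cfg.alpha:
        if ratio > 0:
            return BiasCall.MBG, ratio
        if ratio < 0:
            return BiasCall.FBG, ratio
        logger.warning("significant gene with log2 ratio 0 kept UBG")
    return BiasCall.UBG, ratio


def classify_table(de_table: pd.DataFrame, cfg: ThresholdConfig) -> pd.DataFrame:
    """Vectorised bias classification of a per-gene DE table.

    ``de_table`` needs columns gene_id, expr_male, expr_female and p_raw
    (p_adj optional; computed by BH from p_raw when absent and mode is FDR).
    Returns a copy with p_adj, log2_ratio and call columns.
    """
    required = {"gene_id", "expr_male", "expr_female"}
    missing = required - set(de_table.columns)
    if missing:
        raise ValueError(f"DE table missing columns: {sorted(missing)}")
    out = de_table.copy()

    if cfg.mode is ThresholdMode.FDR and "p_adj" not in out.columns:
        if "p_raw" not in out.columns:
            raise ValueError("need p_raw to compute adjusted p-values")
        out["p_adj"] = bh_adjust(out["p_raw"].to_numpy())

    calls = []
    ratios = []
    for row in out.itertuples(index=False):
        call, ratio = classify(
            float(row.expr_male),
            float(row.expr_female),
            float(getattr(row, "p_raw", math.nan))
            if hasattr(row, "p_raw") else None,
            float(getattr(row, "p_adj", math.nan))
            if hasattr(row, "p_adj") else None,
            cfg,
        )
        calls.append(call.value)
        ratios.append(ratio)
    out["log2_ratio"] = ratios
    out["call"] = calls
    return out


def magnitude_bin(log2_ratio_value: float) -> MagnitudeBin:
    """Bin the absolute fold change at boundaries 2, 4 and 6 fold.

    Boundary values go to the lower bin, so a log2 ratio of exactly 1
    (2-fold) is "<=2-fold" and exactly 2 (4-fold) is "2-4-fold".
    """
    fold = 2.0 ** abs(log2_ratio_value)
    if fold <= 2.0:
        return MagnitudeBin.UP_TO_2
    if fold <= 4.0:
        return MagnitudeBin.FROM_2_TO_4
    if fold <= 6.0:
        return MagnitudeBin.FROM_4_TO_6
    return MagnitudeBin.ABOVE_6


def standin_de_test(
    counts_male: Sequence[float], counts_female: Sequence[float]
) -> float:
    """Two-sided Welch t-test on log2(count + 1); simulation-only surrogate.

    Returns 1.0 by convention when both groups are constant (zero variance
    leaves the statistic undefined). Requires >= 2 replicates per sex.
    """
    a = np.log2(np.asarray(counts_male, dtype=float) + 1.0)
    b = np.log2(np.asarray(counts_female, dtype=float) + 1.0)
    if a.size < 2 or b.size < 2:
        raise ValueError("standin_de_test needs >= 2 replicates per sex")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return 1.0
    p = stats.ttest_ind(a, b, equal_var=False).pvalue
    return float(p) if not math.isnan(p) else 1.0


def de_table_from_counts(
    counts: pd.DataFrame, metadata: pd.DataFrame
) -> pd.DataFrame:
    """Build a DE table from a count matrix using the stand-in test.

    ``counts``: genes x samples (index = gene ids). ``metadata``: one row per
    sample with columns ``sample`` and ``sex`` ("male"/"female"). Returns a
    DataFrame with gene_id, expr_male, expr_female (mean counts) and p_raw,
    computed by a vectorised Welch t-test on log2(count + 1).
    """
    meta = metadata.set_index("sample")
    missing = set(meta.index) - set(counts.columns)
    if missing:
        raise ValueError(f"metadata samples absent from count matrix: {missing}")
    male_cols = meta.index[meta["sex"] == "male"]
    female_cols = meta.index[meta["sex"] == "female"]
    if len(male_cols) < 2 or len(female_cols) < 2:
        raise ValueError("need >= 2 replicates per sex")

    m = counts[male_cols].to_numpy(dtype=float)
    f = counts[female_cols].to_numpy(dtype=float)
    res = stats.ttest_ind(np.log2(m + 1), np.log2(f + 1), axis=1, equal_var=False)
    p = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
    return pd.DataFrame(
        {
            "gene_id": counts.index.astype(str),
            "expr_male": m.mean(axis=1),
            "expr_female": f.mean(axis=1),
            "p_raw": p,
        }
    ).reset_index(drop=True)
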