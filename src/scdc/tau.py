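"""Tissue-specificity index tau from a multi-tissue expression atlas.

tau = sum_i (1 - x_i / x_max) / (N - 1) over N tissues, ranging from 0 for
a uniformly (broadly) expressed gene to 1 for a gene expressed in a single
tissue. Note that the exact formula used by published atlas analyses is not
always printed; this module pins the standard Yanai-style definition above
with unit tests, and exposes the preprocessing knobs that matter in
practice: per-gene probe collapsing, exclusion of composite structures,
averaging of replicate conditions, and an optional log2 pre-transform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "compute_tau",
    "collapse_probes",
    "prepare_tissues",
    "tau_table",
    "TAU_HOUSEKEEPING_MAX",
    "TAU_SPECIFIC_MIN",
]

# Conventional thresholds: tau < 0.4 housekeeping-like, tau > 0.7 tissue-specific.
TAU_HOUSEKEEPING_MAX = 0.4
TAU_SPECIFIC_MIN = 0.7


def compute_tau(expression: Sequence[float]) -> float:
    """tau over one gene's expression vector across >= 2 tissues.

    All-zero vectors have no defined tau and raise; callers skip such genes
    (tau_table does so with a logged count). Negative inputs (possible after
    microarray background correction) are clamped to zero.
    """
    x = np.asarray(expression, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("tau needs a 1-D vector over >= 2 tissues")
    x = np.clip(x, 0.0, None)
    xmax = x.max()
    if xmax == 0:
        raise ValueError("tau undefined for an all-zero expression vector")
    return float(np.sum(1.0 - x / xmax) / (x.size - 1))


def collapse_probes(
    atlas: pd.DataFrame, probe_map: Mapping[str, str], by: str = "mean"
) -> pd.DataFrame:
    """Collapse a probe-level atlas to gene level.

    For each gene with multiple probes, keep the probe with the highest
    hybridization intensity: by default the highest mean across tissues
    (``by="mean"``), or the highest single-tissue value (``by="max"``).
    Unmapped probes are dropped with a logged count. Returns a gene-indexed
    matrix.
    """
    if by not in ("mean", "max"):
        raise ValueError("by must be 'mean' or 'max'")
    mapped = atlas.index.to_series().map(dict(probe_map))
    n_unmapped = int(mapped.isna().sum())
    if n_unmapped:
        logger.warning("dropping %d unmapped probes", n_unmapped)
    kept = atlas[mapped.notna()]
    genes = mapped.dropna()

    score = kept.mean(axis=1) if by == "mean" else kept.max(axis=1)
    chosen = (
        pd.DataFrame({"gene": genes, "score": score})
        .groupby("gene", sort=False)["score"]
        .idxmax()
    )
    out = kept.loc[chosen]
    out.index = chosen.index
    out.index.name = "gene_id"
    return out


def prepare_tissues(
    atlas: pd.DataFrame,
    exclude: Iterable[str] = (),
    average_groups: Iterable[tuple[str, Sequence[str]]] = (),
) -> pd.DataFrame:
    """Drop composite-structure columns and average replicate conditions.

    ``exclude`` removes whole columns (e.g. composite structures such as
    "head" and "carcass" whose signal duplicates their component tissues).
    ``average_groups`` is a list of (new_name, [columns...]) pairs; each
    group is replaced by one column of arithmetic means (e.g. mated and
    virgin spermatheca). Missing names raise, listing what was not found.
    """
    exclude = list(exclude)
    average_groups = [(name, list(cols)) for name, cols in average_groups]
    wanted = set(exclude) | {c for _n, cols in average_groups for c in cols}
    missing = wanted - set(atlas.columns)
    if missing:
        raise ValueError(f"tissue columns not found: {sorted(missing)}")

    out = atlas.drop(columns=exclude)
    for name, cols in average_groups:
        mean = out[cols].mean(axis=1)
        out = out.drop(columns=cols)
        out[name] = mean
    return out


def tau_table(atlas: pd.DataFrame, log_transform: bool = False) -> pd.DataFrame:
    """Per-gene tau records from a gene-level atlas (genes x tissues).

    Columns: gene_id, tau, n_tissues_used, max_tissue, is_housekeeping
    (tau < 0.4), is_specific (tau > 0.7). Raw intensities are used by
    default; ``log_transform`` applies log2(x + 1) first, a variant some
    tau analyses prefer. All-zero genes are skipped with a logged count.
    """
    values = atlas.to_numpy(dtype=float)
    values = np.clip(values, 0.0, None)
    if log_transform:
        values = np.log2(values + 1.0)
    rows = []
    n_skipped = 0
    for gene_id, x in zip(atlas.index, values):
        if x.max() == 0:
            n_skipped += 1
            continue
        t = compute_tau(x)
        rows.append(
            {
                "gene_id": str(gene_id),
                "tau": t,
                "n_tissues_used": int(x.size),
                "max_tissue": str(atlas.columns[int(np.argmax(x))]),
                "is_housekeeping": t < TAU_HOUSEKEEPING_MAX,
                "is_specific": t > TAU_SPECIFIC_MIN,
            }
        )
    if n_skipped:
        logger.warning("skipped %d genes with all-zero expression", n_skipped)
    return pd.DataFrame(rows)
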