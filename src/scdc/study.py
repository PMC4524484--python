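"""Per-data-set analysis front end.

`TissueStudy` bundles one expression data set (a per-gene DE table, or a
raw count matrix run through the built-in stand-in test) with its gene
annotation, chromosome classes and optional DCC site sets, tissue atlas and
gene ages. `fit()` runs the full analysis chain — bias classification,
X:autosome enrichment, site-proximity statistics, magnitude bins, tau and
age joins — and returns a `StudyResults` object carrying the estimates and
their p-values, with a `summary()` table and TSV/JSON export.

    study = TissueStudy.from_counts(counts, metadata, classes, genes=genes,
                                    site_sets=[mle])
    res = study.fit(ThresholdConfig(mode=ThresholdMode.FDR, alpha=0.05,
                                    pseudocount=1))
    print(res.summary())
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .annotation import BindingSiteSet, ChromClass, GeneModel
from .dosage import mean_age
from .enrichment import (
    ClassCounts,
    class_counts,
    enrichment_table,
    significance_stars,
)
from .proximity import (
    ProximityResult,
    distances_to_nearest,
    magnitude_distance_profile,
    proximity_summary,
)
from .sexbias import ThresholdConfig, classify_table, de_table_from_counts

__all__ = ["TissueStudy", "StudyResults", "compare_results"]


class TissueStudy:
    """One expression data set plus the genomic context to analyse it in.

    Parameters
    ----------
    de_table:
        Per-gene table with gene_id, expr_male, expr_female, p_raw
        (and optionally p_adj) columns, as produced by any upstream DE
        tool or by :meth:`from_counts`.
    classes:
        gene_id -> ChromClass mapping (EXCLUDED genes are dropped from all
        tabulations).
    genes, site_sets:
        Gene models and DCC binding-site sets; required for the proximity
        analyses, optional otherwise.
    tau, ages:
        Optional gene_id -> tau and gene_id -> age-class mappings.
    """

    def __init__(
        self,
        de_table: pd.DataFrame,
        classes: Mapping[str, ChromClass],
        genes: Sequence[GeneModel] | None = None,
        site_sets: Sequence[BindingSiteSet] | None = None,
        tau: Mapping[str, float] | None = None,
        ages: Mapping[str, int] | None = None,
        name: str = "dataset",
    ) -> None:
        self.de_table = de_table
        self.classes = dict(classes)
        self.genes = list(genes) if genes is not None else None
        self.site_sets = list(site_sets) if site_sets is not None else []
        self.tau = dict(tau) if tau is not None else None
        self.ages = dict(ages) if ages is not None else None
        self.name = name

    @classmethod
    def from_counts(
        cls,
        counts: pd.DataFrame,
        metadata: pd.DataFrame,
        classes: Mapping[str, ChromClass],
        **kwargs,
    ) -> "TissueStudy":
        """Build from a genes x samples count matrix via the stand-in test."""
        return cls(de_table_from_counts(counts, metadata), classes, **kwargs)

    def fit(self, threshold: ThresholdConfig | None = None) -> "StudyResults":
        """Run classification and every downstream analysis that has inputs."""
        cfg = threshold if threshold is not None else ThresholdConfig()
        records = classify_table(self.de_table, cfg)
        counts = class_counts(records, self.classes)
        enrich = enrichment_table(counts)

        proximity: dict[str, ProximityResult] = {}
        profiles: dict[str, pd.DataFrame] = {}
        if self.genes is not None and self.site_sets:
            x_genes = [
                g
                for g in self.genes
                if self.classes.get(g.gene_id) is ChromClass.X
            ]
            expressed = set(
                records.loc[records["call"] != "NOT_EXPRESSED", "gene_id"].astype(str)
            )
            x_genes = [g for g in x_genes if g.gene_id in expressed]
            for sites in self.site_sets:
                if not x_genes or len(sites) == 0:
                    continue
                d = distances_to_nearest(x_genes, sites)
                dist = pd.DataFrame(
                    {
                        "gene_id": [g.gene_id for g in x_genes],
                        "distance_bp": d,
                    }
                )
                joined = records.merge(dist, on="gene_id", how="inner")
                proximity[sites.component] = proximity_summary(
                    joined, sites.component
                )
                profiles[sites.component] = magnitude_distance_profile(joined)

        age_summary: dict[str, tuple[float, float]] = {}
        if self.ages is not None:
            for bias_class in ("MBG", "FBG"):
                ids = records.loc[
                    (records["call"] == bias_class)
                    & records["gene_id"].astype(str).map(
                        lambda g: self.classes.get(g) is ChromClass.X
                    ),
                    "gene_id",
                ].astype(str)
                known = [g for g in ids if g in self.ages]
                if known:
                    age_summary[bias_class] = mean_age(ids, self.ages)

        tau_summary: dict[str, float] = {}
        if self.tau is not None:
            for bias_class in ("MBG", "FBG", "UBG"):
                ids = records.loc[
                    (records["call"] == bias_class)
                    & records["gene_id"].astype(str).map(
                        lambda g: self.classes.get(g) is ChromClass.X
                    ),
                    "gene_id",
                ].astype(str)
                vals = [self.tau[g] for g in ids if g in self.tau]
                if vals:
                    tau_summary[bias_class] = float(pd.Series(vals).mean())

        return StudyResults(
            name=self.name,
            threshold=cfg,
            records=records,
            counts=counts,
            enrichment=enrich,
            proximity=proximity,
            magnitude_profiles=profiles,
            mean_age_x=age_summary,
            mean_tau_x=tau_summary,
        )


@dataclass
class StudyResults:
    """Fitted per-data-set results with export and a printable summary."""

    name: str
    threshold: ThresholdConfig
    records: pd.DataFrame
    counts: ClassCounts
    enrichment: pd.DataFrame
    proximity: dict[str, ProximityResult] = field(default_factory=dict)
    magnitude_profiles: dict[str, pd.DataFrame] = field(default_factory=dict)
    mean_age_x: dict[str, tuple[float, float]] = field(default_factory=dict)
    mean_tau_x: dict[str, float] = field(default_factory=dict)

    @property
    def n_expressed(self) -> int:
        return self.counts.n_total

    def summary(self) -> str:
        """Human-readable account of the fitted data set."""
        lines = [
            f"Sex-bias analysis: {self.name}",
            f"  significance: {self.threshold.mode.value}, "
            f"alpha={self.threshold.alpha}",
            f"  expressed genes: {self.n_expressed} "
            f"({self.counts.n_x_total} X-linked, "
            f"{100 * self.counts.n_x_total / max(self.counts.n_total, 1):.1f}%)",
            "",
            "  class  n_autosome  n_X  pct_X  O/E      Fisher p",
        ]
        for _, row in self.enrichment.iterrows():
            oe = (
                f"{row['oe_ratio']:.2f}" if "oe_ratio" in row
                and pd.notna(row.get("oe_ratio")) else "   -"
            )
            pv = (
                f"{row['p_value']:.3g} {row.get('significance', '')}"
                if pd.notna(row.get("p_value")) else "-"
            )
            lines.append(
                f"  {row['class']:<5} {row['count_autosome']:>10} "
                f"{row['count_x']:>4} {row['pct_x']:>5}  {oe:>6}  {pv}"
            )
        for component, prox in self.proximity.items():
            lines.append("")
            lines.append(
                f"  {component} proximity (n={prox.n_genes} expressed X genes): "
                f"rho={prox.rho:.3f} (p={prox.rho_p:.3g}"
                f"{significance_stars(prox.rho_p)})"
            )
            med = prox.median_distance_by_class
            lines.append(
                "    median distance bp — "
                + ", ".join(f"{k}: {v:.0f}" for k, v in med.items())
                + f"; MBG vs UBG Wilcoxon p={prox.wilcoxon_p_mbg_vs_ubg:.3g}"
            )
        if self.mean_tau_x:
            lines.append("")
            lines.append(
                "  mean tau of X-linked genes — "
                + ", ".join(f"{k}: {v:.3f}" for k, v in self.mean_tau_x.items())
            )
        if self.mean_age_x:
            lines.append(
                "  mean age of X-linked genes — "
                + ", ".join(
                    f"{k}: {v[0]:.2f} (coverage {v[1]:.0%})"
                    for k, v in self.mean_age_x.items()
                )
            )
        return "\n".join(lines)

    def save(self, outdir: str | Path) -> Path:
        """Write one TSV per analysis plus a JSON manifest; returns outdir."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.records.to_csv(outdir / "sexbias_records.tsv", sep="\t", index=False)
        self.enrichment.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        stages = ["classify", "class_counts", "enrichment"]
        for component, prox in self.proximity.items():
            df = pd.DataFrame(
                [
                    {
                        "component": component,
                        "n_genes": prox.n_genes,
                        "rho": prox.rho,
                        "rho_p": prox.rho_p,
                        "wilcoxon_p_mbg_vs_ubg": prox.wilcoxon_p_mbg_vs_ubg,
                        **{
                            f"median_distance_{k.lower()}": v
                            for k, v in prox.median_distance_by_class.items()
                        },
                    }
                ]
            )
            df.to_csv(
                outdir / f"proximity_{component.lower()}.tsv", sep="\t", index=False
            )
            self.magnitude_profiles[component].to_csv(
                outdir / f"magnitude_profile_{component.lower()}.tsv",
                sep="\t",
                index=False,
            )
            stages.append(f"proximity_{component}")
        manifest = {
            "dataset": self.name,
            "threshold": {
                "mode": self.threshold.mode.value,
                "alpha": self.threshold.alpha,
                "pseudocount": self.threshold.pseudocount,
                "min_expression": self.threshold.min_expression,
            },
            "n_expressed": self.n_expressed,
            "n_dropped_unannotated": self.counts.n_dropped,
            "stages": stages,
            "config_hash": self.config_hash(),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return outdir

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "dataset": self.name,
                "mode": self.threshold.mode.value,
                "alpha": self.threshold.alpha,
                "pseudocount": self.threshold.pseudocount,
                "min_expression": self.threshold.min_expression,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def compare_results(results: Sequence[StudyResults]) -> pd.DataFrame:
    """Cross-data-set long-format table (data set x class x statistic).

    One row per data set and bias class with counts, X percentage, O/E
    ratio, Fisher p and stars, plus per-component Spearman rho where the
    proximity analysis ran — the layout the multi-panel figures use.
    """
    if len(results) < 2:
        raise ValueError("need >= 2 fitted data sets to compare")
    rows = []
    for res in results:
        for _, erow in res.enrichment.iterrows():
            row = {
                "dataset": res.name,
                "class": erow["class"],
                "count_autosome": erow["count_autosome"],
                "count_x": erow["count_x"],
                "pct_x": erow["pct_x"],
                "oe_ratio": erow.get("oe_ratio"),
                "p_value": erow.get("p_value"),
                "significance": erow.get("significance", ""),
            }
            for component, prox in res.proximity.items():
                row[f"rho_{component.lower()}"] = prox.rho
                row[f"rho_p_{component.lower()}"] = prox.rho_p
            rows.append(row)
    return pd.DataFrame(rows)
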