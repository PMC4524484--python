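"""Gene-annotation and binding-site I/O.

Parses GFF3 gene models and BED interval files into a single internal
coordinate convention (1-based, fully inclusive — the GFF convention) and
classifies chromosome arms as X, autosome, or excluded.

A *gene model* here is the transcriptional unit: the span from the minimum
start to the maximum end over all transcripts of a gene, plus the exonic
length (number of bases covered by the union of the gene's exons), which is
what RPKM normalisation needs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GeneModel",
    "ChromClass",
    "ChromConfig",
    "BindingSiteSet",
    "DCC_COMPONENTS",
    "read_gff",
    "read_bed",
    "write_bed",
    "classify_chromosome",
    "classify_genes",
    "gene_table",
    "write_gene_table",
]

DCC_COMPONENTS = ("MLE", "MSL1", "MSL2", "MSL3", "MOF", "HAS")


class ChromClass(str, Enum):
    """Chromosomal class of a gene: X-linked, autosomal, or excluded."""

    X = "X"
    AUTOSOME = "AUTOSOME"
    EXCLUDED = "EXCLUDED"


@dataclass(frozen=True)
class GeneModel:
    """Transcriptional unit of one gene (1-based inclusive coordinates)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "?"
    exonic_length: int = 0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.exonic_length < 0:
            raise ValueError(f"gene {self.gene_id}: negative exonic length")
        span = self.end - self.start + 1
        if self.exonic_length > span:
            raise ValueError(
                f"gene {self.gene_id}: exonic_length {self.exonic_length} "
                f"exceeds span {span}"
            )

    @property
    def span_length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ChromConfig:
    """Mapping from chromosome-arm names to classes.

    Defaults follow the D. melanogaster convention: arms 2L, 2R, 3L, 3R and
    chromosome 4 are autosomes, X is the X, and everything else
    (heterochromatic arms, unplaced scaffolds, the mitochondrial genome)
    is excluded from chromosomal-distribution counts.
    """

    x_names: frozenset[str] = frozenset({"X"})
    autosome_names: frozenset[str] = frozenset({"2L", "2R", "3L", "3R", "4"})
    excluded_names: frozenset[str] = frozenset()

    def __init__(
        self,
        x_names: Iterable[str] = ("X",),
        autosome_names: Iterable[str] = ("2L", "2R", "3L", "3R", "4"),
        excluded_names: Iterable[str] = (),
    ) -> None:
        object.__setattr__(self, "x_names", frozenset(x_names))
        object.__setattr__(self, "autosome_names", frozenset(autosome_names))
        object.__setattr__(self, "excluded_names", frozenset(excluded_names))
        overlap = self.x_names & self.autosome_names
        if overlap:
            raise ValueError(f"chromosomes in both X and autosome lists: {overlap}")


DEFAULT_CHROM_CONFIG = ChromConfig()


def classify_chromosome(
    chrom: str, config: ChromConfig = DEFAULT_CHROM_CONFIG
) -> ChromClass:
    """Map a chromosome-arm name to its class.

    Unknown names map to ``EXCLUDED`` with a logged warning, so unplaced
    scaffolds never silently inflate autosomal counts.
    """
    if chrom in config.x_names:
        return ChromClass.X
    if chrom in config.autosome_names:
        return ChromClass.AUTOSOME
    if chrom not in config.excluded_names:
        logger.warning("unknown chromosome %r classified as EXCLUDED", chrom)
    return ChromClass.EXCLUDED


def classify_genes(
    genes: Iterable[GeneModel], config: ChromConfig = DEFAULT_CHROM_CONFIG
) -> dict[str, ChromClass]:
    """Classify every gene's chromosome; returns gene_id -> ChromClass."""
    return {g.gene_id: classify_chromosome(g.chrom, config) for g in genes}


@dataclass
class BindingSiteSet:
    """Named set of DCC-component binding intervals (1-based inclusive).

    ``component`` is one of MLE, MSL1, MSL2, MSL3, MOF or HAS (high-affinity
    sites, derived from MLE/MSL2 colocalization). Intervals are kept sorted
    by (chrom, start).
    """

    component: str
    intervals: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.component not in DCC_COMPONENTS:
            raise ValueError(
                f"unknown DCC component {self.component!r}; "
                f"expected one of {DCC_COMPONENTS}"
            )
        for chrom, start, end in self.intervals:
            if start > end:
                raise ValueError(
                    f"{self.component} interval {chrom}:{start}-{end}: start > end"
                )
        self.intervals = sorted(self.intervals)

    def on_chrom(self, chrom: str) -> list[tuple[int, int]]:
        return [(s, e) for c, s, e in self.intervals if c == chrom]

    def __len__(self) -> int:
        return len(self.intervals)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


class GffParseError(ValueError):
    pass


def _parse_attributes(attr_field: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for chunk in attr_field.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" not in chunk:
            continue
        key, value = chunk.split("=", 1)
        out[key.strip()] = value.strip()
    return out


def _merged_length(intervals: Sequence[tuple[int, int]]) -> int:
    """Total bases covered by the union of 1-based inclusive intervals."""
    if not intervals:
        return 0
    ivs = sorted(intervals)
    total = 0
    cur_s, cur_e = ivs[0]
    for s, e in ivs[1:]:
        if s <= cur_e + 1:
            cur_e = max(cur_e, e)
        else:
            total += cur_e - cur_s + 1
            cur_s, cur_e = s, e
    total += cur_e - cur_s + 1
    return total


def read_gff(path: str | Path) -> list[GeneModel]:
    """Parse a GFF3 file into one :class:`GeneModel` per gene.

    The span of a gene is the union of its transcripts' spans; the exonic
    length is the number of bases covered by the union of all its exons
    (across transcripts). Genes with no exon features fall back to the span
    length with a logged warning.

    Raises :class:`GffParseError` naming the offending line on malformed
    input.
    """
    genes: dict[str, dict] = {}
    transcript_parent: dict[str, str] = {}
    # exon intervals keyed by gene id (resolved via transcript parents)
    pending_exons: list[tuple[str, int, int, int]] = []  # parent, start, end, lineno

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GffParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, _source, ftype, start_s, end_s, _score, strand, _frame, attrs = fields
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise GffParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if start > end:
                raise GffParseError(f"{path}: line {lineno}: start > end")
            attributes = _parse_attributes(attrs)
            if ftype == "gene":
                gid = attributes.get("ID")
                if gid is None:
                    raise GffParseError(
                        f"{path}: line {lineno}: gene feature without ID"
                    )
                genes[gid] = {
                    "chrom": chrom,
                    "strand": strand if strand in "+-" else "?",
                    "starts": [start],
                    "ends": [end],
                    "exons": [],
                }
            elif ftype in ("mRNA", "transcript", "ncRNA", "tRNA", "rRNA", "snoRNA",
                           "snRNA", "pseudogene", "miRNA", "pre_miRNA"):
                tid = attributes.get("ID")
                parent = attributes.get("Parent")
                if tid is None or parent is None:
                    raise GffParseError(
                        f"{path}: line {lineno}: transcript without ID/Parent"
                    )
                transcript_parent[tid] = parent
                if parent in genes:
                    genes[parent]["starts"].append(start)
                    genes[parent]["ends"].append(end)
            elif ftype == "exon":
                parent = attributes.get("Parent")
                if parent is None:
                    raise GffParseError(
                        f"{path}: line {lineno}: exon without Parent"
                    )
                for p in parent.split(","):
                    pending_exons.append((p, start, end, lineno))

    for parent, start, end, lineno in pending_exons:
        gid = transcript_parent.get(parent, parent)
        if gid not in genes:
            logger.warning(
                "exon at line %d references unknown parent %r; skipped", lineno, parent
            )
            continue
        genes[gid]["exons"].append((start, end))

    models: list[GeneModel] = []
    for gid, info in genes.items():
        span_start = min(info["starts"])
        span_end = max(info["ends"])
        if info["exons"]:
            exonic = _merged_length(info["exons"])
        else:
            exonic = span_end - span_start + 1
            logger.warning(
                "gene %s has no exon features; exonic_length set to span length", gid
            )
        models.append(
            GeneModel(
                gene_id=gid,
                chrom=info["chrom"],
                start=span_start,
                end=span_end,
                strand=info["strand"],
                exonic_length=exonic,
            )
        )
    return models


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """Read a BED3+ file into internal 1-based inclusive intervals.

    BED is 0-based half-open, so a line ``X 0 100`` becomes ``(X, 1, 100)``.
    Lines with start >= end are rejected (zero-length BED features have no
    1-based inclusive representation).
    """
    intervals: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: BED needs >= 3 columns"
                )
            chrom = fields[0]
            try:
                start0, end0 = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if start0 >= end0:
                raise ValueError(
                    f"{path}: line {lineno}: start {start0} >= end {end0}"
                )
            intervals.append((chrom, start0 + 1, end0))
    return intervals


def write_bed(intervals: Iterable[tuple[str, int, int]], path: str | Path) -> None:
    """Write internal 1-based inclusive intervals as BED3 (0-based half-open)."""
    with open(path, "w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start - 1}\t{end}\n")


# ---------------------------------------------------------------------------
# Tabular export
# ---------------------------------------------------------------------------


def gene_table(
    genes: Sequence[GeneModel], config: ChromConfig = DEFAULT_CHROM_CONFIG
) -> pd.DataFrame:
    """Parsed-gene table: gene_id, chrom, class, start, end, exonic_length."""
    return pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chrom": [g.chrom for g in genes],
            "chrom_class": [classify_chromosome(g.chrom, config).value for g in genes],
            "start": [g.start for g in genes],
            "end": [g.end for g in genes],
            "exonic_length": [g.exonic_length for g in genes],
        }
    )


def write_gene_table(
    genes: Sequence[GeneModel],
    path: str | Path,
    config: ChromConfig = DEFAULT_CHROM_CONFIG,
) -> None:
    gene_table(genes, config).to_csv(path, sep="\t", index=False)
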