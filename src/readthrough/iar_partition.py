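"""Annotation parsing and partitioning of the genome into isolated active regions.

An isolated active region (IAR) is a maximal run of consecutively ordered
genes in which every inter-gene gap is at most ``thr`` base pairs; IARs are
separated by gene deserts longer than ``thr``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

#: Default gap threshold (bp) separating isolated active regions.
DEFAULT_THR = 100_000


class GTFParseError(ValueError):
    """Raised for a malformed GTF line; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


@dataclass
class GeneRecord:
    """One annotated gene.

    Coordinates are 1-based inclusive genomic positions. ``exons`` is the
    per-gene union of exon intervals across transcripts, sorted and
    non-overlapping. ``cds`` is the (start, end) span of the canonical
    (longest-CDS) transcript's CDS features, or ``None``.
    """

    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: tuple[int, int] | None = None

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def validate(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")
        prev_end = None
        for s, e in self.exons:
            if s > e or s < self.start or e > self.end:
                raise ValueError(f"{self.gene_id}: exon ({s},{e}) outside gene span")
            if prev_end is not None and s <= prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or are unsorted")
            prev_end = e


@dataclass
class IsolatedActiveRegion:
    """A maximal run of genes whose consecutive gaps are all <= thr."""

    iar_id: int
    chrom: str
    genes: list[GeneRecord]

    @property
    def span(self) -> tuple[int, int]:
        return min(g.start for g in self.genes), max(g.end for g in self.genes)

    @property
    def n_genes(self) -> int:
        return len(self.genes)


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of 1-based inclusive intervals, sorted and non-overlapping.

    Intervals that touch (end + 1 == next start) are merged as well, so the
    result is the minimal set covering exactly the union of base positions.
    """
    ivs = sorted(intervals)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _parse_attributes(attr_field: str, line_number: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in attr_field.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        parts = chunk.split(None, 1)
        if len(parts) != 2:
            raise GTFParseError(f"malformed attribute {chunk!r}", line_number)
        key, value = parts
        attrs[key] = value.strip().strip('"')
    return attrs


def parse_annotation(gtf_path: str, feature_policy: dict | None = None) -> list[GeneRecord]:
    """Parse a GTF file into one :class:`GeneRecord` per ``gene_id``.

    Exons are merged per gene across transcripts (default policy: union of
    exon intervals). The CDS span is the min/max over CDS features of the
    canonical transcript, chosen as the transcript with the longest total
    CDS. Genes that annotate no exon get a single exon equal to the gene
    span (with a warning). Coordinates stay 1-based inclusive.
    """
    feature_policy = feature_policy or {}
    spans: dict[str, list] = {}  # gene_id -> [chrom, strand, start, end, name]
    exons: dict[str, list[tuple[int, int]]] = {}
    cds_by_tx: dict[str, dict[str, list[tuple[int, int]]]] = {}

    with open(gtf_path) as fh:
        for line_number, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise GTFParseError(
                    f"expected 9 tab-separated fields, got {len(fields)}", line_number
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attr_field = fields
            if feature not in ("gene", "exon", "CDS"):
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise GTFParseError(f"non-integer coordinates {start_s!r}/{end_s!r}", line_number)
            if start > end:
                raise GTFParseError(f"start {start} > end {end}", line_number)
            attrs = _parse_attributes(attr_field, line_number)
            gene_id = attrs.get("gene_id")
            if gene_id is None:
                raise GTFParseError("missing gene_id attribute", line_number)
            name = attrs.get("gene_name", gene_id)
            if feature == "gene":
                spans[gene_id] = [chrom, strand, start, end, name]
            else:
                if gene_id not in spans:
                    spans[gene_id] = [chrom, strand, start, end, name]
                else:
                    spans[gene_id][2] = min(spans[gene_id][2], start)
                    spans[gene_id][3] = max(spans[gene_id][3], end)
                if feature == "exon":
                    exons.setdefault(gene_id, []).append((start, end))
                else:  # CDS
                    tx = attrs.get("transcript_id", "")
                    cds_by_tx.setdefault(gene_id, {}).setdefault(tx, []).append((start, end))

    records: list[GeneRecord] = []
    for gene_id, (chrom, strand, start, end, name) in spans.items():
        gene_exons = merge_intervals(exons.get(gene_id, []))
        if not gene_exons:
            logger.warning("gene %s has no exon features; using gene span", gene_id)
            gene_exons = [(start, end)]
        cds_span = None
        if gene_id in cds_by_tx:
            # canonical transcript = longest total CDS
            best_tx = max(
                cds_by_tx[gene_id].items(),
                key=lambda kv: (sum(e - s + 1 for s, e in kv[1]), kv[0]),
            )[1]
            cds_span = (min(s for s, _ in best_tx), max(e for _, e in best_tx))
        rec = GeneRecord(
            gene_id=gene_id,
            gene_name=name,
            chrom=chrom,
            strand=strand,
            start=start,
            end=end,
            exons=gene_exons,
            cds=cds_span,
        )
        rec.validate()
        records.append(rec)
    records.sort(key=lambda g: (g.chrom, g.start, g.end, g.gene_id))
    return records


def partition_iars(genes: Sequence[GeneRecord], thr: int = DEFAULT_THR) -> list[IsolatedActiveRegion]:
    """Split genes into isolated active regions.

    Genes are ordered by (chrom, genomic start); a new region begins whenever
    ``start[i+1] - end[i] > thr`` or the chromosome changes. Overlapping
    genes (negative gap) always share a region. Partitioning is strand-blind.
    """
    if thr <= 0:
        raise ValueError("thr must be positive")
    ordered = sorted(genes, key=lambda g: (g.chrom, g.start, g.end, g.gene_id))
    iars: list[IsolatedActiveRegion] = []
    current: list[GeneRecord] = []
    for gene in ordered:
        if current:
            prev = current[-1]
            gap = gene.start - prev.end
            if gene.chrom == prev.chrom and gap <= thr:
                if gap < 0:
                    logger.debug("genes %s and %s overlap (gap %d)", prev.gene_id, gene.gene_id, gap)
                current.append(gene)
                continue
            iars.append(IsolatedActiveRegion(iar_id=len(iars), chrom=current[0].chrom, genes=current))
            current = []
        current.append(gene)
    if current:
        iars.append(IsolatedActiveRegion(iar_id=len(iars), chrom=current[0].chrom, genes=current))
    return iars


def iars_to_bed(iars: Sequence[IsolatedActiveRegion]) -> str:
    """Render IARs as BED (0-based half-open), one row per region."""
    lines = []
    for iar in iars:
        start, end = iar.span
        lines.append(f"{iar.chrom}\t{start - 1}\t{end}\tIAR{iar.iar_id}\t{iar.n_genes}\t.")
    return "\n".join(lines) + ("\n" if lines else "")
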