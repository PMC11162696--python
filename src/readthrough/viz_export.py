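"""Splice-pattern export: align read/consensus sequences over the
upstream-TSS to downstream-TTS window, emit BED12 block structures, and draw
a minimal exon-block figure."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from Bio import Align

from readthrough.detect import ReadThroughCall
from readthrough.iar_partition import GeneRecord
from readthrough.index import fetch_sequence

logger = logging.getLogger(__name__)

DEFAULT_MIN_INTRON = 30
MIN_LOCAL_SCORE = 40.0


# --- coordinate conventions ------------------------------------------------
# GTF is 1-based inclusive; BED is 0-based half-open. All conversions go
# through these two functions.


def gtf_to_bed(start: int, end: int) -> tuple[int, int]:
    if start < 1 or end < start:
        raise ValueError(f"invalid 1-based interval ({start}, {end})")
    return start - 1, end


def bed_to_gtf(start: int, end: int) -> tuple[int, int]:
    if start < 0 or end <= start:
        raise ValueError(f"invalid 0-based half-open interval ({start}, {end})")
    return start + 1, end


@dataclass
class SplicePattern:
    chrom: str
    region_start: int  # 0-based half-open region bounds
    region_end: int
    name: str
    strand: str
    blocks: list[tuple[int, int]]  # (genomic bed start, size), sorted


def extract_region(
    call: ReadThroughCall, genome, chrom_length: int | None = None
) -> tuple[str, int, int, str, str]:
    """Window from the upstream TSS to the downstream TTS.

    Returns (chrom, bed_start, bed_end, strand, sequence); coordinates are
    genomic regardless of strand. Out-of-bounds windows are clamped.
    """
    u, d = call.upstream_gene, call.downstream_gene
    if u.chrom != d.chrom:
        raise ValueError("read-through genes must share a chromosome")
    start = min(u.start, d.start)
    end = max(u.end, d.end)
    bed_start, bed_end = gtf_to_bed(start, end)
    if chrom_length is not None and bed_end > chrom_length:
        logger.warning("region clipped to chromosome end (%d > %d)", bed_end, chrom_length)
        bed_end = chrom_length
    if bed_start < 0:
        bed_start = 0
    seq = fetch_sequence(genome, u.chrom, bed_start + 1, bed_end)
    return u.chrom, bed_start, bed_end, u.strand, seq


def _splice_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = 2
    a.mismatch_score = -4
    # skipped reference bases (introns) stay cheap per-base; read insertions do not
    a.open_internal_deletion_score = -8
    a.extend_internal_deletion_score = -0.05
    a.open_internal_insertion_score = -6
    a.extend_internal_insertion_score = -1
    return a


_SPLICE = _splice_aligner()


def align_and_bed(
    seq: str,
    region_seq: str,
    chrom: str,
    region_start: int,
    name: str,
    strand: str = "+",
    min_intron: int = DEFAULT_MIN_INTRON,
) -> str | None:
    """Splice-tolerant local alignment of ``seq`` to the region -> BED12 line.

    Gaps in the reference of at least ``min_intron`` bp become introns
    (block boundaries); smaller gaps are absorbed into blocks. Returns None
    when no alignment clears the score floor.
    """
    if not seq:
        raise ValueError("empty sequence")
    aln = _SPLICE.align(region_seq, seq)[0]
    if aln.score < MIN_LOCAL_SCORE:
        logger.warning("alignment of %s below score floor; skipped", name)
        return None
    t_blocks = aln.aligned[0]
    if len(t_blocks) == 0:
        return None
    merged: list[list[int]] = [[int(t_blocks[0][0]), int(t_blocks[0][1])]]
    for ts, te in t_blocks[1:]:
        if int(ts) - merged[-1][1] < min_intron:
            merged[-1][1] = int(te)
        else:
            merged.append([int(ts), int(te)])
    blocks = [(region_start + ts, te - ts) for ts, te in merged]
    chrom_start = blocks[0][0]
    chrom_end = blocks[-1][0] + blocks[-1][1]
    return bed12_line(chrom, chrom_start, chrom_end, name, int(aln.score), strand, blocks)


def bed12_line(
    chrom: str,
    chrom_start: int,
    chrom_end: int,
    name: str,
    score: int,
    strand: str,
    blocks: Sequence[tuple[int, int]],
) -> str:
    """Format a BED12 record from genomic (start, size) blocks."""
    sizes = ",".join(str(size) for _, size in blocks) + ","
    starts = ",".join(str(s - chrom_start) for s, _ in blocks) + ","
    return "\t".join(
        [
            chrom,
            str(chrom_start),
            str(chrom_end),
            name,
            str(min(score, 1000)),
            strand,
            str(chrom_start),
            str(chrom_end),
            "0",
            str(len(blocks)),
            sizes,
            starts,
        ]
    )


def parse_bed12(line: str) -> SplicePattern:
    fields = line.rstrip("\n").split("\t")
    if len(fields) != 12:
        raise ValueError(f"expected 12 BED fields, got {len(fields)}")
    chrom, start_s, end_s, name, _score, strand = fields[:6]
    start, end = int(start_s), int(end_s)
    n_blocks = int(fields[9])
    sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
    offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
    if len(sizes) != n_blocks or len(offsets) != n_blocks:
        raise ValueError("blockCount disagrees with blockSizes/blockStarts")
    blocks = [(start + off, size) for off, size in zip(offsets, sizes)]
    return SplicePattern(chrom, start, end, name, strand, blocks)


def gene_model_blocks(gene: GeneRecord) -> list[tuple[int, int]]:
    return [(s - 1, e - s + 1) for s, e in gene.exons]


def render(
    patterns: Sequence[SplicePattern],
    genes: Sequence[GeneRecord],
    out_path: str,
) -> None:
    """Minimal exon-block figure: one track per pattern plus gene models."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not patterns:
        raise ValueError("nothing to render")
    fig, ax = plt.subplots(figsize=(10, 1 + 0.4 * (len(patterns) + len(genes))))
    y = 0
    for gene in genes:
        for s, size in gene_model_blocks(gene):
            ax.add_patch(plt.Rectangle((s, y - 0.3), size, 0.6, color="#444444"))
        ax.plot([gene.start - 1, gene.end], [y, y], color="#444444", lw=0.8)
        ax.text(gene.start - 1, y + 0.35, f"{gene.gene_name} ({gene.strand})", fontsize=7)
        y += 1
    for pat in patterns:
        for s, size in pat.blocks:
            ax.add_patch(plt.Rectangle((s, y - 0.3), size, 0.6, color="#1f77b4"))
        if pat.blocks:
            ax.plot(
                [pat.blocks[0][0], pat.blocks[-1][0] + pat.blocks[-1][1]],
                [y, y],
                color="#1f77b4",
                lw=0.8,
            )
        ax.text(pat.region_start, y + 0.35, pat.name, fontsize=7)
        y += 1
    ax.set_ylim(-1, y)
    lo = min(p.region_start for p in patterns)
    hi = max(p.region_end for p in patterns)
    ax.set_xlim(lo - 100, hi + 100)
    ax.set_yticks([])
    ax.set_xlabel("genomic position (bp)")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
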