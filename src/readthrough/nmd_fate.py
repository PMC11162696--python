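"""Fate prediction for called read-throughs: recover the intergenic insert
from supporting reads, build a majority-vote consensus, and classify the
fused transcript as NMD-prone or protein-coding with the 55-nt
exon-junction rule (a premature stop within 55 nt of the last exon-exon
junction escapes decay; the boundary is inclusive)."""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

from Bio import Align

from readthrough.detect import ReadThroughCall
from readthrough.iar_partition import GeneRecord
from readthrough.index import fetch_sequence
from readthrough.sketch import reverse_complement

logger = logging.getLogger(__name__)

NMD_RULE_NT = 55
STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass
class FateResult:
    call: ReadThroughCall | None
    consensus_insert: str
    ptc_found: bool
    stop_codon: str | None
    distance_to_last_junction: int | None
    classification: str  # NMD | protein_coding | indeterminate
    no_valid_stop: bool = False


def _edit_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 0
    a.mismatch_score = -1
    a.open_gap_score = -1
    a.extend_gap_score = -1
    return a


_EDIT = _edit_aligner()

_PREFIX = _edit_aligner()
# free trailing deletions: the exon may align to a prefix of the read window
_PREFIX.open_right_deletion_score = 0
_PREFIX.extend_right_deletion_score = 0

_STAR = Align.PairwiseAligner()
_STAR.mode = "global"
_STAR.match_score = 2
_STAR.mismatch_score = -1
_STAR.open_gap_score = -2
_STAR.extend_gap_score = -0.5


def edit_distance(a: str, b: str) -> int:
    """Levenshtein distance via a unit-cost global alignment."""
    if not a or not b:
        return max(len(a), len(b))
    return int(-_EDIT.score(a, b))


def anchor_band(segment_len: int) -> int:
    return max(20, int(0.2 * segment_len))


def _match_prefix(exon_seq: str, read: str, cursor: int) -> tuple[bool, int, int]:
    """Match one exon against the read starting at ``cursor``.

    Returns (matched, new_cursor, distance): a banded edit-distance match of
    the exon to a prefix of the local read window.
    """
    band = anchor_band(len(exon_seq))
    window = read[cursor : cursor + len(exon_seq) + band]
    if not window:
        return False, cursor, len(exon_seq)
    aln = _PREFIX.align(window, exon_seq)[0]
    dist = int(-aln.score)
    if dist > band:
        return False, cursor, dist
    blocks = aln.aligned[0]
    end = int(blocks[-1][1]) if len(blocks) else 0
    return True, cursor + end, dist


def gene_spliced_seq(genome, gene: GeneRecord) -> tuple[list[str], str]:
    """Per-exon sequences in transcription order (5'->3') and their concat."""
    exon_seqs = [fetch_sequence(genome, gene.chrom, s, e) for s, e in gene.exons]
    if gene.strand == "-":
        exon_seqs = [reverse_complement(s) for s in exon_seqs[::-1]]
    return exon_seqs, "".join(exon_seqs)


def spliced_cds_start(gene: GeneRecord) -> int | None:
    """0-based position of the CDS 5' start in the spliced transcript."""
    if gene.cds is None:
        return None
    pos5 = gene.cds[0] if gene.strand == "+" else gene.cds[1]
    exons = gene.exons if gene.strand == "+" else gene.exons[::-1]
    spliced = 0
    for s, e in exons:
        if s <= pos5 <= e:
            return spliced + (pos5 - s if gene.strand == "+" else e - pos5)
        spliced += e - s + 1
    return None


@dataclass
class AnchorResult:
    segments: list[str]  # intergenic insert candidate per anchored read
    boundary_exon: int  # last fully matched upstream exon (mode over reads)
    first_down_exon: int  # first matched downstream exon (mode over reads)
    n_failed: int


def anchor_reads(
    reads: Sequence[tuple[str, str]],
    upstream: GeneRecord,
    downstream: GeneRecord,
    genome,
) -> AnchorResult:
    """Anchor supporting reads to the upstream gene model exon by exon.

    Each read is oriented to the gene strand, its prefix matched exon-by-exon
    (banded edit distance) against the upstream spliced transcript until the
    boundary exon, and symmetrically from its 3' end against the downstream
    exons; the unexplained middle is the intergenic insert candidate.
    Reads that fail to anchor the first upstream exon are excluded.
    """
    u_exons, _ = gene_spliced_seq(genome, upstream)
    d_exons, _ = gene_spliced_seq(genome, downstream)
    per_read: list[tuple[str, int, int]] = []
    n_failed = 0
    for _rid, seq in reads:
        rc = reverse_complement(seq)
        ok_f, _, dist_f = _match_prefix(u_exons[0], seq, 0)
        ok_r, _, dist_r = _match_prefix(u_exons[0], rc, 0)
        if not ok_f and not ok_r:
            n_failed += 1
            continue
        read = seq if (ok_f and (not ok_r or dist_f <= dist_r)) else rc

        cursor = 0
        boundary = -1
        for i, ex in enumerate(u_exons):
            ok, cursor2, _ = _match_prefix(ex, read, cursor)
            if not ok:
                break
            cursor, boundary = cursor2, i
        if boundary < 0:
            n_failed += 1
            continue

        rev = read[::-1]
        back_cursor = 0
        first_down = len(d_exons)
        for j in range(len(d_exons) - 1, -1, -1):
            ok, back_cursor2, _ = _match_prefix(d_exons[j][::-1], rev, back_cursor)
            if not ok:
                break
            back_cursor, first_down = back_cursor2, j
        if first_down == len(d_exons):
            n_failed += 1
            continue
        down_start = len(read) - back_cursor
        segment = read[cursor:down_start] if down_start > cursor else ""
        per_read.append((segment, boundary, first_down))

    if not per_read:
        return AnchorResult([], len(u_exons) - 1, 0, n_failed)
    boundary = Counter(b for _, b, _ in per_read).most_common(1)[0][0]
    first_down = Counter(f for _, _, f in per_read).most_common(1)[0][0]
    segments = [s for s, b, f in per_read if b == boundary and f == first_down]
    return AnchorResult(segments, boundary, first_down, n_failed)


def consensus_insert(segments: Sequence[str], max_medoid: int = 20) -> str:
    """Star-alignment consensus of the insert segments.

    The medoid segment (minimum total edit distance to the others, sampled
    down to ``max_medoid`` candidates for large pile-ups) is the backbone;
    every other segment is globally aligned to it and a per-column majority
    vote (ties toward the backbone base) yields the consensus. A single
    segment is returned unchanged.
    """
    segs = [s for s in segments]
    if not segs:
        raise ValueError("consensus_insert requires at least one segment")
    if len(segs) == 1:
        return segs[0]
    nonempty = [s for s in segs if s]
    if not nonempty:
        return ""
    if len(segs) - len(nonempty) > len(segs) // 2:
        return ""  # majority of reads saw no insert
    segs = nonempty

    pool = segs if len(segs) <= max_medoid else segs[:: max(1, len(segs) // max_medoid)][:max_medoid]
    totals = [sum(edit_distance(a, b) for b in pool) for a in pool]
    backbone = pool[int(min(range(len(pool)), key=lambda i: totals[i]))]

    n = len(backbone)
    base_votes = [Counter() for _ in range(n)]
    ins_votes: dict[int, Counter] = {}
    n_aligned = 0
    for seg in segs:
        if seg == backbone:
            for i, b in enumerate(backbone):
                base_votes[i][b] += 1
            n_aligned += 1
            continue
        aln = _STAR.align(backbone, seg)[0]
        t_blocks, q_blocks = aln.aligned
        prev_t_end, prev_q_end = 0, 0
        for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
            for p in range(prev_t_end, ts):  # deletion in segment
                base_votes[p]["-"] += 1
            if qs > prev_q_end and ts > 0:  # insertion before this block
                ins_votes.setdefault(ts, Counter())[seg[prev_q_end:qs]] += 1
            for p, q in zip(range(ts, te), range(qs, qe)):
                base_votes[p][seg[q]] += 1
            prev_t_end, prev_q_end = te, qe
        for p in range(prev_t_end, n):
            base_votes[p]["-"] += 1
        n_aligned += 1

    out: list[str] = []
    for i in range(n):
        if i in ins_votes:
            ins_string, count = ins_votes[i].most_common(1)[0]
            if count > n_aligned / 2:
                out.append(ins_string)
        votes = base_votes[i]
        if not votes:
            out.append(backbone[i])
            continue
        top = max(votes.values())
        winners = {b for b, c in votes.items() if c == top}
        pick = backbone[i] if backbone[i] in winners else sorted(winners)[0]
        if pick != "-":
            out.append(pick)
    return "".join(out)


def classify_fate(
    call: ReadThroughCall | None,
    consensus: str,
    upstream: GeneRecord,
    downstream: GeneRecord,
    genome,
    boundary_exon: int | None = None,
    first_down_exon: int = 0,
) -> FateResult:
    """Apply the 55-nt rule to the fused transcript model.

    The model is upstream exons through the boundary exon, then the
    consensus insert, then downstream exons from ``first_down_exon``.
    Translation starts at the upstream CDS start; the first in-frame stop
    at/after the boundary exon is the candidate PTC. Distance is measured
    from the last base of the stop codon to the last exon-exon junction of
    the fused model (positive = PTC upstream of the junction); a distance
    > 55 nt means NMD, <= 55 nt (inclusive) or no PTC means protein-coding.
    """
    u_exons, _ = gene_spliced_seq(genome, upstream)
    d_exons, _ = gene_spliced_seq(genome, downstream)
    if boundary_exon is None:
        boundary_exon = len(u_exons) - 1
    cds_start = spliced_cds_start(upstream)
    if cds_start is None:
        return FateResult(call, consensus, False, None, None, "indeterminate")

    u_part = u_exons[: boundary_exon + 1]
    d_part = d_exons[first_down_exon:]
    fused = "".join(u_part) + consensus + "".join(d_part)
    boundary_start = sum(len(e) for e in u_part[:-1])
    if cds_start >= len(fused) or not d_part:
        return FateResult(call, consensus, False, None, None, "indeterminate")
    last_junction = len(fused) - len(d_part[-1])

    stop_codon = None
    ptc_end = None
    for pos in range(cds_start, len(fused) - 2, 3):
        codon = fused[pos : pos + 3]
        if codon in STOP_CODONS and pos >= boundary_start:
            stop_codon = codon
            ptc_end = pos + 3
            break
    if stop_codon is None:
        return FateResult(call, consensus, False, None, None, "protein_coding", no_valid_stop=True)
    distance = last_junction - ptc_end
    classification = "NMD" if distance > NMD_RULE_NT else "protein_coding"
    return FateResult(call, consensus, True, stop_codon, distance, classification)


def predict_fate(
    call: ReadThroughCall,
    reads_by_id: dict[str, str],
    genome,
) -> FateResult:
    """anchor -> consensus -> classify for one call's supporting reads."""
    reads = [(rid, reads_by_id[rid]) for rid in call.supporting_reads if rid in reads_by_id]
    upstream, downstream = call.upstream_gene, call.downstream_gene
    anchored = anchor_reads(reads, upstream, downstream, genome)
    if anchored.segments:
        consensus = consensus_insert(anchored.segments)
    else:
        consensus = ""
        logger.warning(
            "no read anchored for %s-%s (%d failures); classifying with empty insert",
            upstream.gene_id,
            downstream.gene_id,
            anchored.n_failed,
        )
    return classify_fate(
        call,
        consensus,
        upstream,
        downstream,
        genome,
        boundary_exon=anchored.boundary_exon,
        first_down_exon=anchored.first_down_exon,
    )
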