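"""Two-stage read classification: screen reads against IAR indexes, then
confirm that their minimizer hits come from two transcriptionally adjacent
genes in the right order, aggregate per gene pair, and filter by support."""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from readthrough.iar_partition import GeneRecord, IsolatedActiveRegion
from readthrough.index import IARIndex
from readthrough.sketch import SketchParams, sketch_read

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DetectParams:
    """Thresholds of the screen/confirm stages (all CLI-overridable)."""

    screen_min_hits: int = 3
    per_gene_min_hits: int = 2
    order_frac: float = 0.75
    mono_frac: float = 0.75
    min_support: int = 1
    rep_max: int = 16
    allow_opposite_strand: bool = False


@dataclass
class ReadEvidence:
    """Minimizer hits of one read inside one IAR, on its best orientation."""

    read_id: str
    iar_id: int
    per_gene_hits: dict[int, int]
    hit_positions: list[tuple[int, int, int, str]]  # (read_off, gene_ord, gene_off, strand)
    strand_call: str
    total_hits: int = 0


@dataclass
class ReadThroughCall:
    upstream_gene: GeneRecord
    downstream_gene: GeneRecord
    supporting_reads: list[str]
    upstream_hits: int
    downstream_hits: int
    breakpoint_read_offset: float
    strand: str = "+"

    @property
    def n_supporting_reads(self) -> int:
        return len(self.supporting_reads)


class Metrics(NamedTuple):
    recall: float | None
    precision: float | None
    f1: float | None


def screen_read(
    read_sketch: Sequence[tuple[int, int, str]],
    indexes: Sequence[IARIndex],
    screen_min_hits: int = 3,
    rep_max: int = 16,
) -> list[ReadEvidence]:
    """Count read-minimizer hits per IAR and keep promising candidates.

    For each IAR the orientation with more hits wins; IARs whose total hit
    count reaches ``screen_min_hits`` are returned, best first. Hashes
    matching more than ``rep_max`` postings within an IAR are treated as
    repetitive and excluded from the recorded hit positions (they still
    count toward the screening total).
    """
    by_strand: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    sk = list(read_sketch)
    for strand in "+-":
        entries = [(h, off) for h, off, s in sk if s == strand]
        hashes = np.array([h for h, _ in entries], dtype=np.uint64)
        offs = np.array([off for _, off in entries], dtype=np.int64)
        by_strand[strand] = (hashes, offs)

    candidates: list[ReadEvidence] = []
    for index in indexes:
        best: ReadEvidence | None = None
        for strand in "+-":
            hashes, offs = by_strand[strand]
            qi, genes, goffs = index.query_batch(hashes)
            if qi.size == 0:
                continue
            # hits counted once per matched read minimizer
            matched = np.unique(qi)
            total = int(matched.size)
            if total < screen_min_hits:
                continue
            postings_per_hash = Counter(qi.tolist())
            keep = np.array([postings_per_hash[int(i)] <= rep_max for i in qi], dtype=bool)
            positions = [
                (int(offs[i]), int(g), int(o), strand)
                for i, g, o in zip(qi[keep], genes[keep], goffs[keep])
            ]
            per_gene = Counter(g for _, g, _, _ in positions)
            ev = ReadEvidence(
                read_id="",
                iar_id=index.iar_id,
                per_gene_hits=dict(per_gene),
                hit_positions=positions,
                strand_call=strand,
                total_hits=total,
            )
            if best is None or ev.total_hits > best.total_hits:
                best = ev
        if best is not None:
            candidates.append(best)
    candidates.sort(key=lambda e: (-e.total_hits, e.iar_id))
    return candidates


def _concordant_fraction(read_offs: np.ndarray, gene_offs: np.ndarray) -> float:
    """Fraction of strictly co-monotone hit pairs within one gene (ties excluded)."""
    if read_offs.size < 2:
        return 1.0
    dr = read_offs[:, None] - read_offs[None, :]
    dg = gene_offs[:, None] - gene_offs[None, :]
    upper = np.triu_indices(read_offs.size, k=1)
    prod = dr[upper] * dg[upper]
    informative = prod != 0
    if not informative.any():
        return 1.0
    return float((prod[informative] > 0).mean())


def confirm_readthrough(
    evidence: ReadEvidence,
    iar: IsolatedActiveRegion,
    params: DetectParams = DetectParams(),
) -> tuple[int, int, float] | None:
    """Confirm that the read's hits span two adjacent same-strand genes.

    Returns (upstream ordinal, downstream ordinal, transition read offset)
    or None. Upstream/downstream follow transcription order: for a
    minus-strand pair the genomically-right gene is upstream.
    """
    hits = evidence.hit_positions
    by_gene: dict[int, list[tuple[int, int]]] = defaultdict(list)
    for read_off, gene_ord, gene_off, _ in hits:
        by_gene[gene_ord].append((read_off, gene_off))

    eligible = {g for g, n in evidence.per_gene_hits.items() if n >= params.per_gene_min_hits}
    passing: list[tuple[int, int, int, float]] = []  # (min_hits, -u_ord, u, d, transition)
    for i in sorted(eligible):
        j = i + 1
        if j not in eligible:
            continue
        gi, gj = iar.genes[i], iar.genes[j]
        if gi.strand != gj.strand and not params.allow_opposite_strand:
            continue
        strand = gi.strand
        u, d = (i, j) if strand == "+" else (j, i)
        u_hits = np.array(sorted(by_gene[u]), dtype=np.int64)
        d_hits = np.array(sorted(by_gene[d]), dtype=np.int64)
        u_offs, d_offs = u_hits[:, 0], d_hits[:, 0]
        # (b) cross-gene order consistency on the oriented read
        order = (u_offs[:, None] < d_offs[None, :]).mean()
        if order < params.order_frac:
            continue
        # (c) within-gene co-monotonicity
        if _concordant_fraction(u_offs, u_hits[:, 1]) < params.mono_frac:
            continue
        if _concordant_fraction(d_offs, d_hits[:, 1]) < params.mono_frac:
            continue
        u_last = u_offs[u_offs < d_offs.max()]
        d_first = d_offs[d_offs > u_offs.min()]
        lo = float(u_last.max()) if u_last.size else float(np.median(u_offs))
        hi = float(d_first.min()) if d_first.size else float(np.median(d_offs))
        transition = (lo + hi) / 2.0
        support = min(len(u_offs), len(d_offs))
        passing.append((support, -min(u, d), u, d, transition))
    if not passing:
        return None
    if len(passing) > 1:
        logger.debug("read %s: %d adjacent pairs pass; keeping strongest", evidence.read_id, len(passing))
    support, _, u, d, transition = max(passing)
    return u, d, transition


def call_readthroughs(
    reads: Iterable[tuple[str, str]],
    indexes: Sequence[IARIndex],
    iars: Sequence[IsolatedActiveRegion],
    sketch_params: SketchParams,
    params: DetectParams = DetectParams(),
) -> list[ReadThroughCall]:
    """End-to-end per-read screening/confirmation and per-pair aggregation.

    ``reads`` yields (read_id, sequence). Pairs with fewer than
    ``params.min_support`` supporting reads are dropped; output is sorted by
    support (descending), then genomic position. Aggregation is independent
    of input order.
    """
    iar_by_id = {iar.iar_id: iar for iar in iars}
    grouped: dict[tuple[str, str], dict] = {}
    n_bad = 0
    for read_id, seq in reads:
        if not seq or not isinstance(seq, str):
            n_bad += 1
            continue
        sk = sketch_read(seq, sketch_params)
        for evidence in screen_read(sk, indexes, params.screen_min_hits, params.rep_max):
            evidence.read_id = read_id
            iar = iar_by_id[evidence.iar_id]
            confirmed = confirm_readthrough(evidence, iar, params)
            if confirmed is None:
                continue
            u, d, transition = confirmed
            gu, gd = iar.genes[u], iar.genes[d]
            key = (gu.gene_id, gd.gene_id)
            slot = grouped.setdefault(
                key,
                {"u": gu, "d": gd, "reads": [], "u_hits": 0, "d_hits": 0, "transitions": []},
            )
            slot["reads"].append(read_id)
            slot["u_hits"] += evidence.per_gene_hits.get(u, 0)
            slot["d_hits"] += evidence.per_gene_hits.get(d, 0)
            slot["transitions"].append(transition)
            break  # one confirmed pair per read; candidates are best-first
    if n_bad:
        logger.warning("skipped %d unreadable records", n_bad)

    calls: list[ReadThroughCall] = []
    for (u_id, d_id), slot in grouped.items():
        if len(slot["reads"]) < params.min_support:
            continue
        calls.append(
            ReadThroughCall(
                upstream_gene=slot["u"],
                downstream_gene=slot["d"],
                supporting_reads=sorted(slot["reads"]),
                upstream_hits=slot["u_hits"],
                downstream_hits=slot["d_hits"],
                breakpoint_read_offset=float(np.median(slot["transitions"])),
                strand=slot["u"].strand,
            )
        )
    calls.sort(
        key=lambda c: (
            -c.n_supporting_reads,
            c.upstream_gene.chrom,
            min(c.upstream_gene.start, c.downstream_gene.start),
            c.upstream_gene.gene_id,
        )
    )
    return calls


def compute_metrics(
    calls: Sequence[ReadThroughCall] | Sequence[tuple[str, str]],
    truth_pairs: Iterable[tuple[str, str]],
) -> Metrics:
    """Recall/precision/F1 of ordered (upstream, downstream) gene-pair calls."""
    called: set[tuple[str, str]] = set()
    for c in calls:
        if isinstance(c, ReadThroughCall):
            called.add((c.upstream_gene.gene_id, c.downstream_gene.gene_id))
        else:
            called.add(tuple(c))
    truth = set(tuple(t) for t in truth_pairs)
    tp = len(called & truth)
    fp = len(called - truth)
    fn = len(truth - called)
    recall = tp / (tp + fn) if truth else None
    precision = tp / (tp + fp) if called else None
    if recall is None or precision is None or (recall + precision) == 0:
        f1 = None if (recall is None or precision is None) else 0.0
    else:
        f1 = 2 * recall * precision / (recall + precision)
    return Metrics(recall, precision, f1)


def calls_to_tsv(calls: Sequence[ReadThroughCall]) -> str:
    """Primary per-pair output table."""
    header = (
        "upstream_gene_id\tupstream_gene_name\tdownstream_gene_id\tdownstream_gene_name\t"
        "chrom\tstrand\tn_supporting_reads\tupstream_hits\tdownstream_hits\tread_ids"
    )
    rows = [header]
    for c in calls:
        rows.append(
            "\t".join(
                [
                    c.upstream_gene.gene_id,
                    c.upstream_gene.gene_name,
                    c.downstream_gene.gene_id,
                    c.downstream_gene.gene_name,
                    c.upstream_gene.chrom,
                    c.strand,
                    str(c.n_supporting_reads),
                    str(c.upstream_hits),
                    str(c.downstream_hits),
                    ",".join(c.supporting_reads),
                ]
            )
        )
    return "\n".join(rows) + "\n"
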