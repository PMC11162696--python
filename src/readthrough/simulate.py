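"""Synthetic benchmark generator: toy genome + annotation, single-gene
transcripts, read-through isoforms of adjacent same-strand gene pairs, and
long reads with controllable length-coverage and error rates.

The error model is i.i.d. per base (independent substitution / insertion /
deletion rates) rather than a trained ONT profile, so noisy-mode results are
a deliberately scaled-down emulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from readthrough.iar_partition import GeneRecord
from readthrough.sketch import reverse_complement

_STOPS = ("TAA", "TAG", "TGA")
_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_chroms: int = 2
    genes_per_chrom: int = 20
    exon_count_range: tuple[int, int] = (2, 4)
    exon_len_range: tuple[int, int] = (120, 300)
    intron_len_range: tuple[int, int] = (150, 500)
    intergenic_gap_range: tuple[int, int] = (300, 2000)
    desert_prob: float = 0.0  # chance of a > thr gene desert between genes
    desert_gap: int = 250_000
    n_readthrough_pairs: int = 10
    depth: float = 100.0
    min_coverage_frac: float = 0.9
    error_rates: tuple[float, float, float] = (0.0, 0.0, 0.0)  # sub, ins, del
    perfect: bool = True
    insert_mode: str = "spliced_out"  # or "retained"

    def __post_init__(self):
        for p in self.error_rates:
            if not 0.0 <= p <= 1.0:
                raise ValueError("error rates must be probabilities")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not 0.0 < self.min_coverage_frac <= 1.0:
            raise ValueError("min_coverage_frac must be in (0, 1]")
        if self.insert_mode not in ("spliced_out", "retained"):
            raise ValueError("insert_mode must be 'spliced_out' or 'retained'")


@dataclass
class Transcript:
    tx_id: str
    gene_ids: tuple[str, ...]
    seq: str
    is_readthrough: bool
    pair: tuple[str, str] | None = None  # (upstream, downstream) gene ids


@dataclass
class SimulatedGenome:
    chrom_seqs: dict[str, str]
    genes: list[GeneRecord]
    transcripts: list[Transcript]
    truth_pairs: list[tuple[str, str]]
    gtf: str


@dataclass
class SimulatedRead:
    read_id: str
    tx_id: str
    tx_start: int  # pre-error coordinates on the source transcript
    tx_end: int
    orientation: str
    seq: str
    is_readthrough: bool


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _make_cdna(rng: np.random.Generator, cdna_len: int) -> tuple[str, int, int]:
    """Random cDNA with a clean ORF: returns (seq, cds_start, cds_end) in
    0-based spliced coordinates, CDS stop-free except its terminal stop."""
    utr5 = int(rng.integers(15, 46))
    utr3_min = 20
    cds_len = cdna_len - utr5 - utr3_min
    cds_len -= cds_len % 3
    if cds_len < 30:
        raise ValueError("cdna too short for an ORF; increase exon lengths")
    n_codons = cds_len // 3 - 2  # minus start and stop
    codons = [_CODONS[i] for i in rng.integers(0, len(_CODONS), n_codons)]
    stop = _STOPS[int(rng.integers(0, 3))]
    cds = "ATG" + "".join(codons) + stop
    utr3 = cdna_len - utr5 - len(cds)
    seq = _random_seq(rng, utr5) + cds + _random_seq(rng, utr3)
    return seq, utr5, utr5 + len(cds)


@dataclass
class _GeneDraft:
    sense_seq: str  # genomic span, sense (annotated) strand
    exons_rel: list[tuple[int, int]]  # 0-based half-open, sense orientation
    cdna: str
    cds_rel: tuple[int, int]  # spliced coords of CDS, 0-based half-open
    strand: str = "+"


def _draft_gene(rng: np.random.Generator, config: SimConfig) -> _GeneDraft:
    lo, hi = config.exon_count_range
    n_exons = int(rng.integers(lo, hi + 1))
    lens = [int(rng.integers(*config.exon_len_range)) for _ in range(n_exons)]
    cdna, cds_lo, cds_hi = _make_cdna(rng, sum(lens))
    exons_rel: list[tuple[int, int]] = []
    parts: list[str] = []
    pos = 0  # genomic cursor (sense)
    spliced = 0
    for i, ln in enumerate(lens):
        parts.append(cdna[spliced : spliced + ln])
        exons_rel.append((pos, pos + ln))
        pos += ln
        spliced += ln
        if i < n_exons - 1:
            intron_len = int(rng.integers(*config.intron_len_range))
            parts.append(_random_seq(rng, intron_len))
            pos += intron_len
    return _GeneDraft("".join(parts), exons_rel, cdna, (cds_lo, cds_hi))


def _spliced_to_sense_intervals(
    exons_rel: Sequence[tuple[int, int]], lo: int, hi: int
) -> list[tuple[int, int]]:
    """Map a spliced [lo, hi) interval onto sense-genomic sub-intervals."""
    out = []
    spliced = 0
    for s, e in exons_rel:
        ln = e - s
        a, b = max(lo, spliced), min(hi, spliced + ln)
        if a < b:
            out.append((s + (a - spliced), s + (b - spliced)))
        spliced += ln
    return out


def make_genome(config: SimConfig) -> SimulatedGenome:
    """Build the toy genome, annotation, truth transcripts and truth pairs.

    Read-through isoforms are added for ``n_readthrough_pairs`` disjoint
    adjacent same-strand gene pairs; in the default ``spliced_out`` mode the
    fused cDNA is the concatenation of the two parents' spliced exons in
    transcription order. All transcripts get equal expression downstream.
    """
    rng = np.random.default_rng(config.seed)
    n_genes = config.n_chroms * config.genes_per_chrom

    # choose disjoint adjacent pairs (within a chromosome): sample among the
    # non-overlapping (2j, 2j+1) slots so any feasible request succeeds
    slots: list[int] = []
    for c in range(config.n_chroms):
        base = c * config.genes_per_chrom
        slots.extend(base + 2 * j for j in range(config.genes_per_chrom // 2))
    if config.n_readthrough_pairs > len(slots):
        raise ValueError("not enough adjacent gene pairs for requested read-throughs")
    rng.shuffle(slots)
    pair_left_set = set(slots[: config.n_readthrough_pairs])

    strands = ["+" if rng.random() < 0.5 else "-" for _ in range(n_genes)]
    for i in pair_left_set:
        strands[i + 1] = strands[i]

    chrom_seqs: dict[str, str] = {}
    genes: list[GeneRecord] = []
    transcripts: list[Transcript] = []
    truth_pairs: list[tuple[str, str]] = []
    gtf_rows: list[str] = []
    drafts: list[_GeneDraft] = []
    gene_gap_seq: dict[int, str] = {}  # gap sequence after gene i (genomic)

    gidx = 0
    for c in range(config.n_chroms):
        chrom = f"chr{c + 1}"
        segments: list[str] = []
        cursor = int(rng.integers(200, 500))
        segments.append(_random_seq(rng, cursor))
        for gi in range(config.genes_per_chrom):
            draft = _draft_gene(rng, config)
            draft.strand = strands[gidx]
            glen = len(draft.sense_seq)
            genomic = draft.sense_seq if draft.strand == "+" else reverse_complement(draft.sense_seq)
            start = cursor + 1  # 1-based inclusive
            end = cursor + glen
            segments.append(genomic)
            cursor += glen

            def to_genomic(rel: tuple[int, int]) -> tuple[int, int]:
                a, b = rel  # 0-based half-open, sense orientation
                if draft.strand == "+":
                    return start + a, start + b - 1
                return start + (glen - b), start + (glen - a) - 1

            exons_g = sorted(to_genomic(iv) for iv in draft.exons_rel)
            cds_sense = _spliced_to_sense_intervals(draft.exons_rel, *draft.cds_rel)
            cds_g = sorted(to_genomic(iv) for iv in cds_sense)
            gene_id = f"G{gidx:04d}"
            record = GeneRecord(
                gene_id=gene_id,
                gene_name=gene_id,
                chrom=chrom,
                strand=draft.strand,
                start=start,
                end=end,
                exons=exons_g,
                cds=(cds_g[0][0], cds_g[-1][1]) if cds_g else None,
            )
            record.validate()
            genes.append(record)
            drafts.append(draft)
            transcripts.append(
                Transcript(f"{gene_id}.t1", (gene_id,), draft.cdna, is_readthrough=False)
            )
            attrs = f'gene_id "{gene_id}"; gene_name "{gene_id}";'
            tx_attrs = f'gene_id "{gene_id}"; transcript_id "{gene_id}.t1"; gene_name "{gene_id}";'
            gtf_rows.append(
                f"{chrom}\tsim\tgene\t{start}\t{end}\t.\t{draft.strand}\t.\t{attrs}"
            )
            gtf_rows.append(
                f"{chrom}\tsim\ttranscript\t{start}\t{end}\t.\t{draft.strand}\t.\t{tx_attrs}"
            )
            for s, e in exons_g:
                gtf_rows.append(f"{chrom}\tsim\texon\t{s}\t{e}\t.\t{draft.strand}\t.\t{tx_attrs}")
            for s, e in cds_g:
                gtf_rows.append(f"{chrom}\tsim\tCDS\t{s}\t{e}\t.\t{draft.strand}\t0\t{tx_attrs}")

            if gi < config.genes_per_chrom - 1:
                if config.desert_prob > 0 and rng.random() < config.desert_prob:
                    gap = config.desert_gap
                else:
                    gap = int(rng.integers(*config.intergenic_gap_range))
                gap_seq = _random_seq(rng, gap)
                segments.append(gap_seq)
                gene_gap_seq[gidx] = gap_seq
                cursor += gap
            gidx += 1
        segments.append(_random_seq(rng, int(rng.integers(200, 500))))
        chrom_seqs[chrom] = "".join(segments)

    for i in sorted(pair_left_set):
        left, right = genes[i], genes[i + 1]
        strand = left.strand
        if strand == "+":
            u, d = i, i + 1
            insert = gene_gap_seq[i]
        else:
            u, d = i + 1, i
            insert = reverse_complement(gene_gap_seq[i])
        fused = drafts[u].cdna + (insert if config.insert_mode == "retained" else "") + drafts[d].cdna
        u_id, d_id = genes[u].gene_id, genes[d].gene_id
        transcripts.append(
            Transcript(
                f"RT_{u_id}_{d_id}", (u_id, d_id), fused, is_readthrough=True, pair=(u_id, d_id)
            )
        )
        truth_pairs.append((u_id, d_id))

    return SimulatedGenome(
        chrom_seqs=chrom_seqs,
        genes=genes,
        transcripts=transcripts,
        truth_pairs=truth_pairs,
        gtf="\n".join(gtf_rows) + "\n",
    )


def apply_errors(
    seq: str, rng: np.random.Generator, sub: float, ins: float, dele: float
) -> str:
    """i.i.d. per-base corruption: substitution (to a different base),
    insertion after the base, deletion of the base."""
    n = len(seq)
    if n == 0 or (sub == 0 and ins == 0 and dele == 0):
        return seq
    dels = rng.random(n) < dele
    subs = rng.random(n) < sub
    inss = rng.random(n) < ins
    sub_pick = rng.integers(0, 3, n)
    ins_pick = rng.integers(0, 4, n)
    acgt = "ACGT"
    out: list[str] = []
    for i, b in enumerate(seq):
        if not dels[i]:
            if subs[i]:
                others = acgt.replace(b, "") if b in acgt else acgt[:3]
                b = others[sub_pick[i]]
            out.append(b)
        if inss[i]:
            out.append(acgt[ins_pick[i]])
    return "".join(out)


def simulate_reads(
    transcripts: Sequence[Transcript], config: SimConfig, rng: np.random.Generator | None = None
) -> list[SimulatedRead]:
    """Sample reads per transcript until ``depth``-fold coverage is reached.

    Each read covers a contiguous fraction drawn uniformly from
    [min_coverage_frac, 1] of its transcript, anchored at the 5' or 3' end
    with equal probability, reverse-complemented half the time, and (unless
    ``perfect``) corrupted by the i.i.d. error model. Truth coordinates are
    recorded pre-error.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    sub, ins, dele = (0.0, 0.0, 0.0) if config.perfect else config.error_rates
    reads: list[SimulatedRead] = []
    for tx in transcripts:
        L = len(tx.seq)
        target = config.depth * L
        total = 0
        i = 0
        while total < target:
            frac = rng.uniform(config.min_coverage_frac, 1.0)
            rl = max(1, int(round(frac * L)))
            if rng.random() < 0.5:
                start, end = 0, rl  # 5'-anchored
            else:
                start, end = L - rl, L
            raw = tx.seq[start:end]
            orientation = "+" if rng.random() < 0.5 else "-"
            seq = raw if orientation == "+" else reverse_complement(raw)
            seq = apply_errors(seq, rng, sub, ins, dele)
            reads.append(
                SimulatedRead(
                    read_id=f"{tx.tx_id}_r{i}",
                    tx_id=tx.tx_id,
                    tx_start=start,
                    tx_end=end,
                    orientation=orientation,
                    seq=seq,
                    is_readthrough=tx.is_readthrough,
                )
            )
            total += rl
            i += 1
    return reads


def truth_pairs_tsv(sim: SimulatedGenome) -> str:
    rows = ["upstream_gene_id\tdownstream_gene_id"]
    rows += [f"{u}\t{d}" for u, d in sim.truth_pairs]
    return "\n".join(rows) + "\n"


def truth_reads_tsv(reads: Sequence[SimulatedRead]) -> str:
    rows = ["read_id\ttx_id\ttx_start\ttx_end\torientation\tis_readthrough"]
    for r in reads:
        rows.append(
            f"{r.read_id}\t{r.tx_id}\t{r.tx_start}\t{r.tx_end}\t{r.orientation}\t{int(r.is_readthrough)}"
        )
    return "\n".join(rows) + "\n"
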