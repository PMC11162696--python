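"""Per-region slot-array minimizer index.

Each isolated active region stores its minimizers in one contiguous
fixed-size array. The home slot of a posting is ``hash % modulus`` where
``modulus = n_minimizers`` when ``n_minimizers >= mo`` and ``mo`` otherwise;
collisions are resolved by linear probing into subsequent slots (wrapping),
which preserves the contiguous-memory layout while guaranteeing that every
inserted posting remains retrievable.
"""

from __future__ import annotations

import json
import struct
from dataclasses import asdict
from typing import Sequence

import numpy as np

from readthrough.iar_partition import GeneRecord, IsolatedActiveRegion
from readthrough.sketch import Minimizer, SketchParams, reverse_complement, sketch_gene

#: Capacity slack over max(n_minimizers, mo); keeps probe chains short.
SLACK = 1.3

_MAGIC = b"RTIDX1\n"


class IARIndex:
    """Open-addressed postings table for one IAR.

    Slots are parallel arrays (hash, gene ordinal, gene offset, occupancy).
    """

    def __init__(self, iar_id: int, n_minimizers: int, mo: int):
        self.iar_id = iar_id
        self.n_minimizers = n_minimizers
        self.modulus = n_minimizers if n_minimizers >= mo else mo
        self.capacity = max(int(np.ceil(SLACK * max(n_minimizers, mo))), 8)
        self.slot_hash = np.zeros(self.capacity, dtype=np.uint64)
        self.slot_gene = np.zeros(self.capacity, dtype=np.int32)
        self.slot_offset = np.zeros(self.capacity, dtype=np.int64)
        self.occupied = np.zeros(self.capacity, dtype=bool)
        self.n_inserted = 0

    def home_slot(self, h: int) -> int:
        return int(h % self.modulus)

    def insert(self, h: int, gene_ordinal: int, offset: int) -> None:
        if self.n_inserted >= self.capacity:
            raise RuntimeError("index capacity exceeded")  # cannot happen via build_iar_index
        pos = self.home_slot(h)
        while self.occupied[pos]:
            pos = (pos + 1) % self.capacity
        self.slot_hash[pos] = np.uint64(h)
        self.slot_gene[pos] = gene_ordinal
        self.slot_offset[pos] = offset
        self.occupied[pos] = True
        self.n_inserted += 1

    def query(self, h: int) -> list[tuple[int, int]]:
        """All (gene_ordinal, offset) postings inserted with hash ``h``,
        in insertion order; empty list if absent."""
        out: list[tuple[int, int]] = []
        pos = self.home_slot(h)
        for _ in range(self.capacity):
            if not self.occupied[pos]:
                break
            if self.slot_hash[pos] == np.uint64(h):
                out.append((int(self.slot_gene[pos]), int(self.slot_offset[pos])))
            pos = (pos + 1) % self.capacity
        return out

    def query_batch(self, qhashes: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Vectorized lookup of many hashes at once.

        Returns parallel arrays (query_index, gene_ordinal, gene_offset),
        one row per matching posting.
        """
        q = np.asarray(qhashes, dtype=np.uint64)
        if q.size == 0 or self.n_inserted == 0:
            return (np.empty(0, np.int64), np.empty(0, np.int64), np.empty(0, np.int64))
        pos = (q % np.uint64(self.modulus)).astype(np.int64)
        alive = np.arange(q.size, dtype=np.int64)
        out_q, out_g, out_o = [], [], []
        for _ in range(self.capacity):
            if alive.size == 0:
                break
            p = pos[alive]
            occ = self.occupied[p]
            hit = occ & (self.slot_hash[p] == q[alive])
            if hit.any():
                out_q.append(alive[hit])
                out_g.append(self.slot_gene[p[hit]].astype(np.int64))
                out_o.append(self.slot_offset[p[hit]])
            alive = alive[occ]
            pos[alive] = (pos[alive] + 1) % self.capacity
        if not out_q:
            return (np.empty(0, np.int64), np.empty(0, np.int64), np.empty(0, np.int64))
        return (np.concatenate(out_q), np.concatenate(out_g), np.concatenate(out_o))

    def _arrays(self) -> tuple[np.ndarray, ...]:
        return self.slot_hash, self.slot_gene, self.slot_offset, self.occupied


def build_iar_index(minimizers: Sequence[Minimizer], mo: int) -> IARIndex:
    """Build the slot array for one IAR's minimizers.

    Exact duplicate postings (hash, gene_ordinal, offset) are stored once;
    n_minimizers counts the distinct postings and sets the modulus branch.
    """
    if mo < 1:
        raise ValueError("mo must be >= 1")
    seen: set[tuple[int, int, int]] = set()
    postings: list[tuple[int, int, int]] = []
    for m in minimizers:
        key = (m.hash, m.gene_ordinal, m.offset)
        if key not in seen:
            seen.add(key)
            postings.append(key)
    index = IARIndex(iar_id=0, n_minimizers=len(postings), mo=mo)
    for h, g, o in postings:
        index.insert(h, g, o)
    return index


def query_index(index: IARIndex, h: int) -> list[tuple[int, int]]:
    return index.query(h)


def fetch_sequence(genome, chrom: str, start: int, end: int) -> str:
    """Extract [start, end] (1-based inclusive) from a FASTA accessor.

    Accepts a pyfaidx.Fasta or a plain ``{chrom: sequence}`` mapping.
    """
    try:
        record = genome[chrom]
    except KeyError:
        raise KeyError(f"chromosome {chrom!r} missing from genome FASTA") from None
    piece = record[start - 1 : end]
    return str(getattr(piece, "seq", piece)).upper()


def gene_sequence(genome, gene: GeneRecord) -> str:
    """Genomic span of the gene on its annotated strand (5'->3')."""
    seq = fetch_sequence(genome, gene.chrom, gene.start, gene.end)
    return reverse_complement(seq) if gene.strand == "-" else seq


def build_all(
    iars: Sequence[IsolatedActiveRegion], genome, params: SketchParams
) -> list[IARIndex]:
    """One independent index per IAR (no shared mutable state across builds)."""
    indexes: list[IARIndex] = []
    for iar in iars:
        minimizers: list[Minimizer] = []
        for ordinal, gene in enumerate(iar.genes):
            seq = gene_sequence(genome, gene)
            minimizers.extend(sketch_gene(seq, params, gene_ordinal=ordinal))
        index = build_iar_index(minimizers, params.mo)
        index.iar_id = iar.iar_id
        indexes.append(index)
    return indexes


# ---------------------------------------------------------------------------
# serialization: versioned binary, bit-exact round-trip


def _gene_to_dict(g: GeneRecord) -> dict:
    d = asdict(g)
    d["exons"] = [list(e) for e in g.exons]
    d["cds"] = list(g.cds) if g.cds else None
    return d


def _gene_from_dict(d: dict) -> GeneRecord:
    return GeneRecord(
        gene_id=d["gene_id"],
        gene_name=d["gene_name"],
        chrom=d["chrom"],
        strand=d["strand"],
        start=d["start"],
        end=d["end"],
        exons=[tuple(e) for e in d["exons"]],
        cds=tuple(d["cds"]) if d["cds"] else None,
    )


def save_indexes(
    path: str,
    params: SketchParams,
    iars: Sequence[IsolatedActiveRegion],
    indexes: Sequence[IARIndex],
) -> None:
    header = {
        "params": asdict(params),
        "iars": [
            {"iar_id": iar.iar_id, "chrom": iar.chrom, "genes": [_gene_to_dict(g) for g in iar.genes]}
            for iar in iars
        ],
        "indexes": [
            {
                "iar_id": ix.iar_id,
                "n_minimizers": ix.n_minimizers,
                "modulus": ix.modulus,
                "capacity": ix.capacity,
                "n_inserted": ix.n_inserted,
            }
            for ix in indexes
        ],
    }
    blob = json.dumps(header, sort_keys=True).encode("utf-8")
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(struct.pack("<Q", len(blob)))
        fh.write(blob)
        for ix in indexes:
            for arr in ix._arrays():
                fh.write(arr.tobytes())


def load_indexes(path: str) -> tuple[SketchParams, list[IsolatedActiveRegion], list[IARIndex]]:
    with open(path, "rb") as fh:
        magic = fh.read(len(_MAGIC))
        if magic != _MAGIC:
            raise ValueError(f"{path}: not a readthrough index file")
        (blob_len,) = struct.unpack("<Q", fh.read(8))
        header = json.loads(fh.read(blob_len).decode("utf-8"))
        params = SketchParams(**header["params"])
        iars = [
            IsolatedActiveRegion(
                iar_id=d["iar_id"], chrom=d["chrom"], genes=[_gene_from_dict(g) for g in d["genes"]]
            )
            for d in header["iars"]
        ]
        indexes = []
        for meta in header["indexes"]:
            ix = IARIndex.__new__(IARIndex)
            ix.iar_id = meta["iar_id"]
            ix.n_minimizers = meta["n_minimizers"]
            ix.modulus = meta["modulus"]
            ix.capacity = meta["capacity"]
            ix.n_inserted = meta["n_inserted"]
            cap = ix.capacity
            ix.slot_hash = np.frombuffer(fh.read(8 * cap), dtype=np.uint64).copy()
            ix.slot_gene = np.frombuffer(fh.read(4 * cap), dtype=np.int32).copy()
            ix.slot_offset = np.frombuffer(fh.read(8 * cap), dtype=np.int64).copy()
            ix.occupied = np.frombuffer(fh.read(cap), dtype=bool).copy()
            indexes.append(ix)
    return params, iars, indexes
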