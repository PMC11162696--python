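"""Sliding-window minimizer sketching with a bijective avalanche hash.

Each window of length ``s`` contributes one minimizer: the k-mer whose
64-bit hash is minimal among the ``s - k + 1`` k-mers in the window. The
hash is an invertible multiply-xorshift mix, so distinct k-mers can never
collide; tests may inject an identity hash instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

MASK64 = (1 << 64) - 1

_C1 = 0xFF51AFD7ED558CCD
_C2 = 0xC4CEB9FE1A85EC53
_C1_INV = pow(_C1, -1, 1 << 64)
_C2_INV = pow(_C2, -1, 1 << 64)

#: Sentinel for k-mers containing ambiguous bases.
UNENCODABLE = -1

_BASE_CODES = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODES[_b] = _i
    _BASE_CODES[_b + 32] = _i  # lowercase

_COMPLEMENT = bytes.maketrans(b"ACGTacgtNn", b"TGCAtgcaNn")


def reverse_complement(seq: str) -> str:
    return seq.encode("ascii").translate(_COMPLEMENT)[::-1].decode("ascii")


@dataclass(frozen=True)
class SketchParams:
    """Sketching and pipeline parameters.

    k: k-mer length; s: window length; st: window step; thr: IAR gap
    threshold (bp); mo: index modulus floor (slots); min_support: minimum
    supporting reads for an emitted call.
    """

    k: int = 25
    s: int = 40
    st: int = 9
    thr: int = 100_000
    mo: int = 4096
    min_support: int = 1

    def __post_init__(self):
        if not 1 <= self.k <= 32:
            raise ValueError("k must be in [1, 32]")
        if self.k > self.s:
            raise ValueError("k must not exceed window length s")
        if not 1 <= self.st <= self.s:
            raise ValueError("st must be in [1, s]")
        if self.mo < 1:
            raise ValueError("mo must be >= 1")


#: Preset for noisy (high-error) data.
NOISY_PARAMS = SketchParams(k=15, s=24, st=9)


@dataclass(frozen=True)
class Minimizer:
    hash: int
    kmer_code: int
    gene_ordinal: int
    offset: int
    strand_of_kmer: str = "+"


def encode_kmer(seq: str) -> int:
    """2-bit pack a k-mer (A=0, C=1, G=2, T=3, most-significant base first).

    Returns :data:`UNENCODABLE` if the k-mer contains an ambiguous base.
    """
    if len(seq) > 32:
        raise ValueError("k-mer longer than 32 bases cannot pack into 64 bits")
    code = 0
    for b in seq.encode("ascii"):
        c = _BASE_CODES[b]
        if c > 3:
            return UNENCODABLE
        code = (code << 2) | int(c)
    return code


def decode_kmer(code: int, k: int) -> str:
    return "".join("ACGT"[(code >> (2 * (k - 1 - i))) & 3] for i in range(k))


def avalanche_hash(code):
    """Bijective 64-bit avalanche mix (multiply-xorshift finalizer style).

    Accepts a Python int or a uint64 ndarray; returns the same kind.
    """
    if isinstance(code, np.ndarray):
        x = code.astype(np.uint64, copy=True)
        x ^= x >> np.uint64(33)
        x *= np.uint64(_C1)
        x ^= x >> np.uint64(33)
        x *= np.uint64(_C2)
        x ^= x >> np.uint64(33)
        return x
    x = code & MASK64
    x ^= x >> 33
    x = (x * _C1) & MASK64
    x ^= x >> 33
    x = (x * _C2) & MASK64
    x ^= x >> 33
    return x


def avalanche_hash_inverse(h: int) -> int:
    """Exact inverse of :func:`avalanche_hash` (scalar)."""
    x = h & MASK64
    x ^= x >> 33  # xorshift by >=32 is an involution
    x = (x * _C2_INV) & MASK64
    x ^= x >> 33
    x = (x * _C1_INV) & MASK64
    x ^= x >> 33
    return x


def _kmer_code_array(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Codes of all k-mers of ``seq`` plus a validity mask (no ambiguous base)."""
    b = _BASE_CODES[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if len(b) < k:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    win = np.lib.stride_tricks.sliding_window_view(b, k)
    valid = (win < 4).all(axis=1)
    weights = (np.uint64(4) ** np.arange(k - 1, -1, -1, dtype=np.uint64))
    codes = (win.astype(np.uint64) * weights).sum(axis=1, dtype=np.uint64)
    return codes, valid


def _hash_array(codes: np.ndarray, valid: np.ndarray, hash_fn: Callable | None) -> np.ndarray:
    """Hashes with invalid positions forced to the maximum sentinel."""
    if hash_fn is None:
        hashes = avalanche_hash(codes)
    else:
        hashes = np.array([hash_fn(int(c)) for c in codes], dtype=np.uint64)
    out = hashes.copy()
    out[~valid] = np.uint64(MASK64)
    return out


def window_minimizer(
    window: str, params: SketchParams, hash_fn: Callable | None = None
) -> tuple[int, int] | None:
    """Minimizer of one window: (hash, k-mer offset within window), or None.

    The minimizer is the argmin over the hashes of the window's k-mers;
    k-mers containing ambiguous bases are excluded. ``None`` when no k-mer
    is encodable.
    """
    codes, valid = _kmer_code_array(window, params.k)
    if codes.size == 0 or not valid.any():
        return None
    hashes = _hash_array(codes, valid, hash_fn)
    off = int(np.argmin(hashes))
    return int(hashes[off]), off


def _window_starts(length: int, s: int, st: int) -> list[int]:
    """Window anchor offsets: 0, st, 2*st, ... plus a tail window at length-s
    when the last full window stops short of the sequence end."""
    if length <= s:
        return [0]
    starts = list(range(0, length - s + 1, st))
    if starts[-1] + s < length:
        starts.append(length - s)
    return starts


def sketch_gene(
    gene_seq: str,
    params: SketchParams,
    gene_ordinal: int = 0,
    hash_fn: Callable | None = None,
) -> list[Minimizer]:
    """Sketch one gene sequence into minimizers.

    Windows start at 0, st, 2*st, ...; a final window anchored at
    ``len - s`` is added if needed so the 3' end is covered. A sequence
    shorter than ``s`` (but >= k) is sketched as one truncated window.
    Duplicate (hash, offset) pairs are collapsed. Offsets are 0-based
    positions of the k-mer within ``gene_seq``.
    """
    L = len(gene_seq)
    if L < params.k:
        return []
    codes, valid = _kmer_code_array(gene_seq, params.k)
    hashes = _hash_array(codes, valid, hash_fn)
    seen: set[tuple[int, int]] = set()
    out: list[Minimizer] = []
    for w in _window_starts(L, params.s, params.st):
        hi = min(w + params.s, L) - params.k + 1
        if hi <= w:
            continue
        chunk = hashes[w:hi]
        rel = int(np.argmin(chunk))
        h = int(chunk[rel])
        if not valid[w + rel]:
            continue  # window entirely ambiguous
        off = w + rel
        key = (h, off)
        if key not in seen:
            seen.add(key)
            out.append(
                Minimizer(hash=h, kmer_code=int(codes[off]), gene_ordinal=gene_ordinal, offset=off)
            )
    return out


def sketch_read(
    read_seq: str, params: SketchParams, hash_fn: Callable | None = None
) -> list[tuple[int, int, str]]:
    """Sketch a read and its reverse complement with the gene window scheme.

    Returns (hash, offset, strand) triples; the offset of a "-" entry is the
    k-mer position within the reverse-complemented read. Both orientations
    are sketched because reference genes are sketched on their annotated
    strand only.
    """
    out: list[tuple[int, int, str]] = []
    for strand, seq in (("+", read_seq), ("-", reverse_complement(read_seq))):
        for m in sketch_gene(seq, params, hash_fn=hash_fn):
            out.append((m.hash, m.offset, strand))
    return out
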