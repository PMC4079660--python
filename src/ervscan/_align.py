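"""Alignment primitives: exact k-mer seeding plus edlib verification.

Flank mapping follows the classic seed-and-extend recipe: exact k-mers
(default k=16) sampled along the query vote for a target diagonal; the best
diagonal is verified by a bit-parallel banded alignment (edlib, infix mode)
and accepted when the identity over the full query reaches the caller's
threshold.  With substitution-only divergence the winning diagonal gives
exact target coordinates, which downstream deletion sizing relies on.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import edlib
import numpy as np

_CODE = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _CODE[b] = i


@dataclass
class SeqIndex:
    """Sorted k-mer index of one sequence."""

    k: int
    sorted_codes: np.ndarray
    order: np.ndarray  # positions, sorted by code

    @classmethod
    def build(cls, seq: str, k: int = 16) -> "SeqIndex":
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        codes4 = _CODE[arr]
        n = arr.size - k + 1
        if n <= 0:
            return cls(k, np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.int64))
        codes = np.zeros(n, dtype=np.uint64)
        for j in range(k):
            codes = (codes << np.uint64(2)) | codes4[j:j + n].astype(np.uint64)
        # invalidate k-mers containing non-ACGT bases
        bad = (codes4 > 3).astype(np.int32)
        cbad = np.concatenate(([0], np.cumsum(bad)))
        valid = (cbad[k:] - cbad[:-k]) == 0
        positions = np.flatnonzero(valid).astype(np.int64)
        codes = codes[positions]
        order = np.argsort(codes, kind="stable")
        return cls(k, codes[order], positions[order])

    def locate(self, code: int) -> np.ndarray:
        key = np.uint64(code)  # a Python int key forces a full-array cast
        lo = np.searchsorted(self.sorted_codes, key, side="left")
        hi = np.searchsorted(self.sorted_codes, key, side="right")
        return self.order[lo:hi]


class GenomeIndex:
    """Per-chromosome k-mer indexes of one genome."""

    def __init__(self, genome: dict[str, str], k: int = 16):
        self.k = k
        self.genome = genome
        self.chroms = {name: SeqIndex.build(seq, k) for name, seq in genome.items()}


def _encode_kmer(kmer: str) -> int | None:
    code = 0
    for ch in kmer:
        v = _CODE[ord(ch)]
        if v > 3:
            return None
        code = (code << 2) | int(v)
    return code


@dataclass
class SeedHit:
    chrom: str
    start: int  # query start position on the target (diagonal)
    votes: int
    runner_up_votes: int


def seed_locate(query: str, index: GenomeIndex, n_seeds: int = 24) -> SeedHit | None:
    """Vote for the target diagonal of `query` using sampled exact k-mers."""
    k = index.k
    if len(query) < k:
        return None
    stride = max(1, (len(query) - k) // max(1, n_seeds - 1))
    votes: Counter = Counter()
    for off in range(0, len(query) - k + 1, stride):
        code = _encode_kmer(query[off:off + k])
        if code is None:
            continue
        for chrom, cindex in index.chroms.items():
            for pos in cindex.locate(code):
                votes[(chrom, int(pos) - off)] += 1
    if not votes:
        return None
    ranked = votes.most_common(2)
    (chrom, diag), best = ranked[0]
    runner = ranked[1][1] if len(ranked) > 1 else 0
    return SeedHit(chrom=chrom, start=diag, votes=best, runner_up_votes=runner)


def identity_at(query: str, target: str, start: int, pad: int = 32) -> float:
    """Identity of `query` aligned (infix) inside target[start-pad:start+len+pad]."""
    lo = max(0, start - pad)
    window = target[lo:start + len(query) + pad]
    if not window:
        return 0.0
    res = edlib.align(query, window, mode="HW", task="distance")
    return 1.0 - res["editDistance"] / len(query)


def global_identity(a: str, b: str) -> float:
    """Identity of a global (NW) alignment, normalised by the longer sequence."""
    if not a or not b:
        return 0.0
    res = edlib.align(a, b, mode="NW", task="distance")
    return 1.0 - res["editDistance"] / max(len(a), len(b))


def global_alignment(a: str, b: str) -> tuple[str, str]:
    """Gapped global alignment of two sequences via edlib's cigar."""
    res = edlib.align(a, b, mode="NW", task="path")
    nice = edlib.getNiceAlignment(res, a, b)
    return nice["query_aligned"], nice["target_aligned"]
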