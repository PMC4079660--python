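"""Synthetic consensus library for six gammaretrovirus-like LTR subfamilies.

The library stands in for a Repbase-style reference set of chimpanzee-specific
ERV subfamily consensus sequences.  It is fully synthetic: sequences are
generated deterministically from a fixed internal seed, but the layout follows
the canonical provirus architecture

    5'LTR -- leader -- gag -- pro -- pol -- env -- trailer -- 3'LTR

with one internal region per family (CERV1-like and CERV2-like) and one LTR
per subfamily.  LTR lengths match the reported per-subfamily values
(CERV1 409, PtERV-1c 379, CERV2 544, PtERV-2a 586, PtERV-2b 491,
PtERV-2c 603 bp) and the CERV2-family env gene is shorter than CERV1's, so the
two families have distinct internal anatomies.  Subfamily LTRs within a family
are ~12% diverged siblings, which keeps sequence-based subfamily assignment
non-trivial.

Every gene is an intact open reading frame on the consensus (ATG .. stop with
no internal stop codons), so ORF screening of an unmutated element reports all
four genes intact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np

from ._mutate import mutate_per_site, seq_to_array, array_to_seq
from .io import read_fasta, write_fasta

_LIBRARY_SEED = 20114  # fixed: the library is a reference object, not a simulation

LTR_LENGTHS = {
    "CERV1": 409,
    "PtERV-1c": 379,
    "CERV2": 544,
    "PtERV-2a": 586,
    "PtERV-2b": 491,
    "PtERV-2c": 603,
}

FAMILY_OF = {
    "CERV1": "CERV1",
    "PtERV-1c": "CERV1",
    "CERV2": "CERV2",
    "PtERV-2a": "CERV2",
    "PtERV-2b": "CERV2",
    "PtERV-2c": "CERV2",
}

GENES = ("gag", "pro", "pol", "env")

# gene lengths (bp, including the terminal stop codon); env differs by family
_GENE_LEN = {"gag": 1560, "pro": 900, "pol": 3300}
_ENV_LEN = {"CERV1": 1980, "CERV2": 1500}
_LEADER, _SPACER, _TRAILER = 120, 39, 60

_STOPS = {"TAA", "TAG", "TGA"}
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SubfamilyConsensus:
    """One subfamily: its LTR, the family internal region, and gene spans."""

    name: str
    family: str
    ltr: str
    internal: str
    gene_spans: dict[str, tuple[int, int]]  # 0-based half-open on `internal`

    @property
    def full_sequence(self) -> str:
        return self.ltr + self.internal + self.ltr

    @property
    def ltr_length(self) -> int:
        return len(self.ltr)


@dataclass
class ConsensusLibrary:
    subfamilies: dict[str, SubfamilyConsensus] = field(default_factory=dict)

    def __getitem__(self, name: str) -> SubfamilyConsensus:
        return self.subfamilies[name]

    def __iter__(self):
        return iter(self.subfamilies.values())

    @property
    def names(self) -> list[str]:
        return list(self.subfamilies)

    def ltr_consensus_set(self) -> dict[str, str]:
        return {name: sub.ltr for name, sub in self.subfamilies.items()}

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta({s.name: s.full_sequence for s in self}, outdir / "consensus.fa")
        write_fasta(self.ltr_consensus_set(), outdir / "consensus_ltr.fa")
        meta = {
            s.name: {
                "family": s.family,
                "ltr_length": s.ltr_length,
                "gene_spans": {g: list(sp) for g, sp in s.gene_spans.items()},
            }
            for s in self
        }
        (outdir / "consensus_meta.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, outdir: str | Path) -> "ConsensusLibrary":
        outdir = Path(outdir)
        full = read_fasta(outdir / "consensus.fa")
        meta = json.loads((outdir / "consensus_meta.json").read_text())
        subs = {}
        for name, info in meta.items():
            seq = full[name]
            n = info["ltr_length"]
            subs[name] = SubfamilyConsensus(
                name=name,
                family=info["family"],
                ltr=seq[:n],
                internal=seq[n : len(seq) - n],
                gene_spans={g: tuple(sp) for g, sp in info["gene_spans"].items()},
            )
        return cls(subs)


def _random_seq(rng: np.random.Generator, n: int, gc: float = 0.45) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return array_to_seq(rng.choice(_BASES, size=n, p=p))


def _random_orf(rng: np.random.Generator, n_bp: int) -> str:
    """ATG + random non-stop codons + TAA, total length n_bp (multiple of 3)."""
    assert n_bp % 3 == 0 and n_bp >= 9
    codons = ["ATG"]
    while len(codons) < n_bp // 3 - 1:
        c = _random_seq(rng, 3)
        if c not in _STOPS:
            codons.append(c)
    codons.append("TAA")
    return "".join(codons)


def _resize(seq: str, target: int, rng: np.random.Generator) -> str:
    """Insert or delete one internal block to reach the target length."""
    if len(seq) == target:
        return seq
    if len(seq) > target:
        k = len(seq) - target
        pos = int(rng.integers(10, len(seq) - k - 10))
        return seq[:pos] + seq[pos + k :]
    k = target - len(seq)
    pos = int(rng.integers(10, len(seq) - 10))
    return seq[:pos] + _random_seq(rng, k) + seq[pos:]


def _sibling_ltr(base: str, target_len: int, rng: np.random.Generator, div: float = 0.12) -> str:
    mutated = array_to_seq(mutate_per_site(seq_to_array(base), div, rng))
    return _resize(mutated, target_len, rng)


def _family_internal(rng: np.random.Generator, family: str) -> tuple[str, dict[str, tuple[int, int]]]:
    parts = [_random_seq(rng, _LEADER)]
    spans: dict[str, tuple[int, int]] = {}
    pos = _LEADER
    lengths = dict(_GENE_LEN, env=_ENV_LEN[family])
    for gene in GENES:
        n = lengths[gene]
        parts.append(_random_orf(rng, n))
        spans[gene] = (pos, pos + n)
        pos += n
        parts.append(_random_seq(rng, _SPACER))
        pos += _SPACER
    parts.append(_random_seq(rng, _TRAILER - _SPACER))
    return "".join(parts), spans


def default_library() -> ConsensusLibrary:
    """Deterministically generate the six-subfamily synthetic reference set."""
    rng = np.random.default_rng(_LIBRARY_SEED)
    internals = {fam: _family_internal(rng, fam) for fam in ("CERV1", "CERV2")}
    base_ltr = {
        "CERV1": _random_seq(rng, LTR_LENGTHS["CERV1"]),
        "CERV2": _random_seq(rng, LTR_LENGTHS["CERV2"]),
    }
    ltrs = {
        "CERV1": base_ltr["CERV1"],
        "PtERV-1c": _sibling_ltr(base_ltr["CERV1"], LTR_LENGTHS["PtERV-1c"], rng),
        "CERV2": base_ltr["CERV2"],
        "PtERV-2a": _sibling_ltr(base_ltr["CERV2"], LTR_LENGTHS["PtERV-2a"], rng),
        "PtERV-2b": _sibling_ltr(base_ltr["CERV2"], LTR_LENGTHS["PtERV-2b"], rng),
        "PtERV-2c": _sibling_ltr(base_ltr["CERV2"], LTR_LENGTHS["PtERV-2c"], rng),
    }
    subs = {}
    for name, fam in FAMILY_OF.items():
        internal, spans = internals[fam]
        subs[name] = SubfamilyConsensus(
            name=name, family=fam, ltr=ltrs[name], internal=internal, gene_spans=spans
        )
    return ConsensusLibrary(subs)
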