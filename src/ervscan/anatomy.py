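"""Per-locus anatomy: target-site duplications, LTR pairs, ORF screening.

A classical retroviral integration duplicates 2-5 bp of host sequence on both
sides of the provirus, so a TSD is the hallmark separating classical
insertions from non-classical ones.  The TSD searcher looks for the longest
exact duplication, of length ``min_len..max_len``, ending immediately 5' of
the element and beginning immediately 3' of it.  The search ceiling defaults
to 6 bp (above the 2-5 bp classical range) so over-long duplications are
observed rather than silently capped.

ORF screening translates the internal region on the element strand in all
three frames; a gene is *intact* when a single-frame stop-free stretch covers
at least ``intact_fraction`` (default 0.95) of the gene's consensus length
within +-10% of its expected location, *disrupted* when present but below
that coverage, and *missing* when less than half of the expected span is
available.  An element with all four genes (gag, pro, pol, env) intact is
flagged retrotransposition-competent.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from .catalog import ErvLocus
from .io import revcomp

GENE_ORDER = ("gag", "pro", "pol", "env")


def longest_duplication(left: str, right: str, min_len: int, max_len: int
                        ) -> tuple[int, str]:
    """Longest k in [min_len, max_len] with left[-k:] == right[:k]; (0, "")
    when none."""
    best, seq = 0, ""
    hi = min(max_len, len(left), len(right))
    for k in range(min_len, hi + 1):
        if left[-k:] == right[:k]:
            best, seq = k, right[:k]
    return best, seq


@dataclass
class TsdResult:
    present: bool
    length: int
    sequence: str
    search_window_bp: int
    clipped: bool = False  # flank shorter than the search window


@dataclass
class OrfScreen:
    status: dict[str, str]          # gene -> intact | disrupted | missing
    coverage: dict[str, float]      # longest stop-free ORF / consensus length

    @property
    def rc_flag(self) -> bool:
        return all(s == "intact" for s in self.status.values())


def detect_tsd(genome: dict[str, str], locus: ErvLocus,
               min_len: int = 2, max_len: int = 6) -> TsdResult:
    """Longest exact target-site duplication flanking the locus."""
    seq = genome[locus.chrom]
    if not (0 <= locus.start < locus.end <= len(seq)):
        raise ValueError(f"{locus.locus_id}: span outside genome")
    left = seq[max(0, locus.start - max_len):locus.start]
    right = seq[locus.end:locus.end + max_len]
    clipped = len(left) < max_len or len(right) < max_len
    length, dup = longest_duplication(left, right, min_len, max_len)
    return TsdResult(present=length >= min_len, length=length, sequence=dup,
                     search_window_bp=max_len, clipped=clipped)


def pair_ltrs(genome: dict[str, str], locus: ErvLocus) -> tuple[str, str] | None:
    """Both LTR sequences oriented 5'->3' on the element strand, or None when
    the locus is not full length."""
    if locus.category != "full_length":
        return None
    seq = genome[locus.chrom]
    a = seq[locus.ltr5_span[0]:locus.ltr5_span[1]]
    b = seq[locus.ltr3_span[0]:locus.ltr3_span[1]]
    if locus.strand == "-":
        a, b = revcomp(a), revcomp(b)
    return a, b


def element_sequence(genome: dict[str, str], locus: ErvLocus) -> str:
    """The locus sequence in genome orientation."""
    return genome[locus.chrom][locus.start:locus.end]


def internal_sequence(genome: dict[str, str], locus: ErvLocus) -> str | None:
    """Concatenated internal region oriented 5'->3' on the element strand."""
    if not locus.internal_spans:
        return None
    seq = genome[locus.chrom]
    parts = [seq[a:b] for a, b in sorted(locus.internal_spans)]
    joined = "".join(parts)
    return revcomp(joined) if locus.strand == "-" else joined


def _stop_free_coverage(internal: str, frame: int, window: tuple[int, int]) -> int:
    """Longest stop-free stretch (nt) of `frame` intersected with `window`."""
    coding = internal[frame:]
    coding = coding[:len(coding) - len(coding) % 3]
    aa = str(Seq(coding).translate())
    stops = [frame + 3 * i for i, ch in enumerate(aa) if ch == "*"]
    bounds = [frame - 3] + stops + [frame + 3 * len(aa)]
    best = 0
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        run = (lo + 3, hi)  # nt interval free of stops
        ov = min(run[1], window[1]) - max(run[0], window[0])
        best = max(best, ov)
    return best


def screen_orfs(internal: str | None, gene_spans: dict[str, tuple[int, int]],
                offset: int = 0, intact_fraction: float = 0.95) -> OrfScreen:
    """Screen gag/pro/pol/env intactness of an element-strand internal region.

    ``offset`` is the consensus coordinate of ``internal``'s first base (for
    5'-truncated elements whose retained internal region starts mid-consensus).
    """
    status: dict[str, str] = {}
    coverage: dict[str, float] = {}
    for gene in GENE_ORDER:
        gs, ge = gene_spans[gene]
        glen = ge - gs
        rel = (gs - offset, ge - offset)
        if internal is None:
            status[gene], coverage[gene] = "missing", 0.0
            continue
        avail = min(rel[1], len(internal)) - max(rel[0], 0)
        if avail < 0.5 * glen:
            status[gene], coverage[gene] = "missing", max(0.0, avail / glen)
            continue
        slack = int(0.1 * glen)
        window = (max(0, rel[0] - slack), min(len(internal), rel[1] + slack))
        best = max(_stop_free_coverage(internal, f, window) for f in range(3))
        coverage[gene] = best / glen
        status[gene] = "intact" if coverage[gene] >= intact_fraction else "disrupted"
    return OrfScreen(status=status, coverage=coverage)
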