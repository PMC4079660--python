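"""Decide whether each locus is an ingroup-specific insertion.

The classic comparative test: extract 2 kb of flanking sequence on either
side of the element, locate both flanks in each outgroup genome, and inspect
the orthologous inter-flank interval.  An insertion younger than the
ingroup/outgroup split leaves an (essentially) empty interval in every
outgroup; a pre-divergence element leaves an element-sized interval whose
sequence matches the element.

Status per outgroup:

* ``element_absent``  -- inter-flank gap at most ``absence_threshold`` bp, or
  a larger gap whose sequence does NOT align to the element (that is deleted
  host sequence: the non-classical-insertion signature, with the gap size
  retained for deletion sizing).
* ``element_present`` -- gap at least ``presence_margin`` x element length
  AND the gap sequence aligns to the element at >= ``min_identity``.
* ``unmapped``        -- flanks not located (or located inconsistently), or
  an ambiguous partial-element gap.

Final call: ``ingroup_specific`` iff every mapped outgroup is element_absent
and at least one outgroup mapped; ``shared`` iff any outgroup is
element_present; ``unresolved`` iff all outgroups are unmapped.

Both flanks are required to land on the same outgroup chromosome, in the
same orientation, within 10 x the element length of each other, before a
presence/absence call is made; this guards against paralogous flank hits and
substitutes for the manual inspection step of the original screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._align import GenomeIndex, identity_at, global_identity, seed_locate
from .catalog import ErvLocus

DEFAULT_FLANK_BP = 2000


@dataclass
class Flanks:
    left: str
    right: str
    left_clipped: bool = False
    right_clipped: bool = False


@dataclass
class FlankHit:
    chrom: str
    start: int
    end: int
    identity: float


@dataclass
class MappingResult:
    status: str  # "mapped" | "unmapped"
    left: FlankHit | None = None
    right: FlankHit | None = None
    gap_bp: int | None = None          # orthologous inter-flank span (>= 0)
    gap_interval: tuple[str, int, int] | None = None


@dataclass
class OrthologCall:
    locus_id: str
    statuses: dict[str, str] = field(default_factory=dict)
    intervals: dict[str, tuple[str, int, int] | None] = field(default_factory=dict)
    outgroup_gaps: dict[str, int | None] = field(default_factory=dict)
    final_call: str = "unresolved"

    def finalize(self) -> "OrthologCall":
        statuses = list(self.statuses.values())
        if any(s == "element_present" for s in statuses):
            self.final_call = "shared"
        elif all(s == "unmapped" for s in statuses) or not statuses:
            self.final_call = "unresolved"
        elif all(s == "element_absent" for s in statuses if s != "unmapped"):
            self.final_call = "ingroup_specific"
        return self


def extract_flanks(genome: dict[str, str], locus: ErvLocus,
                   flank_bp: int = DEFAULT_FLANK_BP) -> Flanks:
    """Sequences immediately outside the locus span, clipped at chromosome
    ends with the clip recorded."""
    if flank_bp < 1:
        raise ValueError("flank_bp must be >= 1")
    seq = genome[locus.chrom]
    if not (0 <= locus.start < locus.end <= len(seq)):
        raise ValueError(f"{locus.locus_id}: locus span outside the genome")
    lo = max(0, locus.start - flank_bp)
    hi = min(len(seq), locus.end + flank_bp)
    return Flanks(
        left=seq[lo:locus.start], right=seq[locus.end:hi],
        left_clipped=lo > locus.start - flank_bp,
        right_clipped=hi < locus.end + flank_bp)


def _map_one_flank(flank: str, index: GenomeIndex, min_identity: float,
                   min_cov: float, n_seeds: int = 24,
                   min_votes: int = 2) -> FlankHit | None:
    if not flank:
        return None
    hit = seed_locate(flank, index, n_seeds=n_seeds)
    if hit is None or hit.votes < min_votes:
        return None
    if hit.runner_up_votes >= 0.8 * hit.votes and hit.runner_up_votes >= min_votes:
        return None  # paralogous/ambiguous placement
    target = index.genome[hit.chrom]
    start = hit.start
    if start < 0 or start + len(flank) > len(target):
        # flank runs past the contig end; evaluate the overlapping part
        usable_lo = max(0, start)
        usable_hi = min(len(target), start + len(flank))
        if (usable_hi - usable_lo) < min_cov * len(flank):
            return None
    ident = identity_at(flank, target, max(0, start))
    if ident < min_identity:
        return None
    return FlankHit(chrom=hit.chrom, start=start, end=start + len(flank),
                    identity=ident)


def map_flanks(flanks: Flanks, index: GenomeIndex, element_length: int,
               min_identity: float = 0.85, min_cov: float = 0.5,
               max_span_factor: int = 10) -> MappingResult:
    """Locate both flanks in one outgroup and measure the inter-flank gap."""
    left = _map_one_flank(flanks.left, index, min_identity, min_cov)
    right = _map_one_flank(flanks.right, index, min_identity, min_cov)
    if left is None or right is None or left.chrom != right.chrom:
        return MappingResult(status="unmapped", left=left, right=right)
    gap = right.start - left.end
    if gap < -50 or gap > max_span_factor * max(element_length, 1000):
        return MappingResult(status="unmapped", left=left, right=right)
    gap = max(0, gap)
    return MappingResult(status="mapped", left=left, right=right, gap_bp=gap,
                         gap_interval=(left.chrom, left.end, right.start))


def call_specificity(locus: ErvLocus, element_seq: str,
                     mappings: dict[str, MappingResult],
                     outgroup_genomes: dict[str, dict[str, str]],
                     absence_threshold: int = 50,
                     presence_margin: float = 0.5,
                     min_identity: float = 0.85) -> OrthologCall:
    """Combine per-outgroup flank mappings into a specificity call."""
    if not mappings:
        raise ValueError("at least one outgroup is required")
    call = OrthologCall(locus_id=locus.locus_id)
    element_length = max(len(element_seq), 1)
    for name, mapping in mappings.items():
        if mapping.status != "mapped":
            call.statuses[name] = "unmapped"
            call.intervals[name] = None
            call.outgroup_gaps[name] = None
            continue
        call.intervals[name] = mapping.gap_interval
        call.outgroup_gaps[name] = mapping.gap_bp
        gap = mapping.gap_bp
        if gap <= absence_threshold:
            call.statuses[name] = "element_absent"
            continue
        chrom, lo, hi = mapping.gap_interval
        gap_seq = outgroup_genomes[name][chrom][max(0, lo):hi]
        ident = global_identity(gap_seq, element_seq)
        if ident >= min_identity:
            if gap >= presence_margin * element_length:
                call.statuses[name] = "element_present"
            else:
                call.statuses[name] = "unmapped"  # ambiguous partial element
        else:
            # gap sequence is unrelated host sequence: the element itself is
            # absent and the gap is deletion evidence (non-classical insertion)
            call.statuses[name] = "element_absent"
    return call.finalize()
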