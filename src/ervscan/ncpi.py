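"""Non-classical insertions: TSD-absent, deletion-associated, microhomology.

A non-classical insertion (NCPI) is an element that integrated without the
TSD hallmark and whose arrival coincided with the loss of host sequence; the
favoured interpretation is a double-strand-break repair remnant, and short
(2-3 bp) microhomology between the element terminus and the flank at the
breakpoint junction is the signature of end-joining repair.

Calling rule: a locus is an NCPI candidate iff (a) no 2-5 bp TSD was detected
AND (b) at least one outgroup mapped at the orthologous position.  The
orthologous inter-flank gap sizes the deletion (consensus = median across
outgroups); a TSD-absent locus whose orthologous gap is below the absence
threshold is retained as an insertion-only NCPI with deletion size 0.
Requiring a mapped outgroup, and never TSD absence alone, guards against the
high chance rate of spurious short TSDs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from statistics import median

import pandas as pd

from ._decimal import round_half_up

log = logging.getLogger(__name__)


def longest_junction_overlap(upstream: str, downstream: str, max_len: int = 10) -> int:
    """Longest m <= max_len with upstream[-m:] == downstream[:m].

    At a left junction call it with (retained left flank, element sequence);
    at a right junction with (element sequence, retained right flank).
    """
    best = 0
    hi = min(max_len, len(upstream), len(downstream))
    for m in range(1, hi + 1):
        if upstream[-m:] == downstream[:m]:
            best = m
    return best


@dataclass
class MicrohomologyScan:
    left_len: int
    left_seq: str
    right_len: int
    right_seq: str

    @property
    def max_len(self) -> int:
        return max(self.left_len, self.right_len)


@dataclass
class NcpiEvent:
    locus_id: str
    tsd_absent: bool
    deletion_size_bp: int
    left_breakpoint: int
    right_breakpoint: int
    microhomology_left: str = ""
    microhomology_right: str = ""
    per_outgroup_deletion: dict[str, int] = field(default_factory=dict)
    supporting_outgroups: int = 0
    size_disagreement: bool = False
    low_confidence: bool = False

    @property
    def microhomology_len(self) -> int:
        return max(len(self.microhomology_left), len(self.microhomology_right))


def scan_microhomology(element_seq: str, left_flank: str, right_flank: str,
                       max_len: int = 10) -> MicrohomologyScan:
    """Microhomology between the element termini and the retained flanks."""
    ml = longest_junction_overlap(left_flank, element_seq, max_len)
    mr = longest_junction_overlap(element_seq, right_flank, max_len)
    return MicrohomologyScan(
        left_len=ml, left_seq=element_seq[:ml] if ml else "",
        right_len=mr, right_seq=element_seq[len(element_seq) - mr:] if mr else "")


def size_deletion(outgroup_gaps: dict[str, int], residual_ingroup_gap: int = 0,
                  disagreement_fraction: float = 0.10
                  ) -> tuple[int, dict[str, int], bool, bool]:
    """Deletion size per outgroup and the median consensus.

    Returns (consensus, per_outgroup, disagreement_flag, low_confidence_flag).
    Per outgroup the deletion is the orthologous inter-flank span minus the
    residual ingroup inter-flank span (excluding the element itself).
    """
    if not outgroup_gaps:
        raise ValueError("no mapped outgroup to size the deletion against")
    sizes = {name: max(0, gap - residual_ingroup_gap)
             for name, gap in outgroup_gaps.items()}
    values = sorted(sizes.values())
    consensus = int(round(median(values)))
    low_confidence = len(values) < 2
    disagreement = False
    if len(values) >= 2 and consensus > 0:
        spread = max(values) - min(values)
        disagreement = spread > disagreement_fraction * consensus
    return consensus, sizes, disagreement, low_confidence


def call_ncpi_candidates(tsd_results: dict, ortholog_calls: dict,
                         loci_by_id: dict, genome: dict[str, str],
                         absence_threshold: int = 50,
                         classical_range: tuple[int, int] = (2, 5),
                         flank_scan_bp: int = 20,
                         max_microhomology: int = 10) -> list[NcpiEvent]:
    """Identify NCPI events among ingroup-specific loci.

    ``tsd_results`` maps locus_id -> TsdResult, ``ortholog_calls`` maps
    locus_id -> OrthologCall (which carries the per-outgroup inter-flank
    gaps).  Loci unmapped in every outgroup are excluded and logged.
    """
    events: list[NcpiEvent] = []
    for locus_id, tsd in sorted(tsd_results.items()):
        call = ortholog_calls[locus_id]
        if call.final_call != "ingroup_specific":
            continue
        has_classical_tsd = (tsd.present
                             and classical_range[0] <= tsd.length <= classical_range[1])
        if has_classical_tsd:
            continue
        gaps = {name: g for name, g in call.outgroup_gaps.items() if g is not None}
        if not gaps:
            log.info("locus %s TSD-absent but unmapped in all outgroups; "
                     "not callable as NCPI", locus_id)
            continue
        locus = loci_by_id[locus_id]
        consensus, sizes, disagreement, low_conf = size_deletion(
            {n: g for n, g in gaps.items()})
        if consensus <= absence_threshold:
            consensus = 0  # insertion-only NCPI
        seq = genome[locus.chrom]
        element_seq = seq[locus.start:locus.end]
        left_flank = seq[max(0, locus.start - flank_scan_bp):locus.start]
        right_flank = seq[locus.end:locus.end + flank_scan_bp]
        mh = scan_microhomology(element_seq, left_flank, right_flank,
                                max_len=max_microhomology)
        events.append(NcpiEvent(
            locus_id=locus_id, tsd_absent=True,
            deletion_size_bp=consensus,
            left_breakpoint=locus.start, right_breakpoint=locus.end,
            microhomology_left=mh.left_seq, microhomology_right=mh.right_seq,
            per_outgroup_deletion=sizes,
            supporting_outgroups=len(sizes),
            size_disagreement=disagreement, low_confidence=low_conf))
    return events


def ncpi_report(events: list[NcpiEvent]) -> dict:
    """Summary table: event count, total/mean/range of deletion sizes.

    The range is max - min of the per-event deletion sizes; the mean is
    rounded half-up to an integer number of base pairs.
    """
    if not events:
        return {"n_events": 0, "total_deletion_bp": 0,
                "mean_deletion_bp": 0, "range_deletion_bp": 0}
    sizes = [e.deletion_size_bp for e in events]
    total = sum(sizes)
    return {
        "n_events": len(events),
        "total_deletion_bp": total,
        "mean_deletion_bp": int(round_half_up(total / len(sizes), 0)),
        "range_deletion_bp": max(sizes) - min(sizes),
    }


def events_to_dataframe(events: list[NcpiEvent]) -> pd.DataFrame:
    rows = []
    for e in events:
        rows.append({
            "locus_id": e.locus_id, "deletion_size_bp": e.deletion_size_bp,
            "left_breakpoint": e.left_breakpoint,
            "right_breakpoint": e.right_breakpoint,
            "microhomology_left": e.microhomology_left,
            "microhomology_right": e.microhomology_right,
            "microhomology_len": e.microhomology_len,
            "supporting_outgroups": e.supporting_outgroups,
            "size_disagreement": e.size_disagreement,
            "low_confidence": e.low_confidence,
        })
    return pd.DataFrame(rows)
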