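"""Parse RepeatMasker annotation and defragment hits into proviral loci.

RepeatMasker reports an LTR retroelement as separate fragments: one row per
LTR and one or more rows for the internal region.  ``defragment`` merges
same-chromosome, same-strand fragments whose inter-fragment gap does not
exceed ``max_gap_bp`` into one locus and assigns a structural category:

* ``full_length`` -- LTR, internal run, LTR (colinear, same strand)
* ``solo_ltr``    -- exactly one LTR, no internal sequence
* ``truncated``   -- internal sequence with one or zero LTRs
* ``unknown``     -- anything else (e.g. two LTRs without internal sequence,
  or an LTR-internal-LTR chain with inconsistent subfamily labels)

Coordinates are 1-based inclusive in the file and 0-based half-open in
memory.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

log = logging.getLogger(__name__)

CATEGORY_ORDER = ("full_length", "solo_ltr", "truncated", "unknown")

_ROLE_SUFFIX = re.compile(r"(?:[-_](?:LTR|int|I))$")


class RepeatMaskerParseError(ValueError):
    pass


@dataclass
class RepeatHit:
    """One repeat fragment (one .out data row); 0-based half-open span."""

    chrom: str
    start: int
    end: int
    strand: str
    repeat_name: str
    repeat_class: str
    divergence_pct: float
    hit_id: int

    @property
    def subfamily(self) -> str:
        return _ROLE_SUFFIX.sub("", self.repeat_name)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ErvLocus:
    locus_id: str
    chrom: str
    start: int
    end: int
    strand: str
    category: str
    ltr5_span: tuple[int, int] | None
    ltr3_span: tuple[int, int] | None
    internal_spans: list[tuple[int, int]]
    subfamily: str | None
    member_hit_ids: list[int] = field(default_factory=list)

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def length(self) -> int:
        return self.end - self.start


def parse_repeatmasker_out(path: str | Path,
                           name_prefixes: tuple[str, ...] | None = None
                           ) -> list[RepeatHit]:
    """Read a RepeatMasker .out file (3 header lines, then 15-column rows).

    ``name_prefixes`` optionally restricts the hits to repeat names starting
    with one of the given prefixes (the repName filter of the original
    table-browser extraction step).
    """
    hits: list[RepeatHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if lineno <= 3 or not line.strip():
                continue
            fields = line.split()
            if len(fields) < 15:
                raise RepeatMaskerParseError(
                    f"{path}: line {lineno}: expected >= 15 columns, "
                    f"got {len(fields)}")
            try:
                start_1b, end_1b = int(fields[5]), int(fields[6])
                divergence = float(fields[1])
            except ValueError as exc:
                raise RepeatMaskerParseError(
                    f"{path}: line {lineno}: malformed numeric field "
                    f"({exc})") from None
            name = fields[9]
            if name_prefixes is not None and not name.startswith(tuple(name_prefixes)):
                continue
            strand = "-" if fields[8] == "C" else "+"
            if start_1b > end_1b:
                raise RepeatMaskerParseError(
                    f"{path}: line {lineno}: begin > end")
            hits.append(RepeatHit(
                chrom=fields[4], start=start_1b - 1, end=end_1b,
                strand=strand, repeat_name=name, repeat_class=fields[10],
                divergence_pct=divergence, hit_id=len(hits)))
    return hits


def _drop_nested(hits: list[RepeatHit]) -> tuple[list[RepeatHit], list[int]]:
    """If one hit lies entirely inside another, keep the longer (deterministic
    tie-break: the earlier-starting, then lower-id hit wins)."""
    kept: list[RepeatHit] = []
    dropped: list[int] = []
    for h in sorted(hits, key=lambda h: (h.start, -(h.end - h.start), h.hit_id)):
        if kept and h.start >= kept[-1].start and h.end <= kept[-1].end:
            dropped.append(h.hit_id)
        else:
            kept.append(h)
    return kept, dropped


def defragment(hits: list[RepeatHit], max_gap_bp: int = 1000,
               ltr_name_set: set[str] | None = None,
               internal_name_set: set[str] | None = None
               ) -> tuple[list[ErvLocus], list[int]]:
    """Merge repeat fragments into loci; returns (loci, ignored_hit_ids).

    Hits whose repeat name is in neither name set are ignored with a logged
    warning.  When both name sets are None, roles are inferred from the
    conventional ``*_LTR`` / ``*-int`` name suffixes.
    """
    def role_of(name: str) -> str | None:
        if ltr_name_set is not None or internal_name_set is not None:
            if ltr_name_set and name in ltr_name_set:
                return "ltr"
            if internal_name_set and name in internal_name_set:
                return "internal"
            return None
        if name.endswith("_LTR"):
            return "ltr"
        if name.endswith(("-int", "_int", "-I", "_I")):
            return "internal"
        return None

    ignored: list[int] = []
    usable: list[RepeatHit] = []
    for h in hits:
        if role_of(h.repeat_name) is None:
            log.warning("ignoring hit %d with unknown repeat name %r",
                        h.hit_id, h.repeat_name)
            ignored.append(h.hit_id)
        else:
            usable.append(h)

    loci: list[ErvLocus] = []
    groups: dict[tuple[str, str], list[RepeatHit]] = {}
    for h in usable:
        groups.setdefault((h.chrom, h.strand), []).append(h)

    chains: list[list[RepeatHit]] = []
    for (chrom, strand) in sorted(groups):
        ordered, nested = _drop_nested(groups[(chrom, strand)])
        ignored.extend(nested)
        chain: list[RepeatHit] = []
        for h in ordered:
            if chain and h.start - chain[-1].end > max_gap_bp:
                chains.append(chain)
                chain = []
            chain.append(h)
        if chain:
            chains.append(chain)

    for i, chain in enumerate(sorted(chains, key=lambda c: (c[0].chrom, c[0].start))):
        loci.append(_classify_chain(chain, f"locus_{i + 1:05d}", role_of))
    return loci, ignored


def _classify_chain(chain: list[RepeatHit], locus_id: str, role_of) -> ErvLocus:
    chain = sorted(chain, key=lambda h: h.start)
    roles = [role_of(h.repeat_name) for h in chain]
    ltr_spans = [(h.start, h.end) for h, r in zip(chain, roles) if r == "ltr"]
    # merge consecutive internal fragments (no LTR in between) into runs
    internal_spans: list[tuple[int, int]] = []
    prev_role = None
    for h, r in zip(chain, roles):
        if r == "internal":
            if prev_role == "internal":
                internal_spans[-1] = (internal_spans[-1][0],
                                      max(internal_spans[-1][1], h.end))
            else:
                internal_spans.append((h.start, h.end))
        prev_role = r

    n_ltr, has_int = len(ltr_spans), bool(internal_spans)
    subfams = Counter(h.subfamily for h in chain)
    top = subfams.most_common()
    subfamily = top[0][0] if (len(top) == 1 or top[0][1] > top[1][1]) else None
    consistent = len(subfams) == 1

    category = "unknown"
    if n_ltr == 2 and has_int:
        # full length requires LTR - internal - LTR colinearity
        if (ltr_spans[0][1] <= internal_spans[0][0]
                and internal_spans[-1][1] <= ltr_spans[1][0]):
            category = "full_length" if consistent else "unknown"
    elif n_ltr == 1 and not has_int:
        category = "solo_ltr"
    elif has_int and n_ltr <= 1:
        category = "truncated"

    strand = chain[0].strand
    if category == "full_length" or (category == "unknown" and n_ltr == 2):
        if strand == "+":
            ltr5, ltr3 = ltr_spans[0], ltr_spans[1]
        else:
            ltr5, ltr3 = ltr_spans[1], ltr_spans[0]
    elif n_ltr == 1:
        only = ltr_spans[0]
        if category == "truncated" and internal_spans:
            # one LTR next to internal sequence: decide 5' vs 3' from geometry
            before_internal = only[1] <= internal_spans[0][0]
            is_five_prime = before_internal if strand == "+" else not before_internal
            ltr5, ltr3 = (only, None) if is_five_prime else (None, only)
        else:
            ltr5, ltr3 = only, None
    else:
        ltr5 = ltr3 = None

    return ErvLocus(
        locus_id=locus_id, chrom=chain[0].chrom,
        start=min(h.start for h in chain), end=max(h.end for h in chain),
        strand=strand, category=category, ltr5_span=ltr5, ltr3_span=ltr3,
        internal_spans=internal_spans, subfamily=subfamily,
        member_hit_ids=[h.hit_id for h in chain])


def catalog_summary(loci: list[ErvLocus]) -> dict:
    """Per-category and per-subfamily counts plus the total."""
    by_category = {c: 0 for c in CATEGORY_ORDER}
    by_subfamily: Counter = Counter()
    for locus in loci:
        by_category[locus.category] += 1
        by_subfamily[locus.subfamily or "unassigned"] += 1
    return {
        "by_category": by_category,
        "by_subfamily": dict(sorted(by_subfamily.items(), key=lambda kv: kv[0])),
        "total": len(loci),
    }


def loci_to_dataframe(loci: list[ErvLocus]) -> pd.DataFrame:
    rows = []
    for l in loci:
        rows.append({
            "locus_id": l.locus_id, "chrom": l.chrom, "start": l.start,
            "end": l.end, "strand": l.strand, "category": l.category,
            "subfamily": l.subfamily if l.subfamily else "unassigned",
            "n_fragments": len(l.member_hit_ids),
        })
    return pd.DataFrame(rows)


def write_bed(loci: list[ErvLocus], path: str | Path) -> None:
    """BED6 export: name = locus_id, score = 0."""
    with open(path, "w") as fh:
        for l in sorted(loci, key=lambda l: (l.chrom, l.start)):
            fh.write(f"{l.chrom}\t{l.start}\t{l.end}\t{l.locus_id}\t0\t{l.strand}\n")
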