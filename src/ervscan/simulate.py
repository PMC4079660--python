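"""Synthetic genomes with planted ERV events and a machine-readable truth ledger.

The generator emulates the comparative setting the pipeline is built for: an
ancestral genome shared by an ingroup and ``k`` outgroups; post-divergence
insertions present only in the ingroup (full-length proviruses with 2-5 bp
target-site duplications, solitary LTRs from LTR-LTR recombination, truncated
copies); optional pre-divergence "decoy" elements shared by all genomes; and
non-classical insertions (NCPIs) that replace a genomic segment, lack a TSD
and optionally carry 2-3 bp of junction microhomology.

Design notes
------------
* Placement keeps a >= ``min_spacing_bp`` gap between event footprints so the
  2-kb flanks used downstream never overlap another event, and rejects sites
  whose flanks are not unique in the ancestor.
* Planted hallmark signatures (TSD length/sequence, microhomology lengths,
  TSD absence at NCPI junctions) are validated locally at planting time and
  the site is resampled on chance collisions, so the ledger is an exact
  oracle for the detectors.
* LTRs of one element are identical at insertion and then aged independently
  with a per-site Poisson substitution process (ti:tv = 2:1) at
  ``element_age_myr * ltr_mutation_rate`` expected substitutions per site.
* Internal regions carry no random drift: retrotransposition-competent
  elements keep a pristine internal region and non-competent ones receive
  deliberately injected premature stop codons, so the ledger's per-gene
  ``orf_intact`` flags are constructed truth rather than being re-derived
  with the screening code.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._mutate import mutate_per_site, mutate_seq, seq_to_array, array_to_seq
from .anatomy import longest_duplication
from .ncpi import longest_junction_overlap
from .consensus import ConsensusLibrary, SubfamilyConsensus, GENES, default_library
from .io import revcomp, write_fasta

CATEGORIES = ("full_length", "solo_ltr", "truncated", "ncpi")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class ConfigError(ValueError):
    """Invalid simulation configuration."""


class PlacementError(RuntimeError):
    """A sampled insertion site collided with an existing event or failed
    hallmark validation; the caller should resample."""


@dataclass
class SimulationConfig:
    seed: int = 0
    ancestor_length_bp: int = 1_000_000
    n_chromosomes: int = 1
    gc_fraction: float = 0.41
    n_full_length: int = 10
    n_solo_ltr: int = 10
    n_truncated: int = 2
    n_ncpi: int = 2
    n_decoy_shared: int = 0
    n_outgroups: int = 3
    tsd_length_range: tuple[int, int] = (2, 5)
    ncpi_deletion_range_bp: tuple[int, int] = (100, 5000)
    microhomology_range: tuple[int, int] = (2, 3)
    microhomology_prob: float = 5.0 / 7.0
    ltr_mutation_rate: float = 0.0023  # substitutions / site / myr
    element_age_myr: float = 2.0
    decoy_age_myr: float = 8.0
    outgroup_divergence: float = 0.01  # substitutions / site
    rc_fraction: float = 0.5
    min_spacing_bp: int = 5000
    flank_bp: int = 2000
    split_internal_fragments: bool = False
    split_gap_bp: int = 80

    def validate(self) -> None:
        if self.ancestor_length_bp <= 0:
            raise ConfigError("ancestor_length_bp must be positive")
        if self.n_chromosomes < 1:
            raise ConfigError("n_chromosomes must be >= 1")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ConfigError("gc_fraction must lie in [0, 1]")
        for name in ("n_full_length", "n_solo_ltr", "n_truncated", "n_ncpi",
                     "n_decoy_shared", "n_outgroups"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        lo, hi = self.tsd_length_range
        if not (1 <= lo <= hi <= 10):
            raise ConfigError("tsd_length_range must lie within [1, 10]")
        lo, hi = self.microhomology_range
        if not (0 <= lo <= hi <= 10):
            raise ConfigError("microhomology_range must lie within [0, 10]")
        lo, hi = self.ncpi_deletion_range_bp
        if lo < 0 or hi < lo:
            raise ConfigError("invalid ncpi_deletion_range_bp")
        for name in ("ltr_mutation_rate", "element_age_myr", "decoy_age_myr",
                     "outgroup_divergence"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")


@dataclass
class TruthEvent:
    """One planted event, with its final (derived-genome) coordinates.

    ``start``/``end`` are 0-based half-open and delimit the element itself
    (TSD copies sit outside the span, in the flanks).  ``structure`` records
    the structural class of NCPI events (which are themselves full-length or
    solitary-LTR shaped); for classical events it equals ``category``.
    """

    event_id: str
    category: str
    structure: str
    chrom: str
    strand: str
    start: int
    end: int
    insertion_point_ancestor: int
    tsd: str | None
    deletion_size_bp: int
    microhomology_left: str
    microhomology_right: str
    subfamily: str
    planted_age_myr: float
    orf_intact: dict[str, bool] | None
    ltr5_span: tuple[int, int] | None
    ltr3_span: tuple[int, int] | None
    internal_spans: list[tuple[int, int]] = field(default_factory=list)

    @property
    def rc_flag(self) -> bool:
        return bool(self.orf_intact) and all(self.orf_intact.values())


@dataclass
class TruthLedger:
    events: list[TruthEvent] = field(default_factory=list)
    decoys: list[TruthEvent] = field(default_factory=list)

    def validate(self, genome: dict[str, str]) -> None:
        for ev in self.events:
            if not (0 <= ev.start < ev.end <= len(genome[ev.chrom])):
                raise ValueError(f"{ev.event_id}: coordinates outside genome")
            if ev.category == "ncpi":
                if ev.tsd is not None or ev.deletion_size_bp < 0:
                    raise ValueError(f"{ev.event_id}: inconsistent NCPI record")
            elif ev.deletion_size_bp != 0:
                raise ValueError(f"{ev.event_id}: deletion on classical event")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "events": [dataclasses.asdict(e) for e in self.events],
            "decoys": [dataclasses.asdict(e) for e in self.decoys],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthLedger":
        payload = json.loads(Path(path).read_text())

        def build(d):
            for k in ("ltr5_span", "ltr3_span"):
                if d[k] is not None:
                    d[k] = tuple(d[k])
            d["internal_spans"] = [tuple(s) for s in d["internal_spans"]]
            return TruthEvent(**d)

        return cls(
            events=[build(d) for d in payload["events"]],
            decoys=[build(d) for d in payload["decoys"]],
        )


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    library: ConsensusLibrary
    ancestor: dict[str, str]
    ingroup: dict[str, str]
    outgroups: list[dict[str, str]]
    ledger: TruthLedger

    def write(self, outdir: str | Path) -> dict[str, Path]:
        return write_truth(self, outdir)


# ---------------------------------------------------------------------------
# ancestor and outgroups

def generate_ancestor(config: SimulationConfig,
                      rng: np.random.Generator | None = None) -> dict[str, str]:
    """Random i.i.d. ancestor split into ``n_chromosomes`` chromosomes."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    gc = config.gc_fraction
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    n, k = config.ancestor_length_bp, config.n_chromosomes
    lengths = [n // k] * k
    lengths[-1] += n - sum(lengths)
    return {
        f"chr{i + 1}": array_to_seq(rng.choice(_BASES, size=m, p=p))
        for i, m in enumerate(lengths)
    }


def derive_outgroups(ancestor: dict[str, str], config: SimulationConfig, k: int,
                     rng: np.random.Generator | None = None) -> list[dict[str, str]]:
    """k independent outgroups: the ancestor with per-site substitutions at
    ``outgroup_divergence`` and no ingroup-specific events."""
    if k < 1:
        raise ConfigError("need at least one outgroup")
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    out = []
    for _ in range(k):
        out.append({
            chrom: array_to_seq(
                mutate_per_site(seq_to_array(seq), config.outgroup_divergence, rng))
            for chrom, seq in ancestor.items()
        })
    return out


# ---------------------------------------------------------------------------
# element construction

@dataclass
class _Element:
    seq: str
    strand: str
    subfamily: str
    structure: str
    ltr5_rel: tuple[int, int] | None
    ltr3_rel: tuple[int, int] | None
    internal_rel: list[tuple[int, int]]
    orf_intact: dict[str, bool] | None
    age: float


def _inject_stop(internal: str, span: tuple[int, int]) -> str:
    """Replace the middle codon of a gene with TAA (premature stop)."""
    gs, ge = span
    codon = gs + 3 * (((ge - gs) // 3) // 2)
    return internal[:codon] + "TAA" + internal[codon + 3:]


def _flip_span(span, total):
    a, b = span
    return (total - b, total - a)


def build_element(cons: SubfamilyConsensus, structure: str, age: float,
                  strand: str, rate: float, rng: np.random.Generator,
                  disrupt_genes: frozenset[str] = frozenset(),
                  clip: tuple[str, float] | None = None) -> _Element:
    """Assemble one element sequence plus its role spans and truth flags."""
    mu = age * rate
    if structure == "solo_ltr":
        ltr = mutate_seq(cons.ltr, mu, rng)
        seq = ltr
        ltr5_rel, ltr3_rel, internal_rel = (0, len(ltr)), None, []
        orf = None
    else:
        ltr5 = mutate_seq(cons.ltr, mu, rng)
        ltr3 = mutate_seq(cons.ltr, mu, rng)
        internal = cons.internal
        orf = {g: True for g in GENES}
        for g in disrupt_genes:
            internal = _inject_stop(internal, cons.gene_spans[g])
            orf[g] = False
        if structure == "full_length":
            seq = ltr5 + internal + ltr3
            n5, ni = len(ltr5), len(internal)
            ltr5_rel = (0, n5)
            internal_rel = [(n5, n5 + ni)]
            ltr3_rel = (n5 + ni, n5 + ni + len(ltr3))
        elif structure == "truncated":
            side, frac = clip if clip is not None else ("3p", 0.5)
            ni = len(internal)
            cut = int(ni * frac)
            if side == "3p":  # keep 5'LTR + internal prefix
                kept = internal[:cut]
                seq = ltr5 + kept
                ltr5_rel = (0, len(ltr5))
                internal_rel = [(len(ltr5), len(ltr5) + cut)]
                ltr3_rel = None
                retained = (0, cut)
            else:  # keep internal suffix + 3'LTR
                kept = internal[cut:]
                seq = kept + ltr3
                ltr5_rel = None
                internal_rel = [(0, ni - cut)]
                ltr3_rel = (ni - cut, ni - cut + len(ltr3))
                retained = (cut, ni)
            for g, (gs, ge) in cons.gene_spans.items():
                if not (retained[0] <= gs and ge <= retained[1]):
                    orf[g] = False
        else:
            raise ValueError(f"unknown structure {structure!r}")
    if strand == "-":
        total = len(seq)
        seq = revcomp(seq)
        ltr5_rel = _flip_span(ltr5_rel, total) if ltr5_rel else None
        ltr3_rel = _flip_span(ltr3_rel, total) if ltr3_rel else None
        internal_rel = sorted(_flip_span(s, total) for s in internal_rel)
    return _Element(seq, strand, cons.name, structure,
                    ltr5_rel, ltr3_rel, internal_rel, orf, age)


# ---------------------------------------------------------------------------
# planting

_VALID_W = 16  # context window for local hallmark validation


def _validate_classical(anc: str, site: int, tsd_len: int) -> str:
    """Check that the planted TSD will be recovered exactly; return the TSD."""
    tsd = anc[site:site + tsd_len]
    if len(tsd) < tsd_len or any(b not in "ACGT" for b in tsd):
        raise PlacementError("target site truncated or ambiguous")
    leftctx = anc[max(0, site + tsd_len - _VALID_W):site + tsd_len]
    rightctx = anc[site:site + _VALID_W]
    found, _ = longest_duplication(leftctx, rightctx, 2, 6)
    if found != tsd_len:
        raise PlacementError("chance TSD extension/collision at target site")
    return tsd


def _validate_ncpi(anc: str, site: int, deletion: int, elem: str,
                   mh_left: int, mh_right: int) -> None:
    """Check TSD absence and exact microhomology recovery at both junctions."""
    leftctx = anc[max(0, site - _VALID_W):site - mh_left] + elem[:mh_left] if mh_left \
        else anc[max(0, site - _VALID_W):site]
    rt = site + deletion
    rightctx = (elem[-mh_right:] if mh_right else "") + \
        anc[rt + mh_right:rt + mh_right + _VALID_W]
    tsd_found, _ = longest_duplication(leftctx, rightctx, 2, 6)
    if tsd_found:
        raise PlacementError("chance TSD at NCPI junction")
    if longest_junction_overlap(leftctx, elem, 10) != mh_left:
        raise PlacementError("left microhomology not exactly recoverable")
    if longest_junction_overlap(elem, rightctx, 10) != mh_right:
        raise PlacementError("right microhomology not exactly recoverable")


def plant_element(genome: dict[str, str], chrom: str, site: int,
                  cons: SubfamilyConsensus, category: str,
                  config: SimulationConfig, rng: np.random.Generator, *,
                  age: float | None = None, strand: str = "+",
                  disrupt_genes: frozenset[str] = frozenset(),
                  clip: tuple[str, float] | None = None,
                  occupied: list[tuple[int, int]] | None = None,
                  event_id: str = "ev") -> tuple[dict[str, str], TruthEvent]:
    """Plant one classical insertion (full_length / solo_ltr / truncated) with
    an exact duplicated target site of sampled length.

    Raises :class:`PlacementError` when the site collides with a previously
    planted element (``occupied`` intervals, genome coordinates) or a chance
    sequence coincidence would corrupt the hallmark; callers resample.
    """
    if category not in ("full_length", "solo_ltr", "truncated"):
        raise ValueError(f"not a classical category: {category!r}")
    anc = genome[chrom]
    if not 0 < site < len(anc):
        raise PlacementError("site outside chromosome")
    if occupied and any(lo <= site < hi for lo, hi in occupied):
        raise PlacementError("site inside a previously planted element")
    if age is None:
        age = config.element_age_myr
    elem = build_element(cons, category, age, strand, config.ltr_mutation_rate,
                         rng, disrupt_genes=disrupt_genes, clip=clip)
    tsd_len = int(rng.integers(config.tsd_length_range[0],
                               config.tsd_length_range[1] + 1))
    tsd = _validate_classical(anc, site, tsd_len)
    derived = anc[:site + tsd_len] + elem.seq + anc[site:]
    start = site + tsd_len
    end = start + len(elem.seq)
    shift = lambda sp: (sp[0] + start, sp[1] + start) if sp else None
    event = TruthEvent(
        event_id=event_id, category=category, structure=category,
        chrom=chrom, strand=strand, start=start, end=end,
        insertion_point_ancestor=site, tsd=tsd, deletion_size_bp=0,
        microhomology_left="", microhomology_right="",
        subfamily=cons.name, planted_age_myr=age, orf_intact=elem.orf_intact,
        ltr5_span=shift(elem.ltr5_rel), ltr3_span=shift(elem.ltr3_rel),
        internal_spans=[shift(s) for s in elem.internal_rel],
    )
    out = dict(genome)
    out[chrom] = derived
    return out, event


def plant_ncpi(genome: dict[str, str], chrom: str, site: int,
               cons: SubfamilyConsensus, config: SimulationConfig,
               rng: np.random.Generator, *, age: float | None = None,
               strand: str = "+", structure: str | None = None,
               deletion_size: int | None = None,
               microhomology: tuple[int, int] | None = None,
               occupied: list[tuple[int, int]] | None = None,
               event_id: str = "ev") -> tuple[dict[str, str], TruthEvent]:
    """Plant a non-classical insertion: a genomic segment of sampled size is
    replaced by the element (full-length or solitary LTR), with no TSD and
    optional junction microhomology.

    Microhomology is realised by rewriting the <= 3 retained flank bases next
    to each junction so they equal the element terminus; outgroups keep the
    ancestral bases.
    """
    anc = genome[chrom]
    if age is None:
        age = config.element_age_myr
    if structure is None:
        structure = "solo_ltr" if rng.random() < 4.0 / 7.0 else "full_length"
    if deletion_size is None:
        lo, hi = config.ncpi_deletion_range_bp
        deletion_size = int(rng.integers(lo, hi + 1))
    if site + deletion_size + 1 > len(anc) or site < 1:
        raise PlacementError("deletion window does not fit in the chromosome")
    if occupied and any(lo <= site < hi or lo < site + deletion_size <= hi
                        for lo, hi in occupied):
        raise PlacementError("site inside a previously planted element")
    elem = build_element(cons, structure, age, strand,
                         config.ltr_mutation_rate, rng)
    if microhomology is None:
        mlo, mhi = config.microhomology_range
        mh_l = int(rng.integers(mlo, mhi + 1)) if rng.random() < config.microhomology_prob else 0
        mh_r = int(rng.integers(mlo, mhi + 1)) if rng.random() < config.microhomology_prob else 0
    else:
        mh_l, mh_r = microhomology
    _validate_ncpi(anc, site, deletion_size, elem.seq, mh_l, mh_r)
    left = anc[:site - mh_l] + elem.seq[:mh_l] if mh_l else anc[:site]
    rt = site + deletion_size
    right = (elem.seq[-mh_r:] + anc[rt + mh_r:]) if mh_r else anc[rt:]
    derived = left + elem.seq + right
    start, end = site, site + len(elem.seq)
    shift = lambda sp: (sp[0] + start, sp[1] + start) if sp else None
    event = TruthEvent(
        event_id=event_id, category="ncpi", structure=structure,
        chrom=chrom, strand=strand, start=start, end=end,
        insertion_point_ancestor=site, tsd=None, deletion_size_bp=deletion_size,
        microhomology_left=elem.seq[:mh_l], microhomology_right=elem.seq[-mh_r:] if mh_r else "",
        subfamily=cons.name, planted_age_myr=age, orf_intact=elem.orf_intact,
        ltr5_span=shift(elem.ltr5_rel), ltr3_span=shift(elem.ltr3_rel),
        internal_spans=[shift(s) for s in elem.internal_rel],
    )
    out = dict(genome)
    out[chrom] = derived
    return out, event


# ---------------------------------------------------------------------------
# whole-dataset orchestration

def _flanks_unique(genome: dict[str, str], chrom: str, left_end: int,
                   right_start: int, flank_bp: int, k: int = 24) -> bool:
    """Cheap flank-uniqueness guard: sampled flank k-mers occur exactly once."""
    seq = genome[chrom]
    windows = [seq[max(0, left_end - flank_bp):left_end],
               seq[right_start:right_start + flank_bp]]
    for win in windows:
        if len(win) < k:
            return False
        for off in (0, len(win) // 2, len(win) - k):
            kmer = win[off:off + k]
            if sum(s.count(kmer) for s in genome.values()) != 1:
                return False
    return True


def _sample_site(genome: dict[str, str], config: SimulationConfig,
                 rng: np.random.Generator, deletion: int,
                 occupied: dict[str, list[tuple[int, int]]]) -> tuple[str, int]:
    chroms = list(genome)
    lengths = np.array([len(genome[c]) for c in chroms], dtype=float)
    margin = config.flank_bp + 64
    chrom = chroms[int(rng.choice(len(chroms), p=lengths / lengths.sum()))]
    n = len(genome[chrom])
    if n < 2 * margin + deletion + 2 * config.min_spacing_bp:
        raise PlacementError("chromosome too short")
    site = int(rng.integers(margin, n - margin - deletion))
    foot = (site - config.min_spacing_bp, site + deletion + config.min_spacing_bp)
    for lo, hi in occupied.get(chrom, ()):
        if lo < foot[1] and foot[0] < hi:
            raise PlacementError("violates spacing to an existing event")
    if not _flanks_unique(genome, chrom, site, site + deletion, config.flank_bp):
        raise PlacementError("flank not unique")
    return chrom, site


def _plant_batch(genome: dict[str, str], specs: list[dict],
                 config: SimulationConfig, rng: np.random.Generator,
                 reserved: dict[str, list[tuple[int, int]]] | None = None,
                 max_attempts: int = 300) -> tuple[dict[str, str], list[TruthEvent]]:
    """Plan sites for all specs against the input genome, then splice them in
    ascending order so recorded coordinates are final."""
    occupied: dict[str, list[tuple[int, int]]] = {
        c: list(v) for c, v in (reserved or {}).items()}
    plans = []  # (chrom, site, spec)
    for spec in specs:
        deletion = spec.get("deletion_probe", 0)
        for attempt in range(max_attempts):
            try:
                chrom, site = _sample_site(genome, config, rng, deletion, occupied)
                # trial-plant on the untouched genome to validate hallmarks;
                # the planter reseeds from a frozen seed on every call so the
                # trial element and the spliced element are byte-identical
                _, event = spec["planter"](genome, chrom, site)
                break
            except PlacementError:
                continue
        else:
            raise PlacementError(
                f"could not place event after {max_attempts} attempts; "
                "genome too small or too crowded")
        occupied.setdefault(chrom, []).append(
            (site - 1, site + event.deletion_size_bp + 1))
        plans.append((chrom, site, spec))
    # splice ascending per chromosome, re-running the planter at the final
    # (offset-adjusted) coordinate
    events: list[TruthEvent] = []
    out = dict(genome)
    per_chrom: dict[str, list] = {}
    for chrom, site, spec in plans:
        per_chrom.setdefault(chrom, []).append((site, spec))
    for chrom in genome:
        delta = 0
        for site, spec in sorted(per_chrom.get(chrom, []), key=lambda t: t[0]):
            out, event = spec["planter"](out, chrom, site + delta)
            event.insertion_point_ancestor = site
            delta += (event.end - event.start) - event.deletion_size_bp
            if event.tsd is not None:
                delta += len(event.tsd)
            events.append(event)
    return out, events


def simulate(config: SimulationConfig) -> SimulatedDataset:
    """Generate the full dataset: ancestor, decoys, outgroups, ingroup, ledger."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    library = default_library()
    names = library.names
    ancestor0 = generate_ancestor(config, rng)

    def classical_spec(category: str, eid: str) -> dict:
        cons = library[names[int(rng.integers(len(names)))]]
        strand = "+" if rng.random() < 0.5 else "-"
        age = config.element_age_myr
        disrupt: frozenset[str] = frozenset()
        clip = None
        if category == "full_length":
            if rng.random() >= config.rc_fraction:
                k = 1 + int(rng.integers(0, 3))
                disrupt = frozenset(
                    np.random.default_rng(rng.integers(2**31)).choice(
                        GENES, size=min(k, 4), replace=False).tolist())
        elif category == "truncated":
            clip = ("3p" if rng.random() < 0.5 else "5p",
                    0.3 + 0.4 * rng.random())
        seed = int(rng.integers(2**31))

        def planter(g, chrom, site, _c=cons, _cat=category, _st=strand,
                    _age=age, _dis=disrupt, _clip=clip, _eid=eid, _seed=seed):
            return plant_element(g, chrom, site, _c, _cat, config,
                                 np.random.default_rng(_seed),
                                 age=_age, strand=_st, disrupt_genes=_dis,
                                 clip=_clip, event_id=_eid)

        return {"planter": planter, "deletion_probe": 0}

    def ncpi_spec(eid: str) -> dict:
        cons = library[names[int(rng.integers(len(names)))]]
        strand = "+" if rng.random() < 0.5 else "-"
        structure = "solo_ltr" if rng.random() < 4.0 / 7.0 else "full_length"
        lo, hi = config.ncpi_deletion_range_bp
        deletion = int(rng.integers(lo, hi + 1))
        mlo, mhi = config.microhomology_range
        mh_l = int(rng.integers(mlo, mhi + 1)) if rng.random() < config.microhomology_prob else 0
        mh_r = int(rng.integers(mlo, mhi + 1)) if rng.random() < config.microhomology_prob else 0
        seed = int(rng.integers(2**31))

        def planter(g, chrom, site, _c=cons, _st=strand, _str=structure,
                    _d=deletion, _mh=(mh_l, mh_r), _eid=eid, _seed=seed):
            return plant_ncpi(g, chrom, site, _c, config,
                              np.random.default_rng(_seed),
                              age=config.element_age_myr, strand=_st,
                              structure=_str, deletion_size=_d,
                              microhomology=_mh, event_id=_eid)

        return {"planter": planter, "deletion_probe": deletion}

    # decoys are planted into the ancestor and therefore shared by all genomes
    decoy_specs = []
    for i in range(config.n_decoy_shared):
        spec = classical_spec("full_length" if i % 2 == 0 else "solo_ltr",
                              f"decoy_{i + 1}")
        decoy_specs.append(spec)
    ancestor, decoys = _plant_batch(ancestor0, decoy_specs, config, rng)
    for d in decoys:
        d.planted_age_myr = config.decoy_age_myr

    outgroups = derive_outgroups(ancestor, config, config.n_outgroups, rng) \
        if config.n_outgroups else []

    specs: list[dict] = []
    counter = 0
    for category, count in (("full_length", config.n_full_length),
                            ("solo_ltr", config.n_solo_ltr),
                            ("truncated", config.n_truncated)):
        for _ in range(count):
            counter += 1
            specs.append(classical_spec(category, f"ev_{counter:04d}"))
    for _ in range(config.n_ncpi):
        counter += 1
        specs.append(ncpi_spec(f"ev_{counter:04d}"))

    reserved = {}
    for d in decoys:
        reserved.setdefault(d.chrom, []).append((d.start, d.end))
    ingroup, events = _plant_batch(ancestor, specs, config, rng, reserved=reserved)

    # decoys were planted into the ancestor; shift their recorded spans by the
    # ingroup events inserted/deleted upstream so the ledger (and the .out
    # annotation built from it) is in ingroup coordinates
    for d in decoys:
        shift = 0
        for ev in events:
            if ev.chrom == d.chrom and ev.insertion_point_ancestor <= d.start:
                shift += (ev.end - ev.start) - ev.deletion_size_bp
                if ev.tsd is not None:
                    shift += len(ev.tsd)
        if shift:
            move = lambda sp: (sp[0] + shift, sp[1] + shift) if sp else None
            d.start += shift
            d.end += shift
            d.ltr5_span = move(d.ltr5_span)
            d.ltr3_span = move(d.ltr3_span)
            d.internal_spans = [move(s) for s in d.internal_spans]

    ledger = TruthLedger(events=events, decoys=decoys)
    ledger.validate(ingroup)
    return SimulatedDataset(config=config, library=library, ancestor=ancestor,
                            ingroup=ingroup, outgroups=outgroups, ledger=ledger)


def simulate_ltr_pair(length: int, age_myr: float, rate: float,
                      rng: np.random.Generator) -> tuple[str, str]:
    """One LTR pair: a random ancestral LTR aged independently on each copy
    (Poisson substitutions, expected ``age_myr * rate`` per site per copy),
    so the expected pair divergence is 2 * rate * age."""
    anc = array_to_seq(rng.choice(_BASES, size=length))
    return (mutate_seq(anc, age_myr * rate, rng),
            mutate_seq(anc, age_myr * rate, rng))


# ---------------------------------------------------------------------------
# emission

_OUT_HEADER = (
    "   SW  perc perc perc  query      position in query           matching"
    "       repeat              position in  repeat\n"
    "score  div. del. ins.  sequence    begin     end    (left)    repeat"
    "         class/family         begin  end (left)     ID\n"
    "\n"
)


def _event_rows(event: TruthEvent, config: SimulationConfig) -> list[tuple]:
    """RepeatMasker-style fragment rows (start, end, repeat_name) for one event."""
    sub = event.subfamily
    rows = []
    if event.ltr5_span:
        rows.append((*event.ltr5_span, f"{sub}_LTR"))
    if event.ltr3_span:
        rows.append((*event.ltr3_span, f"{sub}_LTR"))
    for span in event.internal_spans:
        a, b = span
        if (config.split_internal_fragments
                and event.structure == "full_length"
                and b - a > config.split_gap_bp + 200):
            h = (b - a - config.split_gap_bp) // 2
            rows.append((a, a + h, f"{sub}-int"))
            rows.append((a + h + config.split_gap_bp, b, f"{sub}-int"))
        else:
            rows.append((a, b, f"{sub}-int"))
    rows.sort()
    return rows


def emit_repeatmasker_out(ledger: TruthLedger, genome: dict[str, str],
                          config: SimulationConfig,
                          library: ConsensusLibrary, path: str | Path) -> None:
    """Emit a syntactically standard 15-column RepeatMasker .out file
    (3 header lines, 1-based inclusive coordinates, LTR and internal
    fragments listed separately, strand 'C' for minus-strand hits)."""
    all_events = sorted(ledger.events + ledger.decoys,
                        key=lambda e: (e.chrom, e.start))
    lines = [_OUT_HEADER]
    rid = 0
    for event in all_events:
        rid += 1
        div = 100.0 * event.planted_age_myr * config.ltr_mutation_rate
        strand = "+" if event.strand == "+" else "C"
        for (a, b, name) in _event_rows(event, config):
            left = len(genome[event.chrom]) - b
            rep_len = b - a
            lines.append(
                f"{2000:>5} {div:5.1f}  0.0  0.0  {event.chrom:<10}"
                f"{a + 1:>9} {b:>8} ({left}) {strand:>3} "
                f"{name:<16} LTR/ERV1 {1:>9} {rep_len:>6} (0) {rid:>6}\n"
            )
    Path(path).write_text("".join(lines))


def write_truth(dataset: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    """Write FASTA genomes, the .out annotation, the JSON truth ledger and the
    consensus library; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"ingroup": outdir / "ingroup.fa", "out": outdir / "repeats.out",
             "ledger": outdir / "truth.json", "library": outdir / "library"}
    write_fasta(dataset.ingroup, paths["ingroup"])
    for i, og in enumerate(dataset.outgroups, 1):
        p = outdir / f"outgroup_{i}.fa"
        write_fasta(og, p)
        paths[f"outgroup_{i}"] = p
    emit_repeatmasker_out(dataset.ledger, dataset.ingroup, dataset.config,
                          dataset.library, paths["out"])
    dataset.ledger.to_json(paths["ledger"])
    dataset.library.write(paths["library"])
    return paths
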