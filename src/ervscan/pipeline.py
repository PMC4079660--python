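"""End-to-end orchestration: catalog -> lineage filter -> anatomy -> dating
-> NCPI -> reports.

``run_pipeline`` is deterministic for fixed inputs; every output table
carries a header line with the tool version and a hash of the resolved
configuration, and a manifest records which stages completed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import edlib
import pandas as pd
import yaml

from . import __version__
from ._align import GenomeIndex
from .anatomy import (detect_tsd, element_sequence, internal_sequence,
                      pair_ltrs, screen_orfs)
from .catalog import (ErvLocus, catalog_summary, defragment,
                      loci_to_dataframe, parse_repeatmasker_out, write_bed)
from .consensus import ConsensusLibrary, FAMILY_OF, GENES as GENE_ORDER
from .dating import (SaturatedDistanceError, UndefinedDistanceError,
                     assign_subfamily, estimate_age, k2p_aligned_pair,
                     subfamily_statistics)
from .io import config_hash, read_fasta, revcomp, write_tsv
from .lineage import (OrthologCall, call_specificity, extract_flanks,
                      map_flanks)
from .ncpi import call_ncpi_candidates, events_to_dataframe, ncpi_report
from .polymorphism import (GenotypeMatrix, density_table, family_summary,
                           polymorphism_rate)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    genome: str
    outgroups: list[str]
    repeats_out: str
    library_dir: str
    outdir: str
    genotypes: str | None = None
    name_prefixes: list[str] | None = None
    flank_bp: int = 2000
    kmer: int = 16
    min_identity: float = 0.85
    min_cov: float = 0.5
    absence_threshold: int = 50
    presence_margin: float = 0.5
    max_gap_bp: int = 1000
    intact_fraction: float = 0.95
    tsd_min_len: int = 2
    tsd_max_len: int = 6

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def resolved_hash(self) -> str:
        fields = dataclasses.asdict(self)
        fields.pop("outdir")  # the output location does not affect results
        return config_hash(yaml.safe_dump(fields, sort_keys=True))

    def check_inputs(self) -> None:
        paths = [self.genome, self.repeats_out, self.library_dir, *self.outgroups]
        if self.genotypes:
            paths.append(self.genotypes)
        missing = [p for p in paths if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing input path(s): {missing}")


@dataclass
class PipelineResult:
    loci: list[ErvLocus]
    calls: dict[str, OrthologCall]
    anatomy: pd.DataFrame
    subfamily_stats: pd.DataFrame
    family_table: pd.DataFrame
    ncpi_events: list
    ncpi_summary: dict
    density: pd.DataFrame
    summary: dict
    completed_stages: list[str] = field(default_factory=list)


def _internal_offset(internal: str, consensus_internal: str) -> int:
    """Consensus coordinate of the retained internal region's first base."""
    if len(internal) >= len(consensus_internal) - 1:
        return 0
    res = edlib.align(internal, consensus_internal, mode="HW", task="locations")
    locs = res.get("locations") or []
    return locs[0][0] if locs and locs[0][0] is not None else 0


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    config.check_inputs()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = f"ervscan {__version__} config={config.resolved_hash()}"
    completed: list[str] = []
    manifest = {"version": __version__, "config_hash": config.resolved_hash(),
                "stages": completed}

    def checkpoint() -> None:
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))

    try:
        genome = read_fasta(config.genome)
        outgroups = {f"outgroup_{i + 1}": read_fasta(p)
                     for i, p in enumerate(config.outgroups)}
        library = ConsensusLibrary.load(config.library_dir)

        # --- catalog ---------------------------------------------------
        prefixes = tuple(config.name_prefixes) if config.name_prefixes else None
        hits = parse_repeatmasker_out(config.repeats_out, prefixes)
        loci, ignored = defragment(hits, max_gap_bp=config.max_gap_bp)
        write_tsv(loci_to_dataframe(loci), outdir / "catalog.tsv", header)
        write_bed(loci, outdir / "loci.bed")
        completed.append("catalog")
        checkpoint()

        # --- lineage filter ---------------------------------------------
        indexes = {name: GenomeIndex(og, k=config.kmer)
                   for name, og in outgroups.items()}
        calls: dict[str, OrthologCall] = {}
        for locus in loci:
            flanks = extract_flanks(genome, locus, config.flank_bp)
            elem_seq = element_sequence(genome, locus)
            mappings = {
                name: map_flanks(flanks, idx, locus.length,
                                 min_identity=config.min_identity,
                                 min_cov=config.min_cov)
                for name, idx in indexes.items()}
            calls[locus.locus_id] = call_specificity(
                locus, elem_seq, mappings, outgroups,
                absence_threshold=config.absence_threshold,
                presence_margin=config.presence_margin,
                min_identity=config.min_identity)
        calls_df = pd.DataFrame([
            {"locus_id": lid, "final_call": c.final_call,
             **{f"{name}_status": s for name, s in c.statuses.items()},
             **{f"{name}_gap_bp": c.outgroup_gaps.get(name)
                for name in c.statuses}}
            for lid, c in sorted(calls.items())])
        write_tsv(calls_df, outdir / "ortholog_calls.tsv", header)
        completed.append("lineage_filter")
        checkpoint()

        specific = [l for l in loci
                    if calls[l.locus_id].final_call == "ingroup_specific"]
        loci_by_id = {l.locus_id: l for l in loci}

        # --- anatomy + dating per locus ---------------------------------
        ltr_consensus = library.ltr_consensus_set()
        anatomy_rows = []
        tsd_results = {}
        ltrs_by_subfamily: dict[str, list[str]] = {}
        ltr_lengths: dict[str, list[int]] = {}
        for locus in specific:
            tsd = detect_tsd(genome, locus, config.tsd_min_len, config.tsd_max_len)
            tsd_results[locus.locus_id] = tsd
            pair = pair_ltrs(genome, locus)
            ltr_d = None
            if pair is not None:
                try:
                    ltr_d = k2p_aligned_pair(*pair).d
                except (SaturatedDistanceError, UndefinedDistanceError):
                    ltr_d = None
            # subfamily from the LTR sequence (5' if present)
            ltr_seq = None
            if pair is not None:
                ltr_seq = pair[0]
            else:
                span = locus.ltr5_span or locus.ltr3_span
                if span is not None:
                    ltr_seq = genome[locus.chrom][span[0]:span[1]]
                    if locus.strand == "-":
                        ltr_seq = revcomp(ltr_seq)
            if ltr_seq is not None:
                label, dist, margin, tie = assign_subfamily(ltr_seq, ltr_consensus)
            else:
                label, dist, margin, tie = None, None, None, False
            if label is not None:
                ltr_lengths.setdefault(label, []).append(len(ltr_seq))
                if pair is not None:
                    ltrs_by_subfamily.setdefault(label, []).extend(pair)
            # ORF screen on the internal region
            sub_for_genes = label if label in library.names else locus.subfamily
            if sub_for_genes in library.names:
                cons = library[sub_for_genes]
                internal = internal_sequence(genome, locus)
                offset = (_internal_offset(internal, cons.internal)
                          if internal is not None else 0)
                screen = screen_orfs(internal, cons.gene_spans, offset=offset,
                                     intact_fraction=config.intact_fraction)
                gene_status = screen.status
                rc = screen.rc_flag
            else:
                gene_status = {g: "missing" for g in GENE_ORDER}
                rc = False
            age = estimate_age(ltr_d) if ltr_d is not None else None
            anatomy_rows.append({
                "locus_id": locus.locus_id, "category": locus.category,
                "subfamily": label or "unassigned",
                "assignment_margin": margin, "assignment_tie": tie,
                "tsd_present": tsd.present, "tsd_len": tsd.length,
                "tsd_seq": tsd.sequence,
                "ltr_pair_k2p": ltr_d,
                "age_young_myr": age.age_young_myr if age else None,
                "age_old_myr": age.age_old_myr if age else None,
                **{f"{g}_status": gene_status[g] for g in GENE_ORDER},
                "rc_flag": rc,
            })
        anatomy_df = pd.DataFrame(anatomy_rows)
        write_tsv(anatomy_df, outdir / "anatomy.tsv", header)
        completed.append("anatomy")
        checkpoint()

        # --- subfamily dating table --------------------------------------
        stats = subfamily_statistics(ltrs_by_subfamily)
        write_tsv(stats, outdir / "subfamily_table.tsv", header)
        completed.append("dating")
        checkpoint()

        # --- NCPI ---------------------------------------------------------
        events = call_ncpi_candidates(
            tsd_results, calls, loci_by_id, genome,
            absence_threshold=config.absence_threshold)
        write_tsv(events_to_dataframe(events), outdir / "ncpi_events.tsv", header)
        summary_ncpi = ncpi_report(events)
        write_tsv(pd.DataFrame([summary_ncpi]), outdir / "ncpi_summary.tsv", header)
        completed.append("ncpi")
        checkpoint()

        # --- reports -------------------------------------------------------
        chrom_lengths = {c: len(s) for c, s in genome.items()}
        density = density_table(specific, chrom_lengths)
        write_tsv(density, outdir / "density.tsv", header)
        fam_table = family_summary(
            [dataclasses.replace(
                l, subfamily=(anatomy_df.set_index("locus_id")
                              .loc[l.locus_id, "subfamily"]
                              if l.locus_id in set(anatomy_df.get("locus_id", []))
                              else l.subfamily))
             for l in specific],
            ltr_lengths=ltr_lengths, family_of=FAMILY_OF)
        write_tsv(fam_table, outdir / "family_table.tsv", header)

        summary = {
            "n_hits": len(hits), "n_ignored_hits": len(ignored),
            "catalog": catalog_summary(loci),
            "calls": {c: sum(1 for v in calls.values() if v.final_call == c)
                      for c in ("ingroup_specific", "shared", "unresolved")},
            "specific_catalog": catalog_summary(specific),
            "ncpi": summary_ncpi,
        }
        if config.genotypes:
            matrix = GenotypeMatrix.from_tsv(config.genotypes)
            poly = {}
            fams = sorted(set(matrix.families.values()))
            for fam in fams:
                n_poly, n_assayed, pct = polymorphism_rate(matrix, family=fam)
                poly[fam] = {"n_polymorphic": n_poly, "n_assayed": n_assayed,
                             "percent": pct}
            n_poly, n_assayed, pct = polymorphism_rate(matrix)
            poly["all"] = {"n_polymorphic": n_poly, "n_assayed": n_assayed,
                           "percent": pct}
            summary["polymorphism"] = poly
        (outdir / "summary.json").write_text(json.dumps(summary, indent=1))
        completed.append("reports")
        checkpoint()

        return PipelineResult(
            loci=loci, calls=calls, anatomy=anatomy_df,
            subfamily_stats=stats, family_table=fam_table,
            ncpi_events=events, ncpi_summary=summary_ncpi,
            density=density, summary=summary, completed_stages=completed)
    except Exception:
        checkpoint()  # retain partial outputs plus the stage manifest
        raise
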