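"""Polymorphism and genome-wide summaries.

LTR retroelement loci can segregate in three allelic states (trimorphism):
element absent, full element present, and solitary LTR present (the
recombination product of the full element).  Given a locus x individual
genotype matrix of those states this module classifies each locus as fixed,
dimorphic or trimorphic, computes polymorphism rates, and produces the
per-subfamily copy-number table and the per-chromosome insertion-density
table.

Missing genotypes (failed assays) are excluded from the distinct-state
count rather than imputed.  Percentages are rounded half-up to one decimal,
matching how such tables are conventionally printed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from ._decimal import round_half_up
from .catalog import CATEGORY_ORDER, ErvLocus

STATES = ("absent", "solo_ltr", "full_length", "missing")


class GenotypeError(ValueError):
    pass


@dataclass
class GenotypeMatrix:
    """Locus x individual allelic states plus per-locus family labels."""

    states: pd.DataFrame                      # index locus_id, columns individuals
    families: dict[str, str] = field(default_factory=dict)  # locus_id -> family label

    def __post_init__(self) -> None:
        bad = set(self.states.values.ravel()) - set(STATES)
        if bad:
            raise GenotypeError(f"unknown genotype states: {sorted(bad)}")
        all_missing = (self.states == "missing").all(axis=1)
        if all_missing.any():
            raise GenotypeError(
                "loci with no non-missing genotype: "
                f"{list(self.states.index[all_missing])}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenotypeMatrix":
        """Long-format TSV reader: columns locus_id, individual, state
        (optional column family)."""
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        required = {"locus_id", "individual", "state"}
        if not required.issubset(df.columns):
            raise GenotypeError(f"genotype TSV needs columns {sorted(required)}")
        wide = df.pivot_table(index="locus_id", columns="individual",
                              values="state", aggfunc="first")
        wide = wide.fillna("missing")
        families = {}
        if "family" in df.columns:
            families = (df.drop_duplicates("locus_id")
                          .set_index("locus_id")["family"].dropna().to_dict())
        return cls(states=wide, families=families)

    @property
    def loci(self) -> list[str]:
        return list(self.states.index)

    @property
    def individuals(self) -> list[str]:
        return list(self.states.columns)


def classify_locus_polymorphism(states) -> str | None:
    """fixed / dimorphic / trimorphic by the number of distinct non-missing
    states; None (not evaluable) with fewer than two informative genotypes."""
    observed = [s for s in states if s != "missing"]
    if len(observed) < 2:
        return None
    n = len(set(observed))
    return {1: "fixed", 2: "dimorphic", 3: "trimorphic"}[n]


def polymorphism_rate(matrix: GenotypeMatrix,
                      family: str | None = None,
                      loci_subset: list[str] | None = None
                      ) -> tuple[int, int, float | None]:
    """(n polymorphic, n assayed, percent to one decimal, half-up).

    A locus counts as polymorphic when dimorphic or trimorphic; loci that are
    not evaluable are excluded from the assayed denominator.  ``family``
    restricts to loci with that family label; ``loci_subset`` to an explicit
    locus list (e.g. the retrotransposition-competent set).
    """
    loci = matrix.loci
    if family is not None:
        loci = [l for l in loci if matrix.families.get(l) == family]
    if loci_subset is not None:
        subset = set(loci_subset)
        loci = [l for l in loci if l in subset]
    n_poly = n_assayed = 0
    for locus in loci:
        cls = classify_locus_polymorphism(matrix.states.loc[locus])
        if cls is None:
            continue
        n_assayed += 1
        if cls in ("dimorphic", "trimorphic"):
            n_poly += 1
    if n_assayed == 0:
        return 0, 0, None
    return n_poly, n_assayed, round_half_up(100.0 * n_poly / n_assayed, 1)


def family_summary(loci: list[ErvLocus],
                   ltr_lengths: dict[str, list[int]] | None = None,
                   family_of: dict[str, str] | None = None) -> pd.DataFrame:
    """Per-subfamily copy number, full-length and solo-LTR counts, mean LTR
    length, plus per-family solitary-LTR percentages.

    ``ltr_lengths`` maps subfamily -> observed LTR lengths (bp);
    ``family_of`` maps subfamily -> family (defaults to the subfamily itself).
    Family rows aggregate their subfamilies, with
    solo_pct = 100 * sum(solo) / sum(copies).
    """
    rows: dict[str, dict] = {}
    for locus in loci:
        sub = locus.subfamily or "unassigned"
        row = rows.setdefault(sub, {"subfamily": sub, "copy_number": 0,
                                    "full_length": 0, "solo_ltr": 0})
        row["copy_number"] += 1
        if locus.category in ("full_length", "solo_ltr"):
            row[locus.category] += 1
    df = pd.DataFrame(sorted(rows.values(), key=lambda r: r["subfamily"]))
    if df.empty:
        return pd.DataFrame(columns=["subfamily", "family", "copy_number",
                                     "full_length", "solo_ltr",
                                     "mean_ltr_length_bp", "family_solo_pct"])
    fam = family_of or {}
    df["family"] = df["subfamily"].map(lambda s: fam.get(s, s))
    if ltr_lengths:
        df["mean_ltr_length_bp"] = df["subfamily"].map(
            lambda s: (sum(ltr_lengths[s]) / len(ltr_lengths[s]))
            if ltr_lengths.get(s) else None)
    else:
        df["mean_ltr_length_bp"] = None
    fam_totals = df.groupby("family")[["copy_number", "solo_ltr"]].sum()
    solo_pct = {
        f: round_half_up(100.0 * r["solo_ltr"] / r["copy_number"], 1)
        if r["copy_number"] else None
        for f, r in fam_totals.iterrows()}
    df["family_solo_pct"] = df["family"].map(solo_pct)
    return df[["subfamily", "family", "copy_number", "full_length",
               "solo_ltr", "mean_ltr_length_bp", "family_solo_pct"]]


def density_table(loci: list[ErvLocus],
                  chromosome_lengths: dict[str, int]) -> pd.DataFrame:
    """Per-chromosome counts by category and insertions per Mbp."""
    unknown = sorted({l.chrom for l in loci} - set(chromosome_lengths))
    if unknown:
        raise ValueError(f"loci on unknown chromosomes: {unknown}")
    for chrom, n in chromosome_lengths.items():
        if n <= 0:
            raise ValueError(f"non-positive length for {chrom}")
    rows = []
    for chrom in chromosome_lengths:
        counts = {c: 0 for c in CATEGORY_ORDER}
        for locus in loci:
            if locus.chrom == chrom:
                counts[locus.category] += 1
        total = sum(counts.values())
        mbp = chromosome_lengths[chrom] / 1e6
        rows.append({"chrom": chrom, **counts, "total": total,
                     "length_bp": chromosome_lengths[chrom],
                     "density_per_mbp": total / mbp})
    return pd.DataFrame(rows)
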