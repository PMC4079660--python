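"""LTR divergence dating under the Kimura two-parameter model.

The two LTRs of a provirus are identical at integration and accumulate
substitutions independently afterwards, so their corrected divergence d
equals 2 r T for neutral rate r and element age T:

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

with P and Q the transition and transversion proportions over gap-free,
unambiguous alignment columns (the "without INDEL" convention: columns with
a gap or an ambiguity code are excluded from both counts and the site
total).  Ages are reported as an interval from two neutral-rate
calibrations, 0.26 %/site/myr (young bound) and 0.20 %/site/myr (old
bound):

    age_young = d / (2 * 0.0026)   age_old = d / (2 * 0.0020)

so age_old / age_young = 1.3 exactly for any d > 0.
"""

from __future__ import annotations

import math
import shutil
import subprocess
import tempfile
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from ._align import global_alignment
from .io import read_fasta, write_fasta

RATE_FAST = 0.0026  # substitutions / site / myr
RATE_SLOW = 0.0020

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}
_UNAMBIGUOUS = {"A", "C", "G", "T"}

_IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G",
    frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("GC"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D", frozenset("ACT"): "H",
    frozenset("ACG"): "V", frozenset("ACGT"): "N",
}


class SaturatedDistanceError(ValueError):
    """The K2P logarithm argument is non-positive (sequences too diverged)."""


class UndefinedDistanceError(ValueError):
    """No gap-free unambiguous columns to compare."""


@dataclass
class K2pDistance:
    P: float
    Q: float
    d: float
    sites_compared: int


@dataclass
class AgeEstimate:
    d: float
    rate_fast: float
    rate_slow: float
    age_young_myr: float
    age_old_myr: float


def k2p(seq_a: str, seq_b: str) -> K2pDistance:
    """K2P distance of an aligned pair; gap/ambiguous columns are excluded."""
    if len(seq_a) != len(seq_b):
        raise ValueError("k2p requires an aligned (equal-length) pair")
    n = ti = tv = 0
    for a, b in zip(seq_a.upper(), seq_b.upper()):
        if a not in _UNAMBIGUOUS or b not in _UNAMBIGUOUS:
            continue
        n += 1
        if a == b:
            continue
        if (a in _PURINES) == (b in _PURINES):
            ti += 1
        else:
            tv += 1
    if n == 0:
        raise UndefinedDistanceError("zero comparable sites")
    P, Q = ti / n, tv / n
    w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturatedDistanceError(
            f"saturated distance (P={P:.3f}, Q={Q:.3f})")
    d = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    return K2pDistance(P=P, Q=Q, d=d, sites_compared=n)


def k2p_aligned_pair(seq_a: str, seq_b: str) -> K2pDistance:
    """Globally align two unaligned sequences, then compute k2p."""
    a, b = global_alignment(seq_a, seq_b)
    return k2p(a, b)


def estimate_age(d: float, rate_fast: float = RATE_FAST,
                 rate_slow: float = RATE_SLOW) -> AgeEstimate:
    """Calibrated age interval from an LTR-pair divergence (d = 2 r T)."""
    if d < 0:
        raise ValueError("divergence must be non-negative")
    return AgeEstimate(d=d, rate_fast=rate_fast, rate_slow=rate_slow,
                       age_young_myr=d / (2.0 * rate_fast),
                       age_old_myr=d / (2.0 * rate_slow))


def assign_subfamily(ltr_seq: str, consensus_set: dict[str, str]
                     ) -> tuple[str | None, float | None, float | None, bool]:
    """Assign an LTR to the closest consensus by K2P distance.

    Returns (label, best distance, margin to the runner-up, tie_flag).
    Labels at equal distance are broken lexicographically and flagged.
    An LTR saturated against every consensus is unassigned (None).
    """
    if not consensus_set:
        raise ValueError("need at least one consensus sequence")
    distances: list[tuple[float, str]] = []
    for label in sorted(consensus_set):
        try:
            distances.append((k2p_aligned_pair(ltr_seq, consensus_set[label]).d,
                              label))
        except (SaturatedDistanceError, UndefinedDistanceError):
            continue
    if not distances:
        return None, None, None, False
    distances.sort(key=lambda t: (t[0], t[1]))
    best_d, best_label = distances[0]
    if len(distances) == 1:
        return best_label, best_d, None, False
    second_d = distances[1][0]
    return best_label, best_d, second_d - best_d, second_d == best_d


def mean_pairwise_k2p(ltrs: list[str]) -> float | None:
    """Mean K2P distance over all unordered pairs; None for singletons."""
    if len(ltrs) < 2:
        return None
    total, count = 0.0, 0
    for i in range(len(ltrs)):
        for j in range(i + 1, len(ltrs)):
            total += k2p_aligned_pair(ltrs[i], ltrs[j]).d
            count += 1
    return total / count


def subfamily_statistics(ltrs_by_subfamily: dict[str, list[str]]) -> pd.DataFrame:
    """Per-subfamily LTR count, mean length, mean pairwise K2P distance and
    the calibrated age interval (NA for singleton subfamilies)."""
    rows = []
    for label in sorted(ltrs_by_subfamily):
        ltrs = ltrs_by_subfamily[label]
        mean_len = sum(map(len, ltrs)) / len(ltrs) if ltrs else float("nan")
        d = mean_pairwise_k2p(ltrs)
        if d is None:
            rows.append({"subfamily": label, "n_ltrs": len(ltrs),
                         "mean_length_bp": mean_len, "mean_pairwise_k2p": None,
                         "age_young_myr": None, "age_old_myr": None})
        else:
            age = estimate_age(d)
            rows.append({"subfamily": label, "n_ltrs": len(ltrs),
                         "mean_length_bp": mean_len, "mean_pairwise_k2p": d,
                         "age_young_myr": age.age_young_myr,
                         "age_old_myr": age.age_old_myr})
    return pd.DataFrame(rows)


def _mafft_align(sequences: list[str]) -> list[str]:
    """Multiple alignment via the mafft binary."""
    if shutil.which("mafft") is None:
        raise RuntimeError("mafft binary not found on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        inp = Path(tmp) / "in.fa"
        write_fasta({f"s{i}": s for i, s in enumerate(sequences)}, inp)
        res = subprocess.run(["mafft", "--auto", "--quiet", str(inp)],
                             capture_output=True, text=True, check=True)
        out = Path(tmp) / "aln.fa"
        out.write_text(res.stdout)
        aligned = read_fasta(out)
    return [aligned[f"s{i}"] for i in range(len(sequences))]


def build_consensus(sequences: list[str], aligned: bool = False) -> str:
    """Majority-rule consensus of a set of near-identical sequences.

    Unaligned input is multiple-aligned first (mafft).  Per column the
    majority base wins; ties among bases become the IUPAC ambiguity code;
    all-gap columns are dropped and gaps never outvote bases.
    """
    if not sequences:
        raise ValueError("empty input")
    if len(sequences) == 1:
        return sequences[0].upper()
    seqs = [s.upper() for s in sequences]
    if not aligned or len({len(s) for s in seqs}) != 1:
        seqs = [s.upper() for s in _mafft_align(seqs)]
    out = []
    for col in zip(*seqs):
        counts = Counter(b for b in col if b != "-")
        if not counts:
            continue  # all-gap column
        top = counts.most_common()
        best = top[0][1]
        winners = frozenset(b for b, c in top if c == best)
        out.append(_IUPAC.get(winners, "N") if len(winners) > 1 else top[0][0])
    return "".join(out)
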