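"""FASTA and table I/O helpers shared by the pipeline stages."""

from __future__ import annotations

import hashlib
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_RC = str.maketrans("ACGTNRYKMacgtnrykm", "TGCANYRMKtgcanyrmk")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered name -> uppercase sequence dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def config_hash(text: str) -> str:
    return hashlib.sha1(text.encode()).hexdigest()[:12]


def write_tsv(df, path: str | Path, header_comment: str | None = None) -> None:
    """Write a DataFrame as TSV, optionally with a leading '#' comment line."""
    path = Path(path)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False)
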