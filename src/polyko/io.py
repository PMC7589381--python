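"""FASTA/TSV/CSV reading and writing for pipeline artefacts."""

from __future__ import annotations

from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["read_fasta", "write_fasta", "write_tsv_header"]


def read_fasta(path) -> dict[str, str]:
    """FASTA file -> {id: sequence} (order preserving)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path, description: str = "") -> None:
    """{id: sequence} -> FASTA file."""
    records = [
        SeqRecord(Seq(seq), id=name, description=description)
        for name, seq in sequences.items()
    ]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    SeqIO.write(records, str(path), "fasta")


def write_tsv_header(path, lines: list[str]) -> None:
    """Prepend commented header lines (seed, config hash) to a TSV/CSV."""
    p = Path(path)
    body = p.read_text()
    header = "".join(f"# {line}\n" for line in lines)
    p.write_text(header + body)
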