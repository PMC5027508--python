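"""FASTA and small tabular I/O for the survey pipeline."""
from __future__ import annotations

from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .sequence_model import SequenceRecord


def read_fasta(path: str | Path, circular: bool = False) -> list[SequenceRecord]:
    """Read a multi-FASTA file into :class:`SequenceRecord` objects.

    Non-ACGTN IUPAC codes are mapped to N (with a logged warning) by the
    record constructor, matching the exact-identity search strategy.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            SequenceRecord(
                id=rec.id,
                description=rec.description,
                residues=str(rec.seq),
                circular=circular,
            )
        )
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    bio = [
        BioSeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)
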