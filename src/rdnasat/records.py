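"""Sequence records and FASTA I/O.

A :class:`SequenceRecord` is a validated DNA sequence over ``{A,C,G,T,N}``.
Lowercase input is normalized to uppercase on construction; any other symbol
raises. FASTA reading/writing is delegated to Biopython's SeqIO.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_VALID = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# numeric encoding shared with the alignment kernels: A=0 C=1 G=2 T=3 N=4
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGTN"):
    _CODE[ord(_b)] = _i


def reverse_complement(seq: str) -> str:
    """Reverse complement of an upper-case DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode an upper-case DNA string as int8 codes (A=0,C=1,G=2,T=3,N=4)."""
    arr = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr < 0).any():
        bad = sorted({c for c in seq if c not in _VALID})
        raise ValueError(f"invalid DNA symbols: {bad}")
    return arr


@dataclass(frozen=True)
class SequenceRecord:
    """An identified DNA sequence (contig, reference gene, satellite consensus).

    Parameters
    ----------
    id
        Non-empty identifier, unique within a collection.
    seq
        DNA over {A,C,G,T,N}; lowercase accepted and upper-cased.
    description
        Optional free-text description.
    """

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SequenceRecord id must be non-empty")
        seq = self.seq.upper()
        if len(seq) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(seq) - _VALID
        if bad:
            raise ValueError(f"sequence {self.id!r} contains invalid symbols: {sorted(bad)}")
        object.__setattr__(self, "seq", seq)

    def __len__(self) -> int:
        return len(self.seq)

    def reverse_complement(self, id_suffix: str = "_rc") -> "SequenceRecord":
        return SequenceRecord(self.id + id_suffix, reverse_complement(self.seq), self.description)

    def slice(self, start: int, end: int, new_id: str | None = None) -> "SequenceRecord":
        if not (0 <= start < end <= len(self.seq)):
            raise ValueError(f"slice [{start}, {end}) out of bounds for {self.id!r} (len {len(self.seq)})")
        return SequenceRecord(new_id or f"{self.id}:{start}-{end}", self.seq[start:end])


def read_fasta(path: Union[str, Path]) -> list[SequenceRecord]:
    """Read a (multi-)FASTA file into validated records.

    Duplicate ids raise, matching the uniqueness invariant.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, str(rec.seq), rec.description))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: Union[str, Path], width: int = 60) -> None:
    """Write records as wrapped FASTA (default 60 columns)."""
    seq_records = [
        SeqRecord(Seq(r.seq), id=r.id, description=r.description or "") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)
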