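"""Protein sequence I/O and the absolute residue coordinate convention.

Vaccine-peptide labels such as ``p232`` refer to absolute 1-based positions on
the full-length protein. A :class:`ProteinRecord` carries an ``anchor``: the
absolute coordinate of its first residue, so that sub-sequences (e.g. a 15-mer
candidate peptide) keep their positions on the parent protein. External
coordinates are 1-based inclusive; internal offsets are 0-based.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 canonical amino-acid one-letter codes.
CANONICAL_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

_LABEL_RE = re.compile(r"^[pP](\d+)$")


@dataclass(frozen=True)
class ProteinRecord:
    """An amino-acid sequence anchored at an absolute 1-based coordinate.

    Parameters
    ----------
    id
        Sequence identifier.
    sequence
        Uppercase amino-acid string over the 20 canonical letters
        (``X`` only if constructed with ``allow_ambiguous=True``).
    anchor
        Absolute 1-based coordinate of the first residue (default 1).
    """

    id: str
    sequence: str
    anchor: int = 1
    allow_ambiguous: bool = field(default=False, compare=False, repr=False)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if self.anchor < 1:
            raise ValueError(f"record {self.id!r}: anchor must be >= 1, got {self.anchor}")
        alphabet = CANONICAL_AA | {"X"} if self.allow_ambiguous else CANONICAL_AA
        for ch in self.sequence:
            if ch not in alphabet:
                raise ValueError(
                    f"record {self.id!r}: illegal residue character {ch!r}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def end(self) -> int:
        """Absolute 1-based coordinate of the last residue."""
        return self.anchor + len(self.sequence) - 1

    def slice_absolute(self, start: int, end: int) -> str:
        """Sub-sequence for absolute 1-based inclusive coordinates ``[start, end]``."""
        if start < self.anchor or end > self.end or start > end:
            raise ValueError(
                f"absolute range [{start}, {end}] outside record "
                f"[{self.anchor}, {self.end}]"
            )
        off = start - self.anchor
        return self.sequence[off : off + (end - start + 1)]


def position_label(record: ProteinRecord, offset: int) -> str:
    """Label of the residue at 0-based ``offset`` within ``record``, e.g. ``"p232"``."""
    if not 0 <= offset < len(record.sequence):
        raise ValueError(
            f"offset {offset} out of range for record {record.id!r} "
            f"of length {len(record.sequence)}"
        )
    return f"p{record.anchor + offset}"


def parse_position_label(label: str) -> int:
    """Absolute 1-based position encoded by a ``pN`` / ``PN`` label."""
    m = _LABEL_RE.match(label)
    if m is None:
        raise ValueError(f"not a position label: {label!r}")
    return int(m.group(1))


def read_fasta(path, anchor: int = 1, allow_ambiguous: bool = False) -> list[ProteinRecord]:
    """Read a (multi-record) FASTA file of protein sequences.

    Sequences are uppercased; every record receives ``anchor`` (default 1).
    Raises ``ValueError`` for an empty file or an illegal residue character.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            ProteinRecord(
                id=rec.id,
                sequence=str(rec.seq).upper(),
                anchor=anchor,
                allow_ambiguous=allow_ambiguous,
            )
        )
    if not records:
        raise ValueError(f"no sequences in {path}")
    return records


def write_fasta(records: list[ProteinRecord], path) -> None:
    """Write records as unwrapped FASTA (one sequence line per record)."""
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=None)
        writer.write_file(seqs)
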