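"""Genome container and FASTA round-tripping.

A :class:`Genome` is an ordered mapping of contig id to an uppercase
``A/C/G/T/N`` sequence string.  Sequences are validated on construction; all
internal coordinates in this package are 0-based half-open, converted to the
1-based inclusive convention only at I/O boundaries.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InputDataError

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Genome:
    """Named contigs of uppercase nucleotide sequence.

    Parameters
    ----------
    contigs
        Ordered mapping of contig id to sequence.  Ids must be unique and
        non-empty; sequences must be non-empty and drawn from ``ACGTN``.
    """

    contigs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cid, seq in self.contigs.items():
            if not cid:
                raise InputDataError("contig id must be non-empty")
            if not seq:
                raise InputDataError(f"contig {cid!r}: sequence must be non-empty")
            bad = set(seq) - VALID_BASES
            if bad:
                pos = next(i for i, c in enumerate(seq) if c in bad)
                raise InputDataError(
                    f"contig {cid!r}: invalid character {seq[pos]!r} at position {pos}"
                )

    def __len__(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Genome):
            return NotImplemented
        return self.contigs == other.contigs

    def fetch(self, contig: str, start: int, end: int) -> str:
        """Sub-sequence of a contig (0-based half-open, clamped to bounds)."""
        seq = self.contigs[contig]
        return seq[max(0, start) : min(len(seq), end)]


def read_fasta(path: str | Path) -> Genome:
    """Load a FASTA file into a :class:`Genome` (sequences uppercased)."""
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in contigs:
            raise InputDataError(f"duplicate contig id {rec.id!r} in {path}")
        contigs[rec.id] = str(rec.seq).upper()
    if not contigs:
        raise InputDataError(f"no sequences found in {path}")
    return Genome(contigs)


def write_fasta(genome: Genome, path: str | Path, width: int = 70) -> None:
    """Write a genome as FASTA, wrapping sequence lines at `width` columns."""
    records = [
        SeqRecord(Seq(seq), id=cid, description="") for cid, seq in genome.contigs.items()
    ]
    buf = io.StringIO()
    writer = SeqIO.FastaIO.FastaWriter(buf, wrap=width)
    writer.write_file(records)
    Path(path).write_text(buf.getvalue())
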