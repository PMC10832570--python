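"""Aligned-read records and SAM round-tripping (via pysam).

Only the alignment features the audit consumes are modelled: mapped primary
single-end reads with M/I/D/S CIGAR ops on the forward coordinate system.
Quality strings are not used anywhere in the analysis and are written as
absent (``*``).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pysam

from .errors import InputDataError
from .genome import Genome

CIGAR_OPS = "MIDS"
_PYSAM_OP = {0: "M", 1: "I", 2: "D", 4: "S"}
_OP_PYSAM = {v: k for k, v in _PYSAM_OP.items()}

REF_CONSUMING = frozenset("MD")
READ_CONSUMING = frozenset("MIS")


@dataclass
class AlignedRead:
    """A mapped single-end read.

    ``pos`` is the 0-based leftmost reference offset; ``cigar`` is a tuple of
    ``(op, length)`` pairs with op in ``MIDS``.
    """

    id: str
    contig: str
    pos: int
    cigar: tuple[tuple[str, int], ...]
    seq: str
    mapped: bool = True
    strand: str = "+"

    def validate(self) -> None:
        read_len = sum(n for op, n in self.cigar if op in READ_CONSUMING)
        if read_len != len(self.seq):
            raise InputDataError(
                f"read {self.id!r}: CIGAR consumes {read_len} read bases "
                f"but sequence has {len(self.seq)}"
            )
        for op, n in self.cigar:
            if op not in CIGAR_OPS or n < 1:
                raise InputDataError(f"read {self.id!r}: malformed CIGAR op {(op, n)!r}")

    @property
    def ref_end(self) -> int:
        """0-based exclusive rightmost reference position covered."""
        return self.pos + sum(n for op, n in self.cigar if op in REF_CONSUMING)


def read_sam(path: str | Path) -> list[AlignedRead]:
    """Load mapped, primary alignments from a SAM (or BAM) file."""
    reads: list[AlignedRead] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            cigar = []
            for code, n in rec.cigartuples or []:
                if code not in _PYSAM_OP:
                    raise InputDataError(
                        f"read {rec.query_name!r}: unsupported CIGAR op code {code}"
                    )
                cigar.append((_PYSAM_OP[code], n))
            read = AlignedRead(
                id=rec.query_name,
                contig=rec.reference_name,
                pos=rec.reference_start,
                cigar=tuple(cigar),
                seq=rec.query_sequence or "",
                strand="-" if rec.is_reverse else "+",
            )
            read.validate()
            reads.append(read)
    return reads


def sam_header(genome: Genome) -> dict:
    return {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": cid, "LN": len(seq)} for cid, seq in genome.contigs.items()],
    }


def write_sam(reads: list[AlignedRead], genome: Genome, path: str | Path) -> None:
    """Write reads as a coordinate-sorted SAM v1 file with a valid header."""
    header = sam_header(genome)
    tid = {cid: i for i, cid in enumerate(genome.contigs)}
    ordered = sorted(reads, key=lambda r: (tid[r.contig], r.pos))
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in ordered:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = r.id
            seg.flag = 16 if r.strand == "-" else 0
            seg.reference_id = tid[r.contig]
            seg.reference_start = r.pos
            seg.mapping_quality = 60
            seg.cigartuples = [(_OP_PYSAM[op], n) for op, n in r.cigar]
            seg.query_sequence = r.seq
            out.write(seg)
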