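"""Turning discrepancy calls into consensus edits and a curated assembly.

An :class:`Edit` records the short-technology consensus for one called track:
the corrected run length is the short-read modal run.  Edits are validated
against the sequence they claim to change (base and reference run length must
match at the stated coordinates) and applied per contig in descending
coordinate order so earlier coordinates stay valid.  Inserted or deleted
bases are placed at the track's right edge internally — within a homopolymer
every placement is sequence-equivalent — while the optional VCF output
reports the standard left-normalised form with the anchor-base convention.

Only ``called`` sites become edits; ``low_coverage`` and ``ambiguous`` sites
belong in a side report for manual review.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .detect import STATUS_CALLED, DiscrepancyCall
from .errors import ConsistencyError, InputDataError
from .genome import Genome, write_fasta


@dataclass(frozen=True)
class Edit:
    """One homopolymer run-length correction.

    ``position`` is the 1-based coordinate of the track's last reference
    base; the track footprint is ``[position - ref_run + 1, position]``
    (1-based inclusive).
    """

    contig: str
    position: int
    base: str
    ref_run: int
    new_run: int
    n_span_short: int
    modal_count: int

    @property
    def delta(self) -> int:
        return self.new_run - self.ref_run

    def validate(self) -> None:
        if self.delta == 0:
            raise ConsistencyError(f"edit at {self.contig}:{self.position}: delta must be non-zero")
        if self.new_run < 1:
            raise ConsistencyError(f"edit at {self.contig}:{self.position}: new_run must be >= 1")

    @property
    def footprint(self) -> tuple[int, int]:
        """0-based half-open track footprint."""
        return (self.position - self.ref_run, self.position)


def edits_from_calls(calls: list[DiscrepancyCall]) -> list[Edit]:
    """One edit per ``called`` entry, new_run = short-technology modal run.

    Raises if a non-called entry slips through, if a modal length is missing,
    or if two edits overlap on a contig.
    """
    edits = []
    for c in calls:
        if c.status != STATUS_CALLED:
            raise InputDataError(
                f"edits_from_calls: call at {c.track.key} has status {c.status!r}; "
                "only 'called' entries are accepted"
            )
        if c.short_modal is None:
            raise ConsistencyError(f"call at {c.track.key}: missing short-tech modal run")
        e = Edit(
            contig=c.track.contig,
            position=c.track.end,
            base=c.track.base,
            ref_run=c.track.length,
            new_run=c.short_modal,
            n_span_short=c.n_span_short,
            modal_count=c.short_modal_count,
        )
        e.validate()
        edits.append(e)
    edits.sort(key=lambda e: (e.contig, e.position))
    prev: Edit | None = None
    for e in edits:
        if prev is not None and e.contig == prev.contig and e.footprint[0] < prev.footprint[1]:
            raise ConsistencyError(
                f"overlapping edits at {prev.contig}:{prev.position} and {e.contig}:{e.position}"
            )
        prev = e
    return edits


def apply_edits(genome: Genome, edits: list[Edit]) -> Genome:
    """Apply validated edits; corrected length = original + sum of deltas.

    Every edit is checked against the sequence (run base and length at the
    stated coordinates) before any change is made; a mismatch rejects the
    whole batch and leaves the genome untouched.
    """
    by_contig: dict[str, list[Edit]] = {}
    for e in edits:
        e.validate()
        if e.contig not in genome.contigs:
            raise InputDataError(f"edit references unknown contig {e.contig!r}")
        by_contig.setdefault(e.contig, []).append(e)

    for cid, es in by_contig.items():
        seq = genome.contigs[cid]
        es.sort(key=lambda e: e.position)
        for a, b in zip(es, es[1:]):
            if b.footprint[0] < a.footprint[1]:
                raise ConsistencyError(
                    f"overlapping edits at {cid}:{a.position} and {cid}:{b.position}"
                )
        for e in es:
            s, t = e.footprint
            if s < 0 or t > len(seq) or seq[s:t] != e.base * e.ref_run:
                raise InputDataError(
                    f"edit at {cid}:{e.position}: sequence does not show a "
                    f"{e.base}x{e.ref_run} run at the stated coordinates"
                )
            if s > 0 and seq[s - 1] == e.base or t < len(seq) and seq[t] == e.base:
                raise InputDataError(
                    f"edit at {cid}:{e.position}: stated run is not maximal in the sequence"
                )

    contigs = dict(genome.contigs)
    for cid, es in by_contig.items():
        seq = contigs[cid]
        # single pass over ascending positions (equivalent to descending-order
        # in-place application, but linear in genome size)
        parts: list[str] = []
        prev = 0
        for e in es:
            s, t = e.footprint
            if e.delta > 0:
                parts.append(seq[prev:t])
                parts.append(e.base * e.delta)
            else:
                parts.append(seq[prev : t + e.delta])
            prev = t
        parts.append(seq[prev:])
        contigs[cid] = "".join(parts)
    return Genome(contigs)


EDIT_COLUMNS = ["contig", "pos_1based", "base", "ref_run", "new_run", "delta", "n_span_short"]


def write_edits_tsv(edits: list[Edit], path: str | Path) -> None:
    rows = [
        {
            "contig": e.contig, "pos_1based": e.position, "base": e.base,
            "ref_run": e.ref_run, "new_run": e.new_run, "delta": e.delta,
            "n_span_short": e.n_span_short,
        }
        for e in edits
    ]
    pd.DataFrame(rows, columns=EDIT_COLUMNS).to_csv(path, sep="\t", index=False)


def write_edits_vcf(genome: Genome, edits: list[Edit], path: str | Path) -> None:
    """Minimal VCF v4.2 of the edits as left-normalised indels on the input genome.

    For a run starting at 0-based ``s``, the anchor base is the reference base
    at ``s - 1`` and POS is its 1-based coordinate ``s``; an insertion of k
    run bases is ``REF=anchor, ALT=anchor + base*k`` and a deletion of k run
    bases is ``REF=anchor + base*k, ALT=anchor``.  A run at the very start of
    a contig falls back to right-anchoring on the first run base.
    """
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=RUN,Number=1,Type=Integer,Description="Reference homopolymer run length">',
    ]
    for cid, seq in genome.contigs.items():
        lines.append(f"##contig=<ID={cid},length={len(seq)}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for e in sorted(edits, key=lambda e: (e.contig, e.position)):
        seq = genome.contigs[e.contig]
        s, t = e.footprint
        k = abs(e.delta)
        if s > 0:
            anchor = seq[s - 1]
            pos = s  # 1-based coordinate of the anchor base
            if e.delta > 0:
                ref, alt = anchor, anchor + e.base * k
            else:
                ref, alt = anchor + e.base * k, anchor
        else:
            pos = 1
            if e.delta > 0:
                ref, alt = e.base, e.base * (k + 1)
            else:
                ref, alt = e.base * (k + 1), e.base
        lines.append(f"{e.contig}\t{pos}\t.\t{ref.upper()}\t{alt.upper()}\t.\tPASS\tRUN={e.ref_run}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_outputs(
    genome: Genome,
    edits: list[Edit],
    out_prefix: str | Path,
    original_genome: Genome | None = None,
    vcf: bool = False,
) -> dict[str, Path]:
    """Corrected FASTA + edits TSV (+ optional VCF against the original genome)."""
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": prefix.with_suffix(".fasta"),
        "edits": Path(str(prefix) + ".edits.tsv"),
    }
    write_fasta(genome, paths["fasta"])
    write_edits_tsv(edits, paths["edits"])
    if vcf:
        if original_genome is None:
            raise InputDataError("VCF output requires the original (pre-edit) genome")
        paths["vcf"] = Path(str(prefix) + ".edits.vcf")
        write_edits_vcf(original_genome, edits, paths["vcf"])
    return paths
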