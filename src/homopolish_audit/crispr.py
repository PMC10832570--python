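"""CRISPR direct-repeat array detection tolerant of IS interruption.

A CRISPR array is a ladder of near-identical direct repeats (~23-50 bp)
separated by unique spacers (~15-70 bp).  In IS-rich genomes an array is
often fragmented: a mobile element lands inside it and splits it into
segments that still share one repeat consensus.  The detector here therefore
has two stages:

1. ``detect_arrays`` — a period-seeded detector in the spirit of CRT: exact
   ``seed_k``-mer recurrences at a near-constant period (one repeat + one
   spacer) nominate candidate repeat ladders; the repeat unit is then
   extended left and right while per-column agreement across the ladder stays
   at or above ``1 - max_mismatch_frac``; a candidate is accepted when the
   repeat-length, spacer-length and minimum-repeat-count constraints all
   hold.  Overlapping candidates are resolved greedily by descending repeat
   count, then leftmost start.
2. ``merge_interrupted`` — adjacent accepted arrays on one contig are merged
   into a single cluster when the gap between them is at most
   ``merge_max_gap`` (default 5 kb, wide enough for one or two nested IS
   copies) and their consensi agree within ``max_mismatch_frac`` edit
   distance (either orientation).

Arrays are reported on the forward strand; the strand flag records the
orientation of the consensus relative to its lexicographically canonical
form, so detection commutes with reverse-complementing the genome.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path

import edlib
import pandas as pd

from .errors import ConfigurationError
from .genome import Genome, revcomp


@dataclass(frozen=True)
class ArrayParams:
    """Detection windows; defaults comfortably contain 36-bp repeats with ~30-bp spacers."""

    repeat_len_min: int = 23
    repeat_len_max: int = 50
    spacer_len_min: int = 15
    spacer_len_max: int = 70
    min_repeats: int = 3
    max_mismatch_frac: float = 0.1
    seed_k: int = 8
    merge_max_gap: int = 5000

    def validate(self) -> None:
        if not self.repeat_len_min < self.repeat_len_max:
            raise ConfigurationError("repeat_len_min must be < repeat_len_max")
        if not self.spacer_len_min < self.spacer_len_max:
            raise ConfigurationError("spacer_len_min must be < spacer_len_max")
        if not 0 <= self.max_mismatch_frac < 0.5:
            raise ConfigurationError("max_mismatch_frac must be in [0, 0.5)")
        if self.min_repeats < 2:
            raise ConfigurationError("min_repeats must be >= 2")
        if self.seed_k < 4 or self.seed_k > self.repeat_len_min:
            raise ConfigurationError("seed_k must be in [4, repeat_len_min]")

    @property
    def period_min(self) -> int:
        return self.repeat_len_min + self.spacer_len_min

    @property
    def period_max(self) -> int:
        return self.repeat_len_max + self.spacer_len_max


@dataclass
class RepeatArray:
    """One detected array or merged cluster.

    ``segments`` are ``(start, end, n_repeats)`` spans of uninterrupted
    repeat ladder; a freshly detected array has one segment, a merged cluster
    several.  ``repeats`` and ``spacers`` are ``(start, end)`` coordinate
    pairs (0-based half-open) across all segments; spacers between segments
    (the interrupting inserts) are not listed.
    """

    contig: str
    segments: list[tuple[int, int, int]]
    repeats: list[tuple[int, int]]
    spacers: list[tuple[int, int]]
    consensus: str
    strand: str
    relaxed_extra: int = 0  # degenerate terminal repeats beyond the strict count

    @property
    def start(self) -> int:
        return self.segments[0][0]

    @property
    def end(self) -> int:
        return self.segments[-1][1]

    @property
    def total_repeats(self) -> int:
        return sum(n for _, _, n in self.segments)

    def repeat_sequences(self, genome: Genome) -> list[str]:
        return [genome.fetch(self.contig, s, e) for s, e in self.repeats]

    def spacer_sequences(self, genome: Genome) -> list[str]:
        return [genome.fetch(self.contig, s, e) for s, e in self.spacers]


def _consensus(columns: list[str]) -> str:
    return "".join(Counter(col).most_common(1)[0][0] for col in columns)


def _column_ok(seq: str, positions: list[int], offset: int, frac: float) -> bool:
    bases = []
    for s in positions:
        p = s + offset
        if p < 0 or p >= len(seq):
            return False
        bases.append(seq[p])
    top = Counter(bases).most_common(1)[0][1]
    return top / len(bases) >= 1 - frac


def _extend_unit(seq: str, seeds: list[int], params: ArrayParams) -> tuple[int, int]:
    """Extend the exact seed left/right by column agreement; returns (left, right) offsets.

    The repeat unit becomes ``[s - left, s + seed_k + right)`` for each seed
    position ``s``.  Extension respects repeat_len_max and keeps every
    inter-seed gap long enough to leave a spacer of at least spacer_len_min.
    """
    min_gap = min(b - a for a, b in zip(seeds, seeds[1:]))
    frac = params.max_mismatch_frac
    left = right = 0
    while True:
        length = params.seed_k + left + right
        if length >= params.repeat_len_max or length >= min_gap - params.spacer_len_min:
            break
        if _column_ok(seq, seeds, params.seed_k + right, frac):
            right += 1
        elif _column_ok(seq, seeds, -(left + 1), frac):
            left += 1
        else:
            break
    # push remaining extension on whichever side still agrees
    while (
        params.seed_k + left + right < min(params.repeat_len_max, min_gap - params.spacer_len_min)
        and _column_ok(seq, seeds, -(left + 1), frac)
    ):
        left += 1
    return left, right


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def _candidate_from_chain(seq: str, contig: str, chain: list[int], params: ArrayParams):
    left, right = _extend_unit(seq, chain, params)
    rep_len = params.seed_k + left + right
    if not params.repeat_len_min <= rep_len <= params.repeat_len_max:
        return None
    starts = [s - left for s in chain]
    # trim ladder ends whose spacer length falls outside the window
    def spacer_ok(a: int, b: int) -> bool:
        return params.spacer_len_min <= b - (a + rep_len) <= params.spacer_len_max

    while len(starts) >= 2 and not spacer_ok(starts[0], starts[1]):
        starts = starts[1:]
    while len(starts) >= 2 and not spacer_ok(starts[-2], starts[-1]):
        starts = starts[:-1]
    if len(starts) < params.min_repeats:
        return None
    if any(not spacer_ok(a, b) for a, b in zip(starts, starts[1:])):
        return None
    if starts[0] < 0 or starts[-1] + rep_len > len(seq):
        return None

    instances = [seq[s : s + rep_len] for s in starts]
    cons = _consensus([
        "".join(inst[i] for inst in instances) for i in range(rep_len)
    ])
    max_d = int(params.max_mismatch_frac * rep_len)
    # drop terminal instances too far from consensus (degenerate edges)
    while starts and _hamming(seq[starts[0] : starts[0] + rep_len], cons) > max_d:
        starts = starts[1:]
    while starts and _hamming(seq[starts[-1] : starts[-1] + rep_len], cons) > max_d:
        starts = starts[:-1]
    if len(starts) < params.min_repeats:
        return None

    # relaxed terminal counting: period-spaced neighbours within twice the budget
    relaxed = 0
    period = starts[1] - starts[0] if len(starts) > 1 else rep_len + params.spacer_len_min
    for probe in (starts[0] - period, starts[-1] + period):
        if 0 <= probe and probe + rep_len <= len(seq):
            if _hamming(seq[probe : probe + rep_len], cons) <= 2 * max_d + 1:
                relaxed += 1

    repeats = [(s, s + rep_len) for s in starts]
    spacers = [(a + rep_len, b) for (a, _), (b, _) in zip(repeats, repeats[1:])]
    strand = "+" if cons <= revcomp(cons) else "-"
    return RepeatArray(
        contig=contig,
        segments=[(starts[0], starts[-1] + rep_len, len(starts))],
        repeats=repeats,
        spacers=spacers,
        consensus=cons,
        strand=strand,
        relaxed_extra=relaxed,
    )


def detect_arrays(genome: Genome, params: ArrayParams = ArrayParams()) -> list[RepeatArray]:
    """Find unmerged repeat arrays on every contig (forward-strand coordinates)."""
    params.validate()
    out: list[RepeatArray] = []
    for cid, seq in genome.contigs.items():
        k = params.seed_k
        positions: dict[str, list[int]] = defaultdict(list)
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" not in kmer:
                positions[kmer].append(i)

        candidates: list[RepeatArray] = []
        for kmer, pos in positions.items():
            if len(pos) < params.min_repeats:
                continue
            chain = [pos[0]]
            for p in pos[1:]:
                gap = p - chain[-1]
                if params.period_min <= gap <= params.period_max:
                    chain.append(p)
                else:
                    if len(chain) >= params.min_repeats:
                        cand = _candidate_from_chain(seq, cid, chain, params)
                        if cand:
                            candidates.append(cand)
                    chain = [p]
            if len(chain) >= params.min_repeats:
                cand = _candidate_from_chain(seq, cid, chain, params)
                if cand:
                    candidates.append(cand)

        # greedy non-overlap resolution: most repeats first, then leftmost
        candidates.sort(key=lambda a: (-a.total_repeats, a.start))
        taken: list[tuple[int, int]] = []
        for cand in candidates:
            if any(cand.start < e and s < cand.end for s, e in taken):
                continue
            taken.append((cand.start, cand.end))
            out.append(cand)
    order = {cid: i for i, cid in enumerate(genome.contigs)}
    out.sort(key=lambda a: (order[a.contig], a.start))
    return out


def _consensus_compatible(a: str, b: str, frac: float) -> bool:
    budget = int(frac * max(len(a), len(b)))
    d_fwd = edlib.align(a, b, task="distance")["editDistance"]
    d_rev = edlib.align(a, revcomp(b), task="distance")["editDistance"]
    return min(d_fwd, d_rev) <= budget


def merge_interrupted(
    arrays: list[RepeatArray], params: ArrayParams = ArrayParams()
) -> list[RepeatArray]:
    """Merge adjacent same-consensus arrays separated by <= merge_max_gap.

    Merging is order-independent (input is re-sorted) and idempotent (a
    merged cluster's consensus is that of its largest segment, so re-merging
    changes nothing).
    """
    params.validate()
    ordered = sorted(arrays, key=lambda a: (a.contig, a.start))
    clusters: list[RepeatArray] = []
    for arr in ordered:
        if clusters:
            cur = clusters[-1]
            gap = arr.start - cur.end
            if (
                arr.contig == cur.contig
                and 0 <= gap <= params.merge_max_gap
                and _consensus_compatible(cur.consensus, arr.consensus, params.max_mismatch_frac)
            ):
                dominant = cur if cur.total_repeats >= arr.total_repeats else arr
                clusters[-1] = RepeatArray(
                    contig=cur.contig,
                    segments=cur.segments + arr.segments,
                    repeats=cur.repeats + arr.repeats,
                    spacers=cur.spacers + arr.spacers,
                    consensus=dominant.consensus,
                    strand=dominant.strand,
                    relaxed_extra=cur.relaxed_extra + arr.relaxed_extra,
                )
                continue
        clusters.append(replace(arr, segments=list(arr.segments)))
    return clusters


def write_arrays_gff3(arrays: list[RepeatArray], path: str | Path) -> None:
    """GFF3 with cluster / segment / repeat / spacer features (1-based inclusive)."""
    lines = ["##gff-version 3"]
    for i, a in enumerate(arrays, 1):
        cid = f"cluster{i}"
        lines.append(
            f"{a.contig}\thomopolish_audit\trepeat_cluster\t{a.start + 1}\t{a.end}\t.\t{a.strand}\t.\t"
            f"ID={cid};total_repeats={a.total_repeats};consensus={a.consensus}"
        )
        for j, (s, e, n) in enumerate(a.segments, 1):
            lines.append(
                f"{a.contig}\thomopolish_audit\trepeat_segment\t{s + 1}\t{e}\t.\t{a.strand}\t.\t"
                f"ID={cid}.seg{j};Parent={cid};n_repeats={n}"
            )
        for j, (s, e) in enumerate(a.repeats, 1):
            lines.append(
                f"{a.contig}\thomopolish_audit\tdirect_repeat\t{s + 1}\t{e}\t.\t{a.strand}\t.\t"
                f"ID={cid}.rep{j};Parent={cid}"
            )
        for j, (s, e) in enumerate(a.spacers, 1):
            lines.append(
                f"{a.contig}\thomopolish_audit\tspacer\t{s + 1}\t{e}\t.\t{a.strand}\t.\t"
                f"ID={cid}.spc{j};Parent={cid}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def arrays_to_frame(arrays: list[RepeatArray]) -> pd.DataFrame:
    rows = [
        {
            "cluster": i,
            "contig": a.contig,
            "start_1based": a.start + 1,
            "end_1based": a.end,
            "strand": a.strand,
            "n_segments": len(a.segments),
            "total_repeats": a.total_repeats,
            "relaxed_repeats": a.total_repeats + a.relaxed_extra,
            "consensus": a.consensus,
        }
        for i, a in enumerate(arrays, 1)
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "cluster", "contig", "start_1based", "end_1based", "strand",
            "n_segments", "total_repeats", "relaxed_repeats", "consensus",
        ],
    )


def write_arrays_tsv(arrays: list[RepeatArray], path: str | Path) -> None:
    arrays_to_frame(arrays).to_csv(path, sep="\t", index=False)
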