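"""Per-track read support and cross-technology discrepancy calling.

This is the computational heart of the curation workflow.  For every
candidate homopolymer track the pipeline asks each technology's reads two
questions: *how long is the run in this read* (``read_observed_run``), and
*what fraction of spanning reads contain a run of at least a given length*
(the containment fraction).  A systematic error is called where the
short-read evidence overwhelmingly supports a run length different from the
assembly while the long-read evidence does not.

Containment semantics
---------------------
At a site where the assembly itself is missing a base, every read trivially
"contains" the assembly's run, so containment against the reference length
carries no signal.  The informative quantity is containment at the *disputed*
run length — the longer of the reference run and the short-technology modal
run.  ``SupportSummary`` therefore keeps the full observed-run histogram;
``summarize_support`` reports ``f_contain`` against a caller-chosen target
(default: the reference run), and ``call_discrepancies`` re-evaluates both
technologies' containment at the disputed length.  At a genuine 1-bp error
site with the reported technology profiles this yields the familiar picture:
about 10% of long reads and about 95% of short reads contain the disputed
base.

Spanning and anchoring
----------------------
A read supports a track only when its alignment covers the track plus
``anchor`` bases on each side with M ops throughout the anchor windows
(soft-clips never anchor; reads with indels inside an anchor window are
non-spanning).  Insertions *at or inside* the track footprint are part of the
observed run when the inserted bases equal the run base — homopolymer indels
are placement-ambiguous, so an insertion at either footprint boundary is the
same event as one inside the run.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .alignments import AlignedRead
from .errors import InputDataError
from .tracks import HomopolymerTrack

DEFAULT_ANCHOR = 5
DEFAULT_MIN_SPAN = 10
DEFAULT_THETA_LONG_MAX = 0.5
DEFAULT_THETA_SHORT_MIN = 0.8

STATUS_CALLED = "called"
STATUS_NOT_CALLED = "not_called"
STATUS_LOW_COVERAGE = "low_coverage"
STATUS_AMBIGUOUS = "ambiguous"


def read_observed_run(
    read: AlignedRead, track: HomopolymerTrack, anchor: int = DEFAULT_ANCHOR
) -> int | None:
    """Observed run length of `track`'s base in one read, or None if non-spanning.

    Spanning requires M-op coverage of every reference position in
    ``[start - anchor, start)`` and ``[end, end + anchor)`` and no insertion
    strictly inside either anchor window.  The observed run counts read bases
    equal to the track base M-aligned within the footprint plus inserted
    copies of the base at insertions whose reference position lies in
    ``[start, end]`` (i.e. inside the footprint or at either boundary).
    """
    if read.contig != track.contig or not read.mapped:
        return None
    lo, hi = track.start - anchor, track.end + anchor
    if read.pos > lo or read.ref_end < hi:
        return None

    if len(read.cigar) == 1 and read.cigar[0][0] == "M":
        # fast path: ungapped read, anchors trivially satisfied
        off = track.start - read.pos
        return read.seq[off : off + track.length].count(track.base)

    need_m = set(range(lo, track.start)) | set(range(track.end, hi))
    run = 0
    ref = read.pos
    rd = 0
    for op, n in read.cigar:
        if op == "M":
            for k in range(n):
                p = ref + k
                if p in need_m:
                    need_m.discard(p)
                elif track.start <= p < track.end and read.seq[rd + k] == track.base:
                    run += 1
            ref += n
            rd += n
        elif op == "D":
            for k in range(n):
                if ref + k in need_m:
                    return None  # deletion inside an anchor window
            ref += n
        elif op == "I":
            if track.start <= ref <= track.end:
                run += sum(1 for c in read.seq[rd : rd + n] if c == track.base)
            elif lo < ref < track.start or track.end < ref < hi:
                return None  # insertion splits an anchor window
            rd += n
        elif op == "S":
            rd += n
        else:  # pragma: no cover - validated upstream
            raise InputDataError(f"read {read.id!r}: unsupported CIGAR op {op!r}")
    if need_m:
        return None  # anchor positions not M-covered
    return run


@dataclass
class SupportSummary:
    """Per-track, per-technology spanning-read support."""

    track: HomopolymerTrack
    tech: str
    n_span: int
    run_length_counts: dict[int, int]
    f_contain: float | None  # None (flagged undefined) when n_span == 0
    low_coverage: bool

    def contain_at(self, target: int) -> float | None:
        """Fraction of spanning reads with observed run >= `target`."""
        if self.n_span == 0:
            return None
        return sum(c for ln, c in self.run_length_counts.items() if ln >= target) / self.n_span

    def modal_run(self) -> tuple[int | None, bool]:
        """(modal observed run length, tie flag); (None, False) when empty."""
        if not self.run_length_counts:
            return None, False
        top = max(self.run_length_counts.values())
        modes = sorted(ln for ln, c in self.run_length_counts.items() if c == top)
        return modes[0], len(modes) > 1


def summarize_support(
    reads: list[AlignedRead],
    track: HomopolymerTrack,
    tech: str,
    anchor: int = DEFAULT_ANCHOR,
    min_span: int = DEFAULT_MIN_SPAN,
    target_run: int | None = None,
) -> SupportSummary:
    """Aggregate ``read_observed_run`` over `reads` for a single track."""
    counts: Counter[int] = Counter()
    for r in reads:
        obs = read_observed_run(r, track, anchor)
        if obs is not None:
            counts[obs] += 1
    n = sum(counts.values())
    target = track.length if target_run is None else target_run
    f = None if n == 0 else sum(c for ln, c in counts.items() if ln >= target) / n
    return SupportSummary(track, tech, n, dict(counts), f, n < min_span)


def support_table(
    reads: list[AlignedRead],
    tracks: list[HomopolymerTrack],
    tech: str,
    anchor: int = DEFAULT_ANCHOR,
    min_span: int = DEFAULT_MIN_SPAN,
) -> list[SupportSummary]:
    """Support summaries for many tracks in one sweep over the reads.

    Equivalent to calling :func:`summarize_support` per track but assigns each
    read to candidate tracks by bisection on track start, which keeps the
    whole-genome computation near-linear.
    """
    by_contig: dict[str, list[HomopolymerTrack]] = {}
    for t in tracks:
        by_contig.setdefault(t.contig, []).append(t)
    starts: dict[str, list[int]] = {}
    for cid, ts in by_contig.items():
        ts.sort(key=lambda t: t.start)
        starts[cid] = [t.start for t in ts]

    counters: dict[tuple, Counter[int]] = {t.key: Counter() for t in tracks}
    for r in reads:
        ts = by_contig.get(r.contig)
        if not ts:
            continue
        st = starts[r.contig]
        i = bisect_left(st, r.pos + anchor)
        end = r.ref_end
        while i < len(ts) and ts[i].start + anchor <= end:
            t = ts[i]
            if t.end + anchor <= end:
                obs = read_observed_run(r, t, anchor)
                if obs is not None:
                    counters[t.key][obs] += 1
            i += 1

    out = []
    for t in tracks:
        counts = counters[t.key]
        n = sum(counts.values())
        f = None if n == 0 else sum(c for ln, c in counts.items() if ln >= t.length) / n
        out.append(SupportSummary(t, tech, n, dict(counts), f, n < min_span))
    return out


@dataclass
class DiscrepancyCall:
    """Cross-technology verdict for one track.

    ``f_long`` / ``f_short`` are containment fractions at the disputed run
    length (max of reference run and short-technology modal run);
    ``delta_bp`` is short-tech modal run minus reference run.
    """

    track: HomopolymerTrack
    f_long: float | None
    f_short: float | None
    delta_bp: int
    n_span_long: int
    n_span_short: int
    short_modal: int | None
    long_modal: int | None
    status: str
    short_modal_count: int = 0  # short reads at the modal length (edit audit trail)


def call_discrepancies(
    long_summaries: list[SupportSummary],
    short_summaries: list[SupportSummary],
    theta_long_max: float = DEFAULT_THETA_LONG_MAX,
    theta_short_min: float = DEFAULT_THETA_SHORT_MIN,
    min_span: int = DEFAULT_MIN_SPAN,
) -> list[DiscrepancyCall]:
    """Pair summaries by track and call systematic discrepancies.

    A track is ``called`` when both technologies have at least `min_span`
    spanning reads, the short-technology modal run differs from the reference
    run, and containment at the disputed length separates the technologies:

    * modal > reference (assembly is missing bases): at most `theta_long_max`
      of long reads and at least `theta_short_min` of short reads contain the
      disputed run;
    * modal < reference (assembly has extra bases): the mirrored condition —
      at most ``1 - theta_short_min`` of short reads and at least
      ``1 - theta_long_max`` of long reads contain the reference run.

    A tie in the short-technology modal run yields ``ambiguous`` (a correction
    must be uniquely supported).  Unpaired tracks raise an error listing the
    orphans.
    """
    long_by = {s.track.key: s for s in long_summaries}
    short_by = {s.track.key: s for s in short_summaries}
    orphans = sorted(set(long_by) ^ set(short_by))
    if orphans:
        raise InputDataError(f"unpaired tracks between technologies: {orphans[:10]}")

    calls = []
    for key in long_by:
        ls, ss = long_by[key], short_by[key]
        track = ls.track
        ref = track.length
        modal_s, tie = ss.modal_run()
        modal_l, _ = ls.modal_run()
        disputed = ref if modal_s is None else max(ref, modal_s)
        f_long = ls.contain_at(disputed)
        f_short = ss.contain_at(disputed)
        delta = 0 if modal_s is None else modal_s - ref

        if ls.n_span < min_span or ss.n_span < min_span:
            status = STATUS_LOW_COVERAGE
        elif tie:
            status = STATUS_AMBIGUOUS
        elif delta == 0:
            status = STATUS_NOT_CALLED
        elif delta > 0:
            status = (
                STATUS_CALLED
                if f_long <= theta_long_max and f_short >= theta_short_min
                else STATUS_NOT_CALLED
            )
        else:
            status = (
                STATUS_CALLED
                if f_long >= 1 - theta_long_max and f_short <= 1 - theta_short_min
                else STATUS_NOT_CALLED
            )
        calls.append(
            DiscrepancyCall(
                track, f_long, f_short, delta, ls.n_span, ss.n_span, modal_s, modal_l,
                status, ss.run_length_counts.get(modal_s, 0) if modal_s is not None else 0,
            )
        )
    calls.sort(key=lambda c: (c.track.contig, c.track.start))
    return calls


CALL_COLUMNS = [
    "contig", "start_1based", "end_1based", "base", "ref_run",
    "n_span_long", "n_span_short", "f_long", "f_short",
    "modal_long", "modal_short", "modal_short_count", "delta_bp", "status",
]


def calls_to_frame(calls: list[DiscrepancyCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append({
            "contig": c.track.contig,
            "start_1based": c.track.start + 1,
            "end_1based": c.track.end,
            "base": c.track.base,
            "ref_run": c.track.length,
            "n_span_long": c.n_span_long,
            "n_span_short": c.n_span_short,
            "f_long": c.f_long,
            "f_short": c.f_short,
            "modal_long": c.long_modal,
            "modal_short": c.short_modal,
            "modal_short_count": c.short_modal_count,
            "delta_bp": c.delta_bp,
            "status": c.status,
        })
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


def write_calls_tsv(calls: list[DiscrepancyCall], path: str | Path) -> None:
    calls_to_frame(calls).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_calls_tsv(path: str | Path) -> list[DiscrepancyCall]:
    df = pd.read_csv(path, sep="\t")
    missing = set(CALL_COLUMNS) - set(df.columns)
    if missing:
        raise InputDataError(f"calls table {path}: missing columns {sorted(missing)}")
    out = []
    for r in df.itertuples():
        track = HomopolymerTrack(str(r.contig), int(r.start_1based) - 1, int(r.end_1based), str(r.base))
        out.append(
            DiscrepancyCall(
                track,
                None if pd.isna(r.f_long) else float(r.f_long),
                None if pd.isna(r.f_short) else float(r.f_short),
                int(r.delta_bp),
                int(r.n_span_long),
                int(r.n_span_short),
                None if pd.isna(r.modal_short) else int(r.modal_short),
                None if pd.isna(r.modal_long) else int(r.modal_long),
                str(r.status),
                0 if pd.isna(r.modal_short_count) else int(r.modal_short_count),
            )
        )
    return out


def plot_support(calls: list[DiscrepancyCall], path: str | Path) -> None:
    """Scatter of per-site containment fractions by technology (Fig-1A style)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pts = [(c.f_long, c.f_short) for c in calls if c.f_long is not None and c.f_short is not None]
    fig, ax = plt.subplots(figsize=(5, 4))
    if pts:
        xs = range(len(pts))
        ax.scatter(xs, [p[0] for p in pts], s=8, c="tab:blue", label="long tech")
        ax.scatter(xs, [p[1] for p in pts], s=8, c="tab:red", label="short tech")
    ax.set_xlabel("site index (genome order)")
    ax.set_ylabel("containment fraction at disputed run length")
    ax.set_ylim(-0.05, 1.05)
    ax.legend(loc="center right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
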