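"""Run-length extraction, support summaries and discrepancy calling."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.stats import binom

import homopolish_audit as ha
from homopolish_audit.alignments import AlignedRead
from homopolish_audit.detect import (
    DiscrepancyCall,
    SupportSummary,
    call_discrepancies,
    read_observed_run,
    summarize_support,
)
from homopolish_audit.errors import InputDataError
from homopolish_audit.tracks import HomopolymerTrack


def oracle_observed_run(read: AlignedRead, track: HomopolymerTrack, anchor: int):
    """Independent oracle: reconstruct the pairwise alignment column-by-column
    and count track-base read columns inside (or attached to) the footprint."""
    cols = []  # (ref_pos | None, attach_ref, read_char | None)
    ref, rd = read.pos, 0
    for op, n in read.cigar:
        for i in range(n):
            if op == "M":
                cols.append((ref, ref, read.seq[rd]))
                ref += 1
                rd += 1
            elif op == "D":
                cols.append((ref, ref, None))
                ref += 1
            elif op == "I":
                cols.append((None, ref, read.seq[rd]))
                rd += 1
            elif op == "S":
                cols.append((None, None, read.seq[rd]))
                rd += 1
    lo, hi = track.start - anchor, track.end + anchor
    m_positions = {c[0] for c in cols if c[0] is not None and c[2] is not None}
    for p in list(range(lo, track.start)) + list(range(track.end, hi)):
        if p not in m_positions:
            return None
    for c in cols:
        if c[0] is None and c[1] is not None:  # insertion column
            if lo < c[1] < track.start or track.end < c[1] < hi:
                return None
    run = 0
    for c in cols:
        if c[2] != track.base:
            continue
        if c[0] is not None and track.start <= c[0] < track.end:
            run += 1
        elif c[0] is None and c[1] is not None and track.start <= c[1] <= track.end:
            run += 1
    return run


TRACK = HomopolymerTrack("c", 10, 14, "G")
REF = "ACGTACGTAC" + "GGGG" + "TACGTACGTA"  # track footprint [10, 14)


def _read(pos, cigar, seq, rid="r"):
    r = AlignedRead(rid, "c", pos, tuple(cigar), seq)
    r.validate()
    return r


@pytest.mark.parametrize(
    "read,expected",
    [
        # fully matching read spanning the track -> reference run length
        (_read(0, [("M", 24)], REF), 4),
        # 1-bp deletion inside the footprint -> 3
        (_read(0, [("M", 11), ("D", 1), ("M", 12)], REF[:11] + REF[12:]), 3),
        # 1-bp G insertion at the right footprint boundary -> 5
        (_read(0, [("M", 14), ("I", 1), ("M", 10)], REF[:14] + "G" + REF[14:]), 5),
        # 1-bp G insertion at the left footprint boundary -> 5
        (_read(0, [("M", 10), ("I", 1), ("M", 14)], REF[:10] + "G" + REF[10:]), 5),
        # non-G insertion at the boundary adds nothing
        (_read(0, [("M", 14), ("I", 1), ("M", 10)], REF[:14] + "A" + REF[14:]), 4),
        # insertion strictly inside an anchor window -> non-spanning
        (_read(0, [("M", 7), ("I", 1), ("M", 17)], REF[:7] + "T" + REF[7:]), None),
        # deletion inside an anchor window -> non-spanning
        (_read(0, [("M", 16), ("D", 1), ("M", 7)], REF[:16] + REF[17:]), None),
        # too short to cover the anchors -> non-spanning
        (_read(8, [("M", 8)], REF[8:16]), None),
        # soft-clip never anchors
        (_read(6, [("S", 6), ("M", 12)], REF[:6] + REF[6:18]), None),
    ],
)
def test_read_observed_run_examples(read, expected):
    assert read_observed_run(read, TRACK, anchor=5) == expected
    assert oracle_observed_run(read, TRACK, anchor=5) == expected


def test_read_observed_run_matches_matrix_oracle():
    """Randomized CIGARs over random tracks agree with the column oracle."""
    rng = np.random.default_rng(99)
    bases = list("ACGT")
    for trial in range(300):
        n_ref = int(rng.integers(30, 80))
        ref = "".join(rng.choice(bases, size=n_ref))
        ts = int(rng.integers(8, n_ref - 12))
        te = ts + int(rng.integers(1, 7))
        track = HomopolymerTrack("c", ts, te, str(rng.choice(bases)))
        pos = int(rng.integers(0, 10))
        # random walk of CIGAR ops
        ops = []
        seq = []
        ref_i = pos
        if rng.random() < 0.2:
            k = int(rng.integers(1, 4))
            ops.append(("S", k))
            seq.append("".join(rng.choice(bases, size=k)))
        while ref_i < n_ref - int(rng.integers(0, 8)):
            op = rng.choice(["M", "M", "M", "I", "D"], p=[0.7, 0.1, 0.05, 0.08, 0.07])
            k = int(rng.integers(1, 6))
            if op == "M":
                k = min(k + 4, n_ref - ref_i)
                frag = list(ref[ref_i : ref_i + k])
                for j in range(k):  # occasional mismatches
                    if rng.random() < 0.05:
                        frag[j] = str(rng.choice(bases))
                seq.append("".join(frag))
                ops.append(("M", k))
                ref_i += k
            elif op == "I":
                seq.append("".join(rng.choice(bases, size=k)))
                ops.append(("I", k))
            else:
                k = min(k, n_ref - ref_i)
                ops.append(("D", k))
                ref_i += k
            if ref_i >= n_ref:
                break
        # collapse adjacent same ops to keep the CIGAR canonical
        canon = []
        for op, k in ops:
            if canon and canon[-1][0] == op:
                canon[-1] = (op, canon[-1][1] + k)
            else:
                canon.append((op, k))
        if not any(op == "M" for op, _ in canon):
            continue
        read = AlignedRead(f"t{trial}", "c", pos, tuple(canon), "".join(seq))
        read.validate()
        anchor = int(rng.integers(1, 6))
        assert read_observed_run(read, track, anchor) == oracle_observed_run(read, track, anchor)


def test_summarize_support_edges():
    s = summarize_support([], TRACK, "long")
    assert s.n_span == 0 and s.f_contain is None and s.low_coverage
    reads = [_read(0, [("M", 24)], REF, f"r{i}") for i in range(10)]
    s = summarize_support(reads, TRACK, "short")
    assert s.n_span == 10 and s.f_contain == 1.0 and not s.low_coverage
    assert s.modal_run() == (4, False)
    assert s.contain_at(5) == 0.0


def test_error_site_containment_within_binomial_bounds(small_run):
    """At simulated error sites, long-tech containment at the disputed length
    sits inside exact binomial 99% bounds around 1 - p_del_long = 0.10."""
    cfg = small_run.bundle.config
    checked = 0
    for c in small_run.called:
        n = c.n_span_long
        k = round(c.f_long * n)
        lo, hi = binom.ppf(0.0005, n, 0.10), binom.ppf(0.9995, n, 0.10)
        assert lo <= k <= hi
        checked += 1
    assert checked == sum(t.is_error_site for t in small_run.bundle.truth)


def _summary(track, counts, tech):
    n = sum(counts.values())
    f = sum(c for ln, c in counts.items() if ln >= track.length) / n if n else None
    return SupportSummary(track, tech, n, counts, f, n < 10)


def test_call_examples():
    t = HomopolymerTrack("c", 100, 104, "G")  # ref run 4
    # the reported regime: 90% of long reads omit, 95% of short reads contain
    ls = _summary(t, {4: 45, 5: 5}, "long")
    ss = _summary(t, {5: 38, 4: 2}, "short")
    (call,) = call_discrepancies([ls], [ss])
    assert call.status == "called" and call.delta_bp == 1
    assert call.f_long == pytest.approx(0.1) and call.f_short == pytest.approx(0.95)

    # perfect agreement -> not called
    ls = _summary(t, {4: 50}, "long")
    ss = _summary(t, {4: 40}, "short")
    (call,) = call_discrepancies([ls], [ss])
    assert call.status == "not_called" and call.delta_bp == 0

    # low coverage is never called
    ls = _summary(t, {4: 1, 5: 2}, "long")
    ss = _summary(t, {5: 38, 4: 2}, "short")
    (call,) = call_discrepancies([ls], [ss], min_span=10)
    assert call.status == "low_coverage"

    # tie in the short-tech mode -> ambiguous
    ls = _summary(t, {4: 45, 5: 5}, "long")
    ss = _summary(t, {4: 20, 5: 20}, "short")
    (call,) = call_discrepancies([ls], [ss])
    assert call.status == "ambiguous"


def test_call_deletion_direction():
    """Mirrored case: assembly has an extra base, short reads support one fewer."""
    t = HomopolymerTrack("c", 100, 105, "G")  # ref run 5
    ls = _summary(t, {5: 45, 4: 5}, "long")  # long reads contain the ref run
    ss = _summary(t, {4: 38, 5: 2}, "short")  # short reads say 4
    (call,) = call_discrepancies([ls], [ss])
    assert call.status == "called" and call.delta_bp == -1


def test_unpaired_tracks_raise():
    t1 = HomopolymerTrack("c", 100, 104, "G")
    t2 = HomopolymerTrack("c", 200, 204, "C")
    with pytest.raises(InputDataError, match="unpaired"):
        call_discrepancies([_summary(t1, {4: 20}, "long")], [_summary(t2, {4: 20}, "short")])


def test_full_synthetic_called_set_equals_truth(small_run):
    assert {c.track.key for c in small_run.called} == small_run.truth_error_keys


def test_sensitivity_and_specificity_over_seeds(multi_seed_runs):
    """Defaults recover >= 99% of truth error sites with zero false positives
    across ten independent simulations at 30x coverage."""
    total_truth = total_called = 0
    for run in multi_seed_runs:
        called = {c.track.key for c in run.called}
        truth = run.truth_error_keys
        assert not called - truth, "false positive discrepancy call"
        total_truth += len(truth)
        total_called += len(called & truth)
    assert total_called / total_truth >= 0.99


def test_threshold_monotonicity(small_run):
    """Raising theta_short_min or lowering theta_long_max never grows the call set."""
    ls, ss = small_run.long_support, small_run.short_support

    def called_at(tl, ts):
        return {
            c.track.key
            for c in call_discrepancies(ls, ss, theta_long_max=tl, theta_short_min=ts)
            if c.status == "called"
        }

    base = called_at(0.5, 0.8)
    assert called_at(0.5, 0.9) <= base
    assert called_at(0.3, 0.8) <= base
    assert called_at(0.3, 0.95) <= called_at(0.5, 0.9)


def test_labels_do_not_matter(small_run):
    """Behaviour depends on argument position (assembly vs evidence), not labels."""
    relabelled = [
        SupportSummary(s.track, "pacbio", s.n_span, s.run_length_counts, s.f_contain, s.low_coverage)
        for s in small_run.long_support
    ]
    calls = call_discrepancies(relabelled, small_run.short_support)
    assert [(c.track.key, c.status) for c in calls] == [
        (c.track.key, c.status) for c in small_run.calls
    ]


def test_calls_tsv_roundtrip(tmp_path, small_run):
    from homopolish_audit.detect import read_calls_tsv, write_calls_tsv

    p = tmp_path / "calls.tsv"
    write_calls_tsv(small_run.calls, p)
    back = read_calls_tsv(p)
    assert [(c.track.key, c.status, c.delta_bp, c.short_modal) for c in back] == [
        (c.track.key, c.status, c.delta_bp, c.short_modal) for c in small_run.calls
    ]
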