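"""Generator contracts: determinism, truth consistency, coverage, error encoding."""

from __future__ import annotations

import numpy as np
import pysam
import pytest
from scipy.stats import binom

import homopolish_audit as ha
from homopolish_audit.errors import ConfigurationError
from homopolish_audit.simulate import (
    SimulationConfig,
    TechnologyProfile,
    long_profile,
    write_simulation,
)

from conftest import small_config


def test_determinism_across_all_operations(tmp_path):
    cfg = small_config(seed=42)
    b1 = ha.simulate_bundle(cfg)
    b2 = ha.simulate_bundle(cfg)
    assert b1.genome == b2.genome
    assert b1.truth == b2.truth
    assert b1.reads == b2.reads
    d1, d2 = tmp_path / "a", tmp_path / "b"
    write_simulation(b1, d1)
    write_simulation(b2, d2)
    for name in ("reference.fasta", "truth.tsv", "reads_long.sam", "reads_short.sam"):
        assert (d1 / name).read_bytes() == (d2 / name).read_bytes()


def test_degenerate_gc_zero_background():
    cfg = SimulationConfig(
        genome_length=20_000, gc_fraction=0.0, seeded_tracks=(("C", 5, 1),),
        n_error_sites=0, read_length_long=300, read_length_short=100, seed=9,
    )
    genome, truth = ha.generate_reference(cfg)
    seq = genome.contigs[truth[0].contig]
    t = truth[0].track
    assert seq[t.start : t.end] == "CCCCC"
    assert set(seq[: t.start]) <= {"A", "T"} and set(seq[t.end :]) <= {"A", "T"}


def test_truth_consistency_rescan(small_run):
    """Re-scanning the emitted genome recovers every seeded track at its coordinates."""
    found = {t.key for t in small_run.tracks}
    for rec in small_run.bundle.truth:
        assert rec.track.key in found
    # error sites: emitted run is one short of the true run
    for rec in small_run.bundle.truth:
        if rec.is_error_site:
            assert rec.track.length == rec.true_run_length - 1
        else:
            assert rec.track.length == rec.true_run_length


def test_config_validation_errors():
    with pytest.raises(ConfigurationError, match="p_del_long"):
        small_config(seed=1, p_del_long=1.5).validate()
    with pytest.raises(ConfigurationError, match="n_error_sites"):
        small_config(seed=1, n_error_sites=1000).validate()
    with pytest.raises(ConfigurationError, match="genome_length"):
        small_config(seed=1, genome_length=500).validate()
    with pytest.raises(ConfigurationError, match="length"):
        small_config(seed=1, seeded_tracks=(("G", 12, 1),)).validate()
    with pytest.raises(ConfigurationError, match="cannot place"):
        ha.generate_reference(small_config(seed=1, genome_length=18_700))


def test_read_length_must_span_tracks():
    cfg = small_config(seed=1)
    genome, truth = ha.generate_reference(cfg)
    tiny = TechnologyProfile("long", 0.9, 5, 6)
    with pytest.raises(ConfigurationError, match="read_length"):
        ha.simulate_reads(genome, truth, tiny, seed=1)


def test_coverage_realism(small_run):
    """Realized mean depth within 10% of requested on a >= 50 kb genome."""
    cfg = small_run.bundle.config
    L = len(small_run.bundle.genome)
    for tech, cov, rl in (("long", cfg.coverage_long, cfg.read_length_long),
                          ("short", cfg.coverage_short, cfg.read_length_short)):
        total = sum(len(r.seq) for r in small_run.bundle.reads[tech])
        assert abs(total / L - cov) / cov < 0.10


def test_p_del_one_reads_match_short_assembly():
    """p_del=1: every error-spanning read omits the base, i.e. matches the
    emitted (one-base-short) reference with a pure match CIGAR."""
    cfg = small_config(seed=7, p_del_long=1.0)
    genome, truth = ha.generate_reference(cfg)
    reads = ha.simulate_reads(genome, truth, long_profile(cfg), seed=5)
    assert all(r.cigar == (("M", cfg.read_length_long),) for r in reads)
    for r in reads:
        assert r.seq == genome.contigs[r.contig][r.pos : r.pos + len(r.seq)]


def test_p_del_zero_reads_carry_the_insertion():
    """p_del=0: every read spanning an error site contains the full true run,
    encoded as exactly one insertion of the missing base inside the track."""
    cfg = small_config(seed=7, p_del_long=0.0)
    genome, truth = ha.generate_reference(cfg)
    reads = ha.simulate_reads(genome, truth, long_profile(cfg), seed=5)
    err = [t for t in truth if t.is_error_site]
    n_ins = 0
    for r in reads:
        spanning = [
            t for t in err
            if r.pos <= t.track.start - 1 and t.track.end + 1 <= r.pos + cfg.read_length_long
        ]
        ins_ops = [(op, n) for op, n in r.cigar if op == "I"]
        if spanning:
            (t,) = spanning  # track separation guarantees at most one
            assert ins_ops == [("I", 1)]
            # insertion sits at the track's left edge (left-aligned)
            assert r.cigar[0] == ("M", t.track.start - r.pos)
            n_ins += 1
        else:
            assert ins_ops == []
    assert n_ins > 0


def test_deletion_fraction_within_binomial_bounds():
    """One error site, p_del=0.9, 50x: realized omission fraction lies in the
    exact binomial 99% interval for the realized spanning-read count."""
    cfg = SimulationConfig(
        genome_length=30_000, seeded_tracks=(("G", 4, 1),), n_error_sites=1,
        coverage_long=50, read_length_long=300, read_length_short=100, seed=21,
    )
    genome, truth = ha.generate_reference(cfg)
    reads = ha.simulate_reads(genome, truth, long_profile(cfg), seed=77)
    t = truth[0].track
    # the generator's Bernoulli draw applies to reads whose 300-bp window
    # contains the track with at least one base of flank on each side
    spanning = [
        r for r in reads if r.pos <= t.start - 1 and t.end + 1 <= r.pos + 300
    ]
    n = len(spanning)
    omitted = sum(1 for r in spanning if len(r.cigar) == 1)
    lo, hi = binom.ppf(0.005, n, 0.9), binom.ppf(0.995, n, 0.9)
    assert lo <= omitted <= hi


def test_write_simulation_files(tmp_path, small_run):
    paths = write_simulation(small_run.bundle, tmp_path / "sim")
    # FASTA round-trips through the package's own reader
    assert ha.read_fasta(paths["fasta"]) == small_run.bundle.genome
    # truth TSV row count equals seeded track count and round-trips
    from homopolish_audit.simulate import read_truth_tsv

    truth_back = read_truth_tsv(paths["truth"])
    assert truth_back == small_run.bundle.truth
    # SAM: alignment line count, mapped primary flags, coordinate sorted
    for tech in ("long", "short"):
        with pysam.AlignmentFile(paths[f"sam_{tech}"]) as fh:
            recs = list(fh)
        assert len(recs) == len(small_run.bundle.reads[tech])
        assert all(not r.is_unmapped and not r.is_secondary for r in recs)
        assert all(r.flag in (0, 16) for r in recs)
        pos = [r.reference_start for r in recs]
        assert pos == sorted(pos)
    # reads round-trip through the package's SAM reader
    back = ha.read_sam(paths["sam_long"])
    orig = sorted(small_run.bundle.reads["long"], key=lambda r: r.pos)
    assert [(r.pos, r.cigar, r.seq) for r in back] == [(r.pos, r.cigar, r.seq) for r in orig]


def test_write_simulation_empty_reads(tmp_path, small_run):
    bundle = ha.SimulationBundle(
        small_run.bundle.config, small_run.bundle.genome, small_run.bundle.truth,
        {"long": []},
    )
    paths = write_simulation(bundle, tmp_path / "empty")
    lines = paths["sam_long"].read_text().splitlines()
    assert all(l.startswith("@") for l in lines)  # header only


def test_multi_bp_deltas():
    cfg = small_config(seed=13, multi_bp_deltas=(2, 3))
    genome, truth = ha.generate_reference(cfg)
    deltas = sorted(
        t.true_run_length - t.track.length for t in truth if t.is_error_site
    )
    assert deltas.count(2) == 1 and deltas.count(3) == 1 and deltas.count(1) == 18


def test_true_genome_restores_missing_bases(small_run):
    tg = ha.true_genome(small_run.bundle.genome, small_run.bundle.truth)
    n_err = sum(t.is_error_site for t in small_run.bundle.truth)
    assert len(tg) == len(small_run.bundle.genome) + n_err
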