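"""Synthetic genomes and pre-aligned reads for two sequencing-technology profiles.

The generator emulates the situation the curation pipeline exists for: a
GC-rich bacterial assembly built from long reads that is systematically one
base short at a designated subset of its G/C homopolymer tracks.  Concretely:

* ``generate_reference`` emits the *assembly under audit* (the long-read
  consensus).  At each designated error site the biologically correct run is
  one or more bases longer than what the assembly records; the truth table
  carries the correct length.
* ``simulate_reads`` emits reads of the *true* sequence aligned against that
  assembly.  A read spanning an error site omits the extra base(s) with
  per-read probability ``p_del`` (the long-read profile uses 0.90, the
  short-read profile 0.05, the regime reported for PacBio vs Illumina); a
  read that does contain them shows up as a 1-bp (or k-bp) insertion in its
  CIGAR, left-aligned within the run as standard indel normalisation does.
  All other bases match the reference exactly.

Reads are emitted pre-aligned (SAM with ground-truth CIGARs) rather than as
FASTQ so that no external mapper enters the test path; real users supply
mapper-produced SAM/BAM.  Reads are single-end and carry no quality model —
the downstream analysis consumes only containment counts.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .alignments import AlignedRead, write_sam
from .errors import ConfigurationError, InputDataError
from .genome import Genome, write_fasta
from .tracks import HomopolymerTrack

CONTIG_ID = "sim_chr"

_DEFAULT_SEEDED = (
    ("G", 4, 65),
    ("C", 4, 65),
    ("G", 5, 30),
    ("C", 5, 30),
    ("G", 6, 30),
    ("C", 6, 30),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic curation experiment.

    Defaults reproduce the reported cross-technology regime: a GC-rich
    chromosome (66% GC), 250 seeded G/C tracks of reference length 4-6 among
    the thousands that arise in the background sequence, 200 of them
    systematic-error sites, long reads omitting the disputed base with
    probability 0.90 and short reads with probability 0.05, 50x coverage for
    both technologies.

    ``seeded_tracks`` entries are ``(base, length, count)`` where *length* is
    the run length recorded in the emitted reference; at error sites the true
    run is ``length + delta`` (delta 1 by default, or taken from
    ``multi_bp_deltas`` for the first few sites to emulate the rarer 2-3 bp
    losses).
    """

    genome_length: int = 600_000
    gc_fraction: float = 0.66
    seeded_tracks: tuple[tuple[str, int, int], ...] = _DEFAULT_SEEDED
    n_error_sites: int = 200
    p_del_long: float = 0.90
    p_del_short: float = 0.05
    coverage_long: float = 50.0
    coverage_short: float = 50.0
    read_length_long: int = 1000
    read_length_short: int = 150
    multi_bp_deltas: tuple[int, ...] = ()
    seed: int = 0

    def validate(self) -> None:
        for name in ("gc_fraction", "p_del_long", "p_del_short"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        for name in ("coverage_long", "coverage_short"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        for base, length, count in self.seeded_tracks:
            if base not in ("G", "C"):
                raise ConfigurationError(f"seeded_tracks: base must be G or C, got {base!r}")
            if not 4 <= length <= 8:
                raise ConfigurationError(f"seeded_tracks: length must be in [4, 8], got {length}")
            if count < 0:
                raise ConfigurationError("seeded_tracks: count must be >= 0")
        if self.n_error_sites > self.total_seeded:
            raise ConfigurationError(
                f"n_error_sites ({self.n_error_sites}) exceeds seeded track count "
                f"({self.total_seeded})"
            )
        if self.genome_length <= 2 * self.max_read_length:
            raise ConfigurationError(
                "genome_length must exceed 2 x max read length "
                f"({self.genome_length} <= {2 * self.max_read_length})"
            )
        for d in self.multi_bp_deltas:
            if d < 2:
                raise ConfigurationError("multi_bp_deltas entries must be >= 2")
        if len(self.multi_bp_deltas) > self.n_error_sites:
            raise ConfigurationError("multi_bp_deltas longer than n_error_sites")

    @property
    def total_seeded(self) -> int:
        return sum(c for _, _, c in self.seeded_tracks)

    @property
    def max_read_length(self) -> int:
        return max(self.read_length_long, self.read_length_short)

    @property
    def max_seeded_length(self) -> int:
        return max((ln for _, ln, _ in self.seeded_tracks), default=0)


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one seeded track (coordinates on the emitted reference)."""

    contig: str
    track: HomopolymerTrack
    is_error_site: bool
    true_run_length: int


@dataclass(frozen=True)
class TechnologyProfile:
    """Per-technology read parameters; two canonical profiles ship as helpers."""

    label: str
    p_del: float
    coverage: float
    read_length: int


def long_profile(config: SimulationConfig) -> TechnologyProfile:
    return TechnologyProfile("long", config.p_del_long, config.coverage_long, config.read_length_long)


def short_profile(config: SimulationConfig) -> TechnologyProfile:
    return TechnologyProfile("short", config.p_del_short, config.coverage_short, config.read_length_short)


def _stage_seeds(seed: int) -> tuple[int, int, int]:
    """Derive independent per-stage substreams (reference, long, short) from one seed."""
    children = np.random.SeedSequence(seed).spawn(3)
    return tuple(int(c.generate_state(1)[0] % 2**31) for c in children)


def generate_reference(config: SimulationConfig) -> tuple[Genome, list[TruthRecord]]:
    """Build the assembly-under-audit and its ground-truth track table.

    The background is i.i.d. with the requested GC fraction; seeded tracks
    are written at deterministic jittered grid positions at least
    ``2 x max read length`` apart, with flanking bases forced to differ from
    the run base so every seeded run is maximal at its recorded coordinates.
    """
    config.validate()
    ref_seed, _, _ = _stage_seeds(config.seed)
    rng = np.random.default_rng(ref_seed)

    L = config.genome_length
    gc = config.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    alphabet = np.frombuffer(b"ACGT", dtype="S1")
    seq = rng.choice(alphabet, size=L, p=probs)

    spec = [(b, ln) for b, ln, c in config.seeded_tracks for _ in range(c)]
    k = len(spec)
    truth: list[TruthRecord] = []
    if k > 0:
        spec = [spec[i] for i in rng.permutation(k)]
        margin = config.max_read_length
        sep = 2 * config.max_read_length
        maxlen = config.max_seeded_length
        slot = (L - 2 * margin) // k
        jitter_max = slot - sep - maxlen - 2
        if slot <= 0 or jitter_max < 1:
            raise ConfigurationError(
                "seeded_tracks: cannot place "
                f"{k} tracks with >= {sep} bp separation in a {L} bp genome"
            )
        starts = [
            margin + i * slot + int(rng.integers(1, jitter_max + 1)) for i in range(k)
        ]
        error_idx = set(rng.choice(k, size=config.n_error_sites, replace=False).tolist())
        bg_prob = dict(zip("ACGT", probs))
        deltas_left = list(config.multi_bp_deltas)
        err_rank = 0
        for i, (start, (base, length)) in enumerate(zip(starts, spec)):
            seq[start : start + length] = np.bytes_(base)
            # flanks forced to differ from the run base (maximality) but drawn
            # from the background composition so degenerate GC settings stay clean
            choices = [b for b in "ACGT" if b != base]
            w = np.array([bg_prob[b] for b in choices])
            w = w / w.sum()
            seq[start - 1] = np.bytes_(str(rng.choice(choices, p=w)))
            seq[start + length] = np.bytes_(str(rng.choice(choices, p=w)))
            is_err = i in error_idx
            if is_err:
                delta = deltas_left[err_rank] if err_rank < len(deltas_left) else 1
                err_rank += 1
            else:
                delta = 0
            truth.append(
                TruthRecord(
                    contig=CONTIG_ID,
                    track=HomopolymerTrack(CONTIG_ID, start, start + length, base),
                    is_error_site=is_err,
                    true_run_length=length + delta,
                )
            )
    genome = Genome({CONTIG_ID: seq.tobytes().decode("ascii")})
    truth.sort(key=lambda t: t.track.start)
    return genome, truth


def true_genome(genome: Genome, truth: list[TruthRecord]) -> Genome:
    """The biologically correct sequence: reference with the missing bases restored."""
    contigs = dict(genome.contigs)
    by_contig: dict[str, list[TruthRecord]] = {}
    for rec in truth:
        if rec.is_error_site:
            by_contig.setdefault(rec.contig, []).append(rec)
    for cid, recs in by_contig.items():
        seq = contigs[cid]
        for rec in sorted(recs, key=lambda r: -r.track.start):
            delta = rec.true_run_length - rec.track.length
            seq = seq[: rec.track.end] + rec.track.base * delta + seq[rec.track.end :]
        contigs[cid] = seq
    return Genome(contigs)


def simulate_reads(
    genome: Genome,
    truth: list[TruthRecord],
    tech: TechnologyProfile,
    seed: int,
) -> list[AlignedRead]:
    """Tile the genome with single-end reads of one technology profile.

    Read starts are uniform over the contig; each read fully spanning an
    error-site track (with at least one anchoring base on each side)
    independently contains the track's missing base(s) with probability
    ``1 - p_del``, encoded as an insertion of the run base left-aligned at
    the track start.  Every other read base matches the reference, so the
    emitted CIGARs are exact ground truth.
    """
    if tech.read_length <= max((r.track.length for r in truth), default=0) + 2:
        raise ConfigurationError(
            f"read_length ({tech.read_length}) must exceed the longest seeded "
            "track length + 2 so reads can span tracks with anchors"
        )
    rng = np.random.default_rng(seed)
    reads: list[AlignedRead] = []
    for cid, seq in genome.contigs.items():
        L = len(seq)
        if tech.read_length > L:
            raise ConfigurationError(
                f"read_length ({tech.read_length}) exceeds contig {cid!r} length ({L})"
            )
        n_reads = int(round(tech.coverage * L / tech.read_length))
        starts = np.sort(rng.integers(0, L - tech.read_length + 1, size=n_reads))
        strands = rng.random(n_reads) < 0.5
        contains = np.zeros(n_reads, dtype=bool)
        site_of = np.full(n_reads, -1, dtype=np.int64)
        err = [r for r in truth if r.is_error_site and r.contig == cid]
        for j, rec in enumerate(err):
            t = rec.track
            # reads fully containing [start-1, end+1)
            lo = bisect_left(starts, t.end + 1 - tech.read_length)
            hi = bisect_right(starts, t.start - 1)
            if hi > lo:
                idx = np.arange(lo, hi)
                site_of[idx] = j
                contains[idx] = rng.random(hi - lo) >= tech.p_del
        for i in range(n_reads):
            s = int(starts[i])
            rid = f"{tech.label}_{cid}_{i:07d}"
            strand = "-" if strands[i] else "+"
            if contains[i]:
                rec = err[site_of[i]]
                t = rec.track
                delta = rec.true_run_length - t.length
                pre = t.start - s
                post = tech.read_length - delta - pre
                rseq = seq[s : t.start] + t.base * delta + seq[t.start : s + tech.read_length - delta]
                cigar = (("M", pre), ("I", delta), ("M", post))
                reads.append(AlignedRead(rid, cid, s, cigar, rseq, strand=strand))
            else:
                reads.append(
                    AlignedRead(
                        rid, cid, s, (("M", tech.read_length),),
                        seq[s : s + tech.read_length], strand=strand,
                    )
                )
    return reads


@dataclass
class SimulationBundle:
    """Everything one simulated experiment produces, held in memory."""

    config: SimulationConfig
    genome: Genome
    truth: list[TruthRecord]
    reads: dict[str, list[AlignedRead]] = field(default_factory=dict)


def simulate_bundle(config: SimulationConfig) -> SimulationBundle:
    """Reference + truth + reads for both technology profiles, one call."""
    genome, truth = generate_reference(config)
    _, seed_long, seed_short = _stage_seeds(config.seed)
    reads = {
        "long": simulate_reads(genome, truth, long_profile(config), seed_long),
        "short": simulate_reads(genome, truth, short_profile(config), seed_short),
    }
    return SimulationBundle(config, genome, truth, reads)


TRUTH_COLUMNS = ["contig", "start_1based", "end_1based", "base", "true_len", "is_error_site"]


def write_truth_tsv(truth: list[TruthRecord], path: str | Path) -> None:
    rows = [
        {
            "contig": r.contig,
            "start_1based": r.track.start + 1,
            "end_1based": r.track.end,
            "base": r.track.base,
            "true_len": r.true_run_length,
            "is_error_site": int(r.is_error_site),
        }
        for r in truth
    ]
    pd.DataFrame(rows, columns=TRUTH_COLUMNS).to_csv(path, sep="\t", index=False)


def read_truth_tsv(path: str | Path) -> list[TruthRecord]:
    df = pd.read_csv(path, sep="\t")
    missing = set(TRUTH_COLUMNS) - set(df.columns)
    if missing:
        raise InputDataError(f"truth table {path}: missing columns {sorted(missing)}")
    return [
        TruthRecord(
            contig=str(r.contig),
            track=HomopolymerTrack(
                str(r.contig), int(r.start_1based) - 1, int(r.end_1based), str(r.base)
            ),
            is_error_site=bool(r.is_error_site),
            true_run_length=int(r.true_len),
        )
        for r in df.itertuples()
    ]


def write_simulation(bundle: SimulationBundle, out_dir: str | Path) -> dict[str, Path]:
    """Emit reference FASTA, one coordinate-sorted SAM per technology, truth TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"fasta": out / "reference.fasta", "truth": out / "truth.tsv"}
    write_fasta(bundle.genome, paths["fasta"])
    write_truth_tsv(bundle.truth, paths["truth"])
    for tech, reads in bundle.reads.items():
        p = out / f"reads_{tech}.sam"
        write_sam(reads, bundle.genome, p)
        paths[f"sam_{tech}"] = p
    return paths
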