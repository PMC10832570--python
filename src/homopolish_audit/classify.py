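"""Stratified error rates by homopolymer context and flank-signature tests.

``stratify`` assigns every called site to its exact (base, length) census
cell, giving per-length error rates with disjoint denominators (the curated
M.-hassiacum-style picture: most errors at length-4 G/C tracks, with the
per-class rate rising slowly with track length).

The two flank analyses ask whether error sites carry any proximal sequence
signature in the 20 bp on each side of the track:

* ``flank_gc_test`` — a label-permutation test on mean flank GC content,
  with add-one smoothing so p is never exactly zero;
* ``kmer_enrichment`` — site-level k-mer presence/absence contingency tables
  with two-sided Fisher exact p-values and Benjamini-Hochberg adjustment
  across all k-mers observed in either group.  This replaces external motif
  suites: "no signature" becomes "no significant k-mer".

Controls are non-called tracks matched on (base, length); flanks exclude the
track itself and are truncated (and flagged) at contig ends.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .detect import STATUS_CALLED, DiscrepancyCall
from .errors import ConfigurationError, ConsistencyError, InputDataError
from .genome import Genome
from .tracks import Census, HomopolymerTrack

DEFAULT_FLANK = 20
DEFAULT_N_PERM = 10_000


@dataclass
class StratifiedRates:
    """Per-(base, length) error counts against census denominators."""

    table: pd.DataFrame  # columns: base, length, n_errors, n_tracks, rate

    def rate(self, base: str, length: int) -> float:
        sel = self.table[(self.table.base == base) & (self.table.length == length)]
        return 0.0 if sel.empty else float(sel.rate.iloc[0])

    def combined_gc(self, length: int) -> tuple[int, int, float]:
        """(n_errors, n_tracks, rate) pooled over G and C at exactly `length`."""
        sel = self.table[self.table.length == length]
        ne, nt = int(sel.n_errors.sum()), int(sel.n_tracks.sum())
        return ne, nt, (ne / nt if nt else 0.0)

    @property
    def total_errors(self) -> int:
        return int(self.table.n_errors.sum())


def stratify(calls: list[DiscrepancyCall], census: Census) -> StratifiedRates:
    """Assign called tracks to exact (base, length) cells; rates use census denominators."""
    errors: dict[tuple[str, int], int] = {}
    for c in calls:
        if c.status != STATUS_CALLED:
            continue
        key = (c.track.base, c.track.length)
        if census.count(*key) == 0:
            raise ConsistencyError(
                f"called track {c.track.key} has no census cell {key}; "
                "census must be computed with the same min_len/bases as the call set"
            )
        errors[key] = errors.get(key, 0) + 1
    rows = []
    for (base, length), n_tracks in sorted(census.counts.items()):
        n_err = errors.get((base, length), 0)
        rows.append({
            "base": base, "length": length,
            "n_errors": n_err, "n_tracks": n_tracks,
            "rate": n_err / n_tracks if n_tracks else 0.0,
        })
    return StratifiedRates(pd.DataFrame(rows, columns=["base", "length", "n_errors", "n_tracks", "rate"]))


@dataclass
class FlankProfile:
    """Flank sequences for one site (track excluded), truncation-flagged."""

    track: HomopolymerTrack
    upstream: str
    downstream: str
    truncated: bool
    group: str  # "error" | "control"

    @property
    def joint(self) -> str:
        return self.upstream + self.downstream

    @property
    def gc_fraction(self) -> float:
        s = self.joint
        if not s:
            return float("nan")
        return sum(1 for c in s if c in "GC") / len(s)


def extract_flanks(
    genome: Genome,
    tracks: list[HomopolymerTrack],
    flank_len: int = DEFAULT_FLANK,
    group: str = "error",
) -> list[FlankProfile]:
    out = []
    for t in tracks:
        up = genome.fetch(t.contig, t.start - flank_len, t.start)
        down = genome.fetch(t.contig, t.end, t.end + flank_len)
        out.append(
            FlankProfile(t, up, down, len(up) < flank_len or len(down) < flank_len, group)
        )
    return out


def match_controls(
    error_tracks: list[HomopolymerTrack],
    candidate_tracks: list[HomopolymerTrack],
    max_ratio: int = 10,
    seed: int = 0,
) -> list[HomopolymerTrack]:
    """Non-error tracks matched on (base, length), subsampled to `max_ratio` x errors."""
    err_keys = {t.key for t in error_tracks}
    want: dict[tuple[str, int], int] = {}
    for t in error_tracks:
        want[(t.base, t.length)] = want.get((t.base, t.length), 0) + 1
    rng = np.random.default_rng(seed)
    out: list[HomopolymerTrack] = []
    for cell, n_err in sorted(want.items()):
        pool = [
            t for t in candidate_tracks
            if (t.base, t.length) == cell and t.key not in err_keys
        ]
        cap = max_ratio * n_err
        if len(pool) > cap:
            idx = rng.choice(len(pool), size=cap, replace=False)
            pool = [pool[i] for i in sorted(idx)]
        out.extend(pool)
    return out


@dataclass
class FlankGCResult:
    mean_error: float
    mean_control: float
    observed_diff: float
    p_value: float
    n_perm: int


def flank_gc_test(
    genome: Genome,
    error_sites: list[HomopolymerTrack],
    control_sites: list[HomopolymerTrack],
    flank_len: int = DEFAULT_FLANK,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> FlankGCResult:
    """Permutation test on |mean flank GC difference| between error and control sites.

    p = (b + 1) / (n_perm + 1) where b counts label permutations achieving an
    absolute mean difference >= the observed one.  Deterministic given `seed`.
    """
    if n_perm < 100:
        raise ConfigurationError(f"n_perm must be >= 100, got {n_perm}")
    if not error_sites or not control_sites:
        raise InputDataError("flank_gc_test: both groups must be non-empty")
    gc_err = np.array([f.gc_fraction for f in extract_flanks(genome, error_sites, flank_len)])
    gc_ctl = np.array([f.gc_fraction for f in extract_flanks(genome, control_sites, flank_len)])
    pooled = np.concatenate([gc_err, gc_ctl])
    n_e = len(gc_err)
    observed = abs(gc_err.mean() - gc_ctl.mean())
    rng = np.random.default_rng(seed)
    b = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if abs(perm[:n_e].mean() - perm[n_e:].mean()) >= observed - 1e-12:
            b += 1
    return FlankGCResult(
        float(gc_err.mean()), float(gc_ctl.mean()), float(observed),
        (b + 1) / (n_perm + 1), n_perm,
    )


def bh_adjust(pvalues: "np.ndarray | list[float]") -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (monotone in p rank)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _site_kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)} if len(seq) >= k else set()


def kmer_enrichment(
    error_flanks: list[FlankProfile],
    control_flanks: list[FlankProfile],
    k: int = 4,
    alpha: float = 0.05,
    per_side: bool = False,
) -> pd.DataFrame:
    """Site-level k-mer presence/absence enrichment between flank groups.

    For every k-mer observed in either group, a 2x2 table of sites
    containing/not containing it is tested with a two-sided Fisher exact
    test; q-values are BH-adjusted across all tested k-mers.  By default the
    two flanks of a site are concatenated; ``per_side=True`` treats each side
    as its own site-sequence.

    Returns a DataFrame (kmer, count_error, count_control, odds_ratio,
    p_value, q_value, significant) sorted by q then p.
    """
    if not error_flanks or not control_flanks:
        raise InputDataError("kmer_enrichment: both groups must be non-empty")
    min_len = min(
        min(len(f.upstream) for f in error_flanks + control_flanks),
        min(len(f.downstream) for f in error_flanks + control_flanks),
    ) if per_side else min(len(f.joint) for f in error_flanks + control_flanks)
    if k < 1 or k > min_len:
        raise InputDataError(f"k ({k}) must be in [1, shortest flank sequence ({min_len})]")

    def presence(flanks: list[FlankProfile]) -> list[set[str]]:
        if per_side:
            return [_site_kmers(f.upstream, k) | _site_kmers(f.downstream, k) for f in flanks]
        return [_site_kmers(f.joint, k) for f in flanks]

    pres_e = presence(error_flanks)
    pres_c = presence(control_flanks)
    n_e, n_c = len(pres_e), len(pres_c)
    universe = sorted(set().union(*pres_e, *pres_c))
    rows = []
    for kmer in universe:
        a = sum(1 for s in pres_e if kmer in s)
        c = sum(1 for s in pres_c if kmer in s)
        table = [[a, n_e - a], [c, n_c - c]]
        odds, p = fisher_exact(table, alternative="two-sided")
        rows.append({"kmer": kmer, "count_error": a, "count_control": c,
                     "odds_ratio": odds, "p_value": p})
    df = pd.DataFrame(rows, columns=["kmer", "count_error", "count_control", "odds_ratio", "p_value"])
    if not df.empty:
        df["q_value"] = bh_adjust(df.p_value.to_numpy())
        df["significant"] = df.q_value <= alpha
        df = df.sort_values(["q_value", "p_value", "kmer"], ignore_index=True)
    else:
        df["q_value"] = []
        df["significant"] = []
    return df


def all_kmers(k: int) -> list[str]:
    """All 4^k nucleotide k-mers in lexicographic order."""
    return ["".join(t) for t in product("ACGT", repeat=k)]
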