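# Methods

## The error model

The analysis targets *systematic* homopolymer under-calls in a long-read
assembly: loci where most long reads share the same 1-bp deletion within a
G/C run, while an independent short-read technology reads the full run.  The
assembly under audit therefore records a run of length `r` where the
biologically correct sequence has `r + δ` (δ = 1 in almost all cases; δ = 2
or 3 occurs rarely and is supported).  Against that assembly, a read that
contains the full true run shows a δ-bp insertion in its CIGAR at the track;
a read that omits the base(s) aligns as a pure match.  Random per-read
sequencing noise is deliberately *not* modelled — the phenomenon of interest
is the shared miscall, and the analysis consumes only containment counts.

## Synthetic data generator

`SimulationConfig` defaults encode the study conditions used throughout the
tests and the acceptance script:

| parameter | default | meaning |
|---|---|---|
| `genome_length` | 600 000 bp | i.i.d. background sequence |
| `gc_fraction` | 0.66 | GC-rich background (the motivating genome is ~66% GC); background G/C runs of length ≥ 4 arise naturally in the thousands |
| `seeded_tracks` | 250 tracks, lengths 4–6 | G/C runs written at jittered grid positions, ≥ 2× max read length apart, flanks forced to differ from the run base (maximality) |
| `n_error_sites` | 200 | seeded tracks whose true run is one base longer than the emitted reference records |
| `p_del_long` / `p_del_short` | 0.90 / 0.05 | per-read probability of omitting the disputed base, the reported long/short regime |
| `coverage_long` / `coverage_short` | 50× / 50× | mean depth; read count = coverage × L / read length |
| `read_length_long` / `read_length_short` | 1000 / 150 bp | single-end |

Reads are emitted pre-aligned (SAM with ground-truth CIGARs, FLAG 0/16,
fixed MAPQ, no qualities) so no external mapper enters the test path.
Insertions are left-aligned within the run, matching standard indel
normalisation.  The per-track separation of 2× read length guarantees a read
spans at most one error site, so each spanning read's Bernoulli draw is
independent.

What the generator does **not** emulate: base-call noise and quality
strings, paired ends, chimeric or supplementary alignments, mapping
ambiguity, coverage waves, or error sites outside seeded tracks.  Passing
tests therefore demonstrate the correctness of the counting, calling and
editing machinery under the systematic-error model — not robustness to
mapper artefacts in real data, where thresholds exist for exactly that
reason.

## Containment and discrepancy calling

For a track `[s, e)` of base `b`, a read is *spanning* when its alignment
covers `[s - a, e + a)` with match ops throughout both anchor windows
(default `a = 5`; soft-clips never anchor; an indel inside an anchor window
disqualifies the read).  Its *observed run* is the number of `b` bases
M-aligned inside the footprint plus inserted `b` bases at insertions whose
reference position lies in `[s, e]` — insertions at either footprint
boundary are the same event as insertions inside the run, because
homopolymer indel placement is ambiguous.

The *containment fraction at target t* is the fraction of spanning reads
with observed run ≥ t.  At a site where the assembly itself is missing a
base, containment at the assembly's own run length is identically 1 for both
technologies and carries no signal; the informative quantity is containment
at the **disputed length** `d = max(r, m)`, where `m` is the short-read
modal observed run.  `SupportSummary` therefore stores the full observed-run
histogram (plus containment at the reference length for reporting), and
`call_discrepancies` evaluates `f_long` and `f_short` at `d`.  A site is
**called** when both technologies have ≥ `min_span` (default 10) spanning
reads, `m ≠ r`, and:

* `m > r` (assembly missing bases): `f_long ≤ θ_long_max` (default 0.5) and
  `f_short ≥ θ_short_min` (default 0.8);
* `m < r` (assembly with extra bases): the mirrored condition,
  `f_long ≥ 1 − θ_long_max` and `f_short ≤ 1 − θ_short_min`.

A tie for the short-read mode yields `ambiguous` (a correction must be
uniquely supported); insufficient depth yields `low_coverage`; both are
listed in a review report, never corrected.  The thresholds sit far from
both the error regime (0.10 / 0.95 at 50×) and the clean regime (1.0 / 1.0),
so calling is insensitive to their exact values; they are config-exposed.

Candidate sites default to G/C tracks of length ≥ 4 from the scanner.  A
`min_len=1`, all-bases scan is available for errors outside that class, off
by default for speed.

## Correction

`new_run` is the short-read modal run.  Edits are validated against the
sequence (base, run length, maximality at the stated coordinates) before any
change; application is equivalent to descending-coordinate in-place editing
but implemented as a single linear pass.  Internally bases are added or
removed at the run's right edge; the optional VCF reports the standard
left-normalised anchor-base form (for a run at a contig start, the record
falls back to right-anchoring on the first run base).  Length conservation —
|corrected| − |original| = Σδ — is an invariant checked in tests, including
a 483-site construction on a ~5.27-Mb genome.

## Census and stratified rates

The census is by **exact** run length: a length-6 run is one length-6 track,
never also a length-4 track, so per-length denominators are disjoint — this
matches reporting error percentages per length class.  G and C runs are
distinct cells, with combined G+C totals also reported.  `N` truncates runs;
tracks never span contig boundaries; circular origin-spanning runs are
joined only under an explicit `circular` flag (origin-spanning homopolymers
are vanishingly unlikely, and the linear default preserves standard-format
coordinate semantics).  Whether published per-length counts are exact-length
or minimum-length classes is not always stated; anyone comparing against a
deposited genome should check both conventions.

## Flank signature tests

Controls are non-called tracks matched on (base, exact length), subsampled
to 10× the error-set size with a seeded RNG when the pool is larger (power
vs runtime).  Flanks are 20 bp per side, excluding the track, truncated and
flagged at contig ends; the two sides are concatenated by default.

* **GC test** — label permutation on the absolute difference of group mean
  flank GC; add-one smoothing `p = (b + 1)/(n_perm + 1)` (default
  `n_perm = 10 000`) avoids zero p-values.
* **k-mer enrichment** — site-level presence/absence per k-mer (default
  `k = 4`), two-sided Fisher exact tests, Benjamini–Hochberg adjustment
  across all k-mers observed in either group, significance at `q ≤ α`
  (default 0.05).  This replaces external motif-discovery suites: "no
  proximal signature" is operationalised as "no significant k-mer".
  Position-weight-matrix discovery and long-range structural effects are out
  of scope.

## CRISPR array detection

A CRT-style period-seeded detector, written from scratch: exact `seed_k`-mer
(default 8) recurrences whose successive gaps fall in
`[repeat_min + spacer_min, repeat_max + spacer_max]` nominate repeat
ladders; the unit is extended left/right while per-column agreement across
ladder instances is ≥ 1 − `max_mismatch_frac` (default 0.1); acceptance
requires repeat length 23–50 bp, spacer lengths 15–70 bp and ≥ 3 repeats.
Degenerate terminal instances beyond the mismatch budget are trimmed from
the strict count but probed at one period's distance with a doubled budget
and reported as a relaxed count, since published repeat totals may include
partially degenerate terminal repeats.  Overlapping candidates are resolved
greedily by descending repeat count, then leftmost start.  The strand flag
records the consensus orientation against its lexicographically canonical
form, making detection commute with reverse-complementing the genome.

Clusters: adjacent arrays merge when the gap is ≤ `merge_max_gap` (default
5 kb — one or two nested IS copies of ~1.3–1.6 kb, without bridging
unrelated loci) and consensi agree within the mismatch budget by edit
distance in either orientation.  Merging is order-independent and
idempotent; the cluster consensus is that of the largest segment.
Cas-gene identification is out of scope; reports carry flanking coordinates
for neighbourhood inspection.

## Interval bookkeeping

All user-facing coordinates are 1-based inclusive (the convention of
published locus claims); computation is 0-based half-open internally.
Because the packaged IS table records starts without strand or per-copy
size, `start_in` is the default overlap mode; `any_overlap` requires sizes.
Footprint fractions use union semantics and, from the per-family table, are
computable only for complete elements (incomplete-element sizes are printed
as ranges), hence reported as a lower bound.  `bp_to_aa` is plain
`bp / 3` — deliberately following the arithmetic of the printed loci it is
validated against, although CDS conventions usually subtract the stop
codon; this is the documented, intentional behaviour.  The packaged gene
table preserves one internal inconsistency of its source (a 583 aa /
3,885,552 entry against 584 aa / 3,985,552 in the accompanying text)
verbatim, flagged in a `note` column; the text values are treated as
authoritative in tests.

## Problem sizes and determinism

The test suite runs the full study conditions (600 kb, 200 error sites,
50×) once, ten independent 30× simulations of 80 kb with 20 error sites
each for the sensitivity/recovery properties, 100 random 10–50-kb sequences
for scanner/oracle equivalence, and 40 random 50-kb sequences for the
CRISPR false-positive rate — sizes chosen so the whole suite completes in a
couple of minutes while keeping every binomial margin wide.  All randomness
flows through explicit integer seeds (one top-level seed spawns per-stage
substreams via `numpy.random.SeedSequence`), so every simulation, test and
pipeline run is bit-reproducible.

## Known limitations

* Detection assumes reads are already aligned sensibly; it never realigns,
  and quality scores are ignored.
* Substitution errors and non-homopolymer indels are out of scope.
* At 30× with 150-bp short reads, a site's short-read spanning count can dip
  into the low twenties, where the default `θ_short_min = 0.8` occasionally
  leaves a true site one read short of calling (observed ~0.5% of sites);
  such sites land in the review report rather than being force-called.
* The deletion-direction call (assembly with an extra base) is implemented
  and tested on constructed summaries, but the generator's default scenario
  exercises only the dominant missing-base direction.
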