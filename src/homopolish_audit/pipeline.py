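"""End-to-end orchestration: scan -> detect -> classify -> correct (-> crispr, intervals).

``run_pipeline`` consumes a :class:`RunConfig` (buildable from a YAML file),
executes the enabled stages in order, writes every stage's machine-readable
output under the run directory, and finishes with a JSON summary whose every
number is recomputable from those stage outputs alone.  One top-level seed
derives per-stage substreams so stage-level reruns match pipeline runs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import classify, correct, crispr, detect, intervals, simulate, tracks
from .alignments import read_sam
from .errors import AuditError, ConfigurationError
from .genome import read_fasta

logger = logging.getLogger("homopolish_audit")


@dataclass
class RunConfig:
    """Paths, stage toggles and stage parameters for one pipeline run.

    Either ``simulate=True`` (inputs are generated) or `fasta`, `long_sam`
    and `short_sam` must point at existing files.  CLI flags override config
    values; config values override the defaults below.
    """

    out_dir: str = "audit_run"
    seed: int = 0
    # inputs
    simulate: bool = False
    fasta: str | None = None
    long_sam: str | None = None
    short_sam: str | None = None
    feature_table: str | None = None
    feature_intervals: list[dict] = field(default_factory=list)  # {family, contig, start, end}
    # stage toggles
    run_scan: bool = True
    run_detect: bool = True
    run_classify: bool = True
    run_correct: bool = True
    run_crispr: bool = False
    run_intervals: bool = False
    # stage parameters
    min_len: int = 4
    bases: str = "GC"
    anchor: int = detect.DEFAULT_ANCHOR
    min_span: int = detect.DEFAULT_MIN_SPAN
    theta_long_max: float = detect.DEFAULT_THETA_LONG_MAX
    theta_short_min: float = detect.DEFAULT_THETA_SHORT_MIN
    flank_len: int = classify.DEFAULT_FLANK
    kmer_k: int = 4
    alpha: float = 0.05
    n_perm: int = classify.DEFAULT_N_PERM
    write_vcf: bool = False
    sim: dict = field(default_factory=dict)  # overrides for SimulationConfig fields
    crispr_params: dict = field(default_factory=dict)  # overrides for ArrayParams fields

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ConfigurationError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)

    def validate(self) -> None:
        stages = [self.run_scan, self.run_detect, self.run_classify, self.run_correct,
                  self.run_crispr, self.run_intervals]
        if not any(stages):
            raise ConfigurationError("nothing to do: all stages toggled off")
        if self.run_detect and not self.run_scan:
            raise ConfigurationError("run_detect requires run_scan")
        if (self.run_classify or self.run_correct) and not self.run_detect:
            raise ConfigurationError("classify/correct require run_detect")
        if not self.simulate:
            for name in ("fasta",) + (("long_sam", "short_sam") if self.run_detect else ()):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise ConfigurationError(f"{name}: path missing or does not exist ({p})")
        if self.run_intervals and self.feature_table is not None:
            if not Path(self.feature_table).exists():
                raise ConfigurationError(f"feature_table does not exist: {self.feature_table}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages; returns the run summary (also written as JSON)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    summary: dict = {"parameters": {k: v for k, v in asdict(config).items()}, "stages": {}}
    try:
        logger.info("run starting with seed %d", config.seed)

        if config.simulate:
            sim_cfg = simulate.SimulationConfig(**{"seed": config.seed, **config.sim})
            bundle = simulate.simulate_bundle(sim_cfg)
            simulate.write_simulation(bundle, out / "simulation")
            genome = bundle.genome
            reads_long, reads_short = bundle.reads["long"], bundle.reads["short"]
            summary["stages"]["simulate"] = {
                "genome_length": len(genome),
                "seeded_tracks": len(bundle.truth),
                "truth_error_sites": sum(r.is_error_site for r in bundle.truth),
            }
        else:
            genome = read_fasta(config.fasta)
            reads_long = read_sam(config.long_sam) if config.run_detect else []
            reads_short = read_sam(config.short_sam) if config.run_detect else []

        calls = []
        census = None
        track_list = []
        if config.run_scan:
            track_list = tracks.scan_tracks(genome, config.min_len, frozenset(config.bases))
            census = tracks.track_census(track_list)
            tracks.write_tracks_bed(track_list, out / "tracks.bed")
            tracks.write_census_tsv(census, out / "census.tsv")
            summary["stages"]["scan"] = {"n_tracks": len(track_list)}
            logger.info("scan: %d tracks (min_len=%d bases=%s)", len(track_list),
                        config.min_len, config.bases)

        if config.run_detect:
            long_sup = detect.support_table(reads_long, track_list, "long",
                                            config.anchor, config.min_span)
            short_sup = detect.support_table(reads_short, track_list, "short",
                                             config.anchor, config.min_span)
            calls = detect.call_discrepancies(long_sup, short_sup, config.theta_long_max,
                                              config.theta_short_min, config.min_span)
            detect.write_calls_tsv(calls, out / "calls.tsv")
            by_status: dict[str, int] = {}
            for c in calls:
                by_status[c.status] = by_status.get(c.status, 0) + 1
            summary["stages"]["detect"] = {"calls_by_status": by_status}
            logger.info("detect: %s", by_status)

        if config.run_classify:
            rates = classify.stratify(calls, census)
            rates.table.to_csv(out / "stratified_rates.tsv", sep="\t", index=False)
            clf: dict = {"total_errors": rates.total_errors}
            called_tracks = [c.track for c in calls if c.status == detect.STATUS_CALLED]
            if called_tracks:
                controls = classify.match_controls(called_tracks, track_list, seed=config.seed)
                if controls:
                    gc_res = classify.flank_gc_test(
                        genome, called_tracks, controls, config.flank_len,
                        config.n_perm, config.seed,
                    )
                    err_fl = classify.extract_flanks(genome, called_tracks, config.flank_len, "error")
                    ctl_fl = classify.extract_flanks(genome, controls, config.flank_len, "control")
                    enr = classify.kmer_enrichment(err_fl, ctl_fl, config.kmer_k, config.alpha)
                    enr.to_csv(out / "kmer_enrichment.tsv", sep="\t", index=False)
                    clf["flank_gc_p"] = gc_res.p_value
                    clf["n_significant_kmers"] = int(enr.significant.sum()) if len(enr) else 0
            summary["stages"]["classify"] = clf

        if config.run_correct:
            called = [c for c in calls if c.status == detect.STATUS_CALLED]
            edits = correct.edits_from_calls(called)
            corrected = correct.apply_edits(genome, edits)
            correct.write_outputs(corrected, edits, out / "curated",
                                  original_genome=genome, vcf=config.write_vcf)
            side = [c for c in calls if c.status in
                    (detect.STATUS_LOW_COVERAGE, detect.STATUS_AMBIGUOUS)]
            detect.write_calls_tsv(side, out / "review_sites.tsv")
            summary["stages"]["correct"] = {
                "edits_applied": len(edits),
                "length_before": len(genome),
                "length_after": len(corrected),
            }
            logger.info("correct: %d edits, %d -> %d bp", len(edits), len(genome), len(corrected))

        if config.run_crispr:
            params = crispr.ArrayParams(**config.crispr_params)
            arrays = crispr.detect_arrays(genome, params)
            clusters = crispr.merge_interrupted(arrays, params)
            crispr.write_arrays_gff3(clusters, out / "crispr.gff3")
            crispr.write_arrays_tsv(clusters, out / "crispr.tsv")
            summary["stages"]["crispr"] = {
                "n_clusters": len(clusters),
                "repeats_per_cluster": [a.total_repeats for a in clusters],
            }

        if config.run_intervals and config.feature_table:
            table = intervals.parse_feature_table(config.feature_table)
            counts = []
            for spec in config.feature_intervals:
                iv = intervals.GenomicInterval(
                    spec.get("contig", ""), int(spec["start"]), int(spec["end"]),
                    spec.get("label", ""),
                )
                counts.append({
                    "family": spec["family"],
                    "interval": f"{iv.start}-{iv.end}",
                    "count": intervals.overlap_count(table, spec["family"], iv),
                })
            summary["stages"]["intervals"] = {"rows": len(table), "counts": counts}

        (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
        logger.info("run complete")
        return summary
    except AuditError:
        logger.exception("run aborted")
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
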