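"""Shared fixtures: small and full-scale simulated curation experiments.

Simulation is the only expensive setup, so the multi-seed small runs and the
single full-scale run are session-scoped and shared across test modules.
"""

from __future__ import annotations

from dataclasses import dataclass

import pytest

import homopolish_audit as ha
from homopolish_audit import detect


def small_config(seed: int, **overrides) -> ha.SimulationConfig:
    """Desk-scale study conditions: 30 seeded tracks, 20 error sites, 30x coverage."""
    base = dict(
        genome_length=80_000,
        seeded_tracks=(("G", 4, 8), ("C", 4, 8), ("G", 5, 7), ("C", 5, 7)),
        n_error_sites=20,
        coverage_long=30,
        coverage_short=30,
        read_length_long=300,
        read_length_short=150,  # the canonical short-read profile length
        seed=seed,
    )
    base.update(overrides)
    return ha.SimulationConfig(**base)


@dataclass
class DetectedRun:
    bundle: ha.SimulationBundle
    tracks: list
    long_support: list
    short_support: list
    calls: list

    @property
    def called(self):
        return [c for c in self.calls if c.status == detect.STATUS_CALLED]

    @property
    def truth_error_keys(self):
        return {t.track.key for t in self.bundle.truth if t.is_error_site}


def run_detection(config: ha.SimulationConfig) -> DetectedRun:
    bundle = ha.simulate_bundle(config)
    tracks = ha.scan_tracks(bundle.genome)
    ls = detect.support_table(bundle.reads["long"], tracks, "long")
    ss = detect.support_table(bundle.reads["short"], tracks, "short")
    calls = detect.call_discrepancies(ls, ss)
    return DetectedRun(bundle, tracks, ls, ss, calls)


@pytest.fixture(scope="session")
def small_run() -> DetectedRun:
    """One small simulated experiment with detection already run."""
    return run_detection(small_config(seed=11))


@pytest.fixture(scope="session")
def multi_seed_runs() -> list[DetectedRun]:
    """Ten independent small experiments (seeds 1..10) for property checks."""
    return [run_detection(small_config(seed=s)) for s in range(1, 11)]


@pytest.fixture(scope="session")
def full_scale_run() -> DetectedRun:
    """The reported study conditions: 200 error sites among >= 1000 G/C tracks,
    p_del_long=0.90, p_del_short=0.05, 50x coverage, seed 1."""
    return run_detection(ha.SimulationConfig(seed=1))
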