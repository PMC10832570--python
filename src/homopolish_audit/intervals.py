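"""Mobile-element tables and 1-based genomic interval arithmetic.

Insertion-sequence (IS) annotations in the source dialect come as one start
position per element copy (family -> list of chromosome starts) plus a
per-family completeness/size table.  This module parses those TSVs, counts
copies inside intervals (the "how many IS256 landed inside the CRISPR
cluster" style of question), computes genome-fraction footprints with union
semantics, and does the small coordinate arithmetic used for printed locus
claims (interval length, bp -> aa).

All user-facing coordinates are 1-based inclusive; conversion to 0-based
half-open happens only inside the computations.  ``bp_to_aa`` is the plain
``length / 3`` convention (no separate stop-codon subtraction), matching the
arithmetic used for the printed loci it is checked against.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .errors import ConfigurationError, InputDataError

COMPLETENESS = ("complete", "incomplete_Nt", "incomplete_Ct", "unknown")


@dataclass(frozen=True)
class GenomicInterval:
    """1-based inclusive interval with an optional label."""

    contig: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise InputDataError(
                f"interval {self.label or self.contig}: need 1 <= start <= end, "
                f"got {self.start}..{self.end}"
            )


def interval_length(interval: GenomicInterval) -> int:
    """Length in bp of a 1-based inclusive interval: end - start + 1."""
    return interval.end - interval.start + 1


def bp_to_aa(length_bp: int) -> int:
    """Amino-acid count as bp / 3; raises unless divisible by 3."""
    if length_bp % 3 != 0:
        raise InputDataError(f"length {length_bp} bp is not a multiple of 3")
    return length_bp // 3


def _parse_position(text: str) -> int:
    return int(text.replace(",", "").replace(" ", "").strip())


@dataclass
class FeatureTable:
    """Rows of (family, start, size, completeness), sorted within family by start."""

    frame: pd.DataFrame  # columns: family, start, size (nullable), completeness

    def families(self) -> list[str]:
        return sorted(self.frame.family.unique())

    def rows_for(self, family: str) -> pd.DataFrame:
        return self.frame[self.frame.family == family]

    def count(self, family: str) -> int:
        return int((self.frame.family == family).sum())

    def __len__(self) -> int:
        return len(self.frame)


def parse_feature_table(path: str | Path) -> FeatureTable:
    """Parse a family/start[/size/completeness] TSV.

    Position fields may contain thousands separators, which are stripped.
    Non-numeric positions and duplicate (family, start) pairs raise parse
    errors carrying the offending line number.
    """
    rows = []
    seen: set[tuple[str, int]] = set()
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or "family" not in header or "start" not in header:
            raise InputDataError(f"{path}: expected a header with 'family' and 'start' columns")
        idx = {name: i for i, name in enumerate(header)}
        for lineno, parts in enumerate(reader, start=2):
            if not parts or not "".join(parts).strip():
                continue
            family = parts[idx["family"]].strip()
            if not family:
                raise InputDataError(f"{path}:{lineno}: empty family")
            try:
                start = _parse_position(parts[idx["start"]])
            except ValueError:
                raise InputDataError(
                    f"{path}:{lineno}: non-numeric position {parts[idx['start']]!r}"
                ) from None
            if start <= 0:
                raise InputDataError(f"{path}:{lineno}: position must be positive")
            key = (family, start)
            if key in seen:
                raise InputDataError(f"{path}:{lineno}: duplicate (family, start) {key}")
            seen.add(key)
            size = None
            if "size" in idx and idx["size"] < len(parts):
                raw = parts[idx["size"]].strip()
                if raw and raw not in ("-", "NA", "?"):
                    size = _parse_position(raw)
            completeness = "unknown"
            if "completeness" in idx and idx["completeness"] < len(parts):
                raw = parts[idx["completeness"]].strip()
                if raw:
                    if raw not in COMPLETENESS:
                        raise InputDataError(f"{path}:{lineno}: bad completeness {raw!r}")
                    completeness = raw
            rows.append({"family": family, "start": start, "size": size, "completeness": completeness})
    frame = pd.DataFrame(rows, columns=["family", "start", "size", "completeness"])
    frame["size"] = frame["size"].astype("Int64")
    frame = frame.sort_values(["family", "start"], ignore_index=True)
    return FeatureTable(frame)


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Canonical serialisation; ``write(parse(t))`` is content-stable."""
    df = table.frame.copy()
    df["size"] = df["size"].map(lambda v: "" if pd.isna(v) else str(int(v)))
    df.to_csv(path, sep="\t", index=False)


def overlap_count(
    table: FeatureTable,
    family: str,
    interval: GenomicInterval,
    mode: str = "start_in",
) -> int:
    """Count of `family` rows overlapping `interval`.

    ``start_in`` (the default, and the right mode for start-only tables)
    counts rows whose start lies in [interval.start, interval.end];
    ``any_overlap`` counts footprint intersection and requires sizes.
    """
    rows = table.rows_for(family)
    if mode == "start_in":
        return int(((rows.start >= interval.start) & (rows.start <= interval.end)).sum())
    if mode == "any_overlap":
        missing = rows[rows["size"].isna()]
        if not missing.empty:
            raise InputDataError(
                f"any_overlap requires sizes; unknown for rows at starts "
                f"{missing.start.tolist()}"
            )
        ends = rows.start + rows["size"].astype(int) - 1
        return int(((rows.start <= interval.end) & (ends >= interval.start)).sum())
    raise ConfigurationError(f"unknown overlap mode {mode!r}")


def footprint_fraction(
    intervals: "list[GenomicInterval] | FeatureTable",
    genome_length: int,
    families: list[str] | None = None,
) -> float:
    """Percentage of the genome covered by the union of the given footprints.

    Accepts explicit intervals or a :class:`FeatureTable` (rows must then
    carry sizes; restrict with `families` to exclude rows whose size is a
    range or unknown).  Overlapping footprints count once.
    """
    if genome_length <= 0:
        raise ConfigurationError("genome_length must be positive")
    if isinstance(intervals, FeatureTable):
        rows = intervals.frame
        if families is not None:
            rows = rows[rows.family.isin(families)]
        missing = rows[rows["size"].isna()]
        if not missing.empty:
            raise InputDataError(
                "footprint_fraction requires sizes for every included row; unknown for "
                f"{missing.family.tolist()}"
            )
        spans = [(int(r.start), int(r.start) + int(r.size) - 1) for r in rows.itertuples()]
    else:
        spans = [(iv.start, iv.end) for iv in intervals]
    spans.sort()
    union = 0
    cur_s = cur_e = None
    for s, e in spans:
        if cur_e is None or s > cur_e + 1:
            if cur_e is not None:
                union += cur_e - cur_s + 1
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        union += cur_e - cur_s + 1
    union = min(union, genome_length)
    return 100.0 * union / genome_length


# ---------------------------------------------------------------------------
# Packaged fixtures transcribing the source annotation tables.

def _data_path(name: str) -> Path:
    return Path(str(resources.files("homopolish_audit").joinpath("data", name)))


def load_is_positions() -> FeatureTable:
    """Per-copy IS start positions on the curated chromosome (family -> starts)."""
    return parse_feature_table(_data_path("mhassiacum_is_positions.tsv"))


def load_is_families() -> pd.DataFrame:
    """Per-family completeness counts and element sizes (bp); size ranges kept as text."""
    return pd.read_csv(_data_path("mhassiacum_is_families.tsv"), sep="\t")


def load_steroid_genes() -> pd.DataFrame:
    """Candidate steroid-degradation genes with printed loci (conflicts preserved, noted)."""
    return pd.read_csv(_data_path("mhassiacum_steroid_genes.tsv"), sep="\t")
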