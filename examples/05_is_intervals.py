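"""Interval bookkeeping on the packaged mobile-element tables.

Loads the transcribed IS position table of the curated chromosome and
reproduces the printed locus arithmetic: IS copies inside the first CRISPR
cluster, per-family copy counts, the complete-element footprint bound, and
the kstD4 locus length.
"""

from homopolish_audit.intervals import (
    GenomicInterval,
    bp_to_aa,
    footprint_fraction,
    interval_length,
    load_is_families,
    load_is_positions,
    overlap_count,
)

table = load_is_positions()
cluster1 = GenomicInterval("chr", 396_249, 409_964, "CRISPR cluster 1")

print(f"IS rows in table:            {len(table)}")
print(f"IS256 inside CRISPR1:        {overlap_count(table, 'IS256', cluster1)}")
print(f"IS21  inside CRISPR1:        {overlap_count(table, 'IS21', cluster1)}")
print(f"ISL3 copies genome-wide:     {table.count('ISL3')}")

fam = load_is_families()
total = int((fam.n_complete * fam.complete_size_bp.fillna(0)).sum())
ivs, pos = [], 1
for _, r in fam.iterrows():
    for _ in range(int(r.n_complete)):
        ivs.append(GenomicInterval("chr", pos, pos + int(r.complete_size_bp) - 1))
        pos += int(r.complete_size_bp) + 10
frac = footprint_fraction(ivs, 5_269_097)
print(f"complete-IS footprint:       {frac:.2f}% of 5,269,097 bp "
      f"(lower bound; partial copies have range sizes)")

kstd4 = GenomicInterval("chr", 3_985_552, 3_987_303, "kstD4")
print(f"kstD4 locus:                 {interval_length(kstd4)} bp = "
      f"{bp_to_aa(interval_length(kstd4))} aa")
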