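"""Detect an IS-interrupted CRISPR array and merge its segments.

Plants a 36-bp direct repeat (the repeat unit of the curated chromosome's
first CRISPR locus) in groups of 20/15/5/4/3 repeats separated by IS-sized
inserts, then detects and merges.
"""

import numpy as np

import homopolish_audit as ha
from homopolish_audit import crispr

REPEAT = "GGTGCGGTTCCTTCGGGAGCCGCTCTTCATTGAGGC"
rng = np.random.default_rng(1)


def rand(n):
    return "".join(rng.choice(list("ACGT"), size=n))


def array(n):
    # unique spacer after every repeat but the last, as in a real array
    return "".join(REPEAT + (rand(30) if i < n - 1 else "") for i in range(n))


parts, groups, gaps = [rand(2000)], (20, 15, 5, 4, 3), (1320, 1320, 2900, 1600)
for i, n in enumerate(groups):
    parts.append(array(n))
    if i < len(gaps):
        parts.append(rand(gaps[i]))  # an IS-sized interruption
parts.append(rand(2000))
genome = ha.Genome({"chr": "".join(parts)})

segments = crispr.detect_arrays(genome)
clusters = crispr.merge_interrupted(segments)

print(f"uninterrupted segments found: {[a.total_repeats for a in segments]}")
print(f"clusters after merging:       {len(clusters)}")
c = clusters[0]
print(f"total repeats:                {c.total_repeats} (planted {sum(groups)})")
print(f"consensus == planted repeat:  {c.consensus == REPEAT}")
print(f"cluster span:                 {c.start + 1}-{c.end} ({len(c.segments)} segments)")
# The five segments merge into a single cluster spanning the IS inserts, with
# the exact planted repeat count and consensus.
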