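"""Permutation enrichment of recurrent copy-number events.

Fifty samples carry uniform background gains plus one shared arm-scale
gain on chromosome 2; repositioning each event uniformly on its own
chromosome builds the null, and BH-adjusted empirical p-values flag the
shared region as enriched.
"""

import numpy as np

from tgctevo.events import EventRecord, merge_significant_bins, permutation_enrichment
from tgctevo.genome import GRCH38_LENGTHS

rng = np.random.default_rng(606)
chroms = ("1", "2", "3", "4")
events = []
for s in range(50):
    for chrom in chroms:
        clen = GRCH38_LENGTHS[chrom]
        for _ in range(rng.poisson(1)):
            length = int(rng.uniform(3e6, 8e6))
            start = int(rng.integers(1, clen - length + 2))
            events.append(EventRecord(f"S{s}", "gain", chrom, start, start + length - 1))
for s in range(40):  # the recurrent event: 80% of samples
    events.append(EventRecord(f"S{s}", "gain", "2", 50_000_001, 80_000_000))

results = permutation_enrichment(events, n_perm=1000, seed=8, chromosomes=chroms)
regions = merge_significant_bins(results)
print(f"bins tested            : {len(results)}")
print(f"significant regions    : {len(regions)}")
for chrom, start, end, kind, direction in regions:
    print(f"  {kind} {chrom}:{start}-{end} {direction}")
print("\nThe merged region recovers the spiked 30 Mb gain; background bins")
print("stay at their null recurrence.")
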