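"""Simulate a biparental cross and inspect its genetic structure.

Builds a 5-chromosome genome map, generates 500 haploid segregants with
Haldane crossovers, and prints the per-marker allele balance and the decay
of marker agreement with genetic distance — the two signatures of meiosis
that every downstream predictor exploits.
"""

import numpy as np

from phenobench import simdata

gmap = simdata.GenomeMap.regular(n_chromosomes=5, length=1.0, markers_per_chromosome=40)
G = simdata.simulate_cross(gmap, n_segregants=500, seed=7)

freq = G.values.mean(axis=0)
print(f"{G.n_samples} segregants × {G.n_markers} markers")
print(f"allele-1 proportion: mean {freq.mean():.3f}, range [{freq.min():.2f}, {freq.max():.2f}]")
# each marker segregates ~1:1 because every chromosome starts from either
# parent with probability 1/2

first = G.values[:, 0]
for j, d in [(1, 0.026), (10, 0.26), (39, 1.0)]:
    agree = (first == G.values[:, j]).mean()
    print(f"agreement with marker {d:.2f} Morgans away: {agree:.3f}")
# agreement decays from ~1 toward 0.5 with genetic distance (linkage)
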