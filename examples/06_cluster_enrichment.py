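"""Cluster regions by z-signature and test set-level enrichment.

Regions with an extreme signature (|z| >= 1.5 on some measure) are
hierarchically clustered on their z-vectors (Euclidean distance, complete
linkage, cut height 7). Set-level enrichment counts trait regions in the
top 5% of a genome-wide random-region distribution and compares the count
to a Binomial(n, 0.05) expectation.
"""

import numpy as np

from evosig.cluster import (binomial_expected_count, build_z_matrix,
                            cluster_regions, extreme_regions,
                            genomewide_enrichment)
from evosig.core import RegionMeasureResult

rng = np.random.default_rng(3)
results = []
for i in range(40):
    base = {"fst": rng.normal(), "phastcons": rng.normal()}
    if i < 6:
        base["fst"] += 3.0        # differentiation-like signature
    elif i < 12:
        base["phastcons"] += 3.0  # conservation-like signature
    for m, z in base.items():
        results.append(RegionMeasureResult(f"r{i:02d}", m, 0.0, 300, 0,
                                           0.5, z, removed=False))

zm = build_z_matrix(results)
extreme = extreme_regions(zm, threshold=1.5)
labels = cluster_regions(zm, cut_height=3.0)
n_clusters = len(set(labels.values()))
print(f"{len(extreme)} of 40 regions carry an extreme signature (|z| >= 1.5)")
print(f"hierarchical clustering yields {n_clusters} clusters")

trait = {f"r{i}": (3.0 if i < 8 else float(rng.normal())) for i in range(40)}
pool = rng.normal(size=8000)
rep = genomewide_enrichment(trait, pool, n_random=5000, n_iter=200, seed=4)
print(f"\nregions in the genome-wide top 5%: {rep.observed_count:.1f} on average")
print(f"expected by chance: {rep.binomial_expected:.1f} "
      f"(binomial p = {rep.binomial_p:.2g})")
print(f"for a 215-region set the chance expectation would be "
      f"{binomial_expected_count(215):.2f}")
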