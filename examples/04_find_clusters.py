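"""Detect clusters of DNMs lying within 20 kb of each other.

Single-linkage chaining per child and chromosome: consecutive DNMs at most
20 kb apart join one cluster, so a chain's span can exceed 20 kb.
"""

import pandas as pd

from dnmsuite import cluster_finder

calls = pd.DataFrame({
    "trio": "T001", "chrom": "chr1",
    "pos": [100_000, 115_000, 140_000, 500_000, 510_000, 525_000],
})
clusters = cluster_finder.detect_clusters(calls, max_gap=20_000)
for c in clusters:
    print(f"cluster {c.cluster_id}: {c.size} DNMs at {c.positions}, "
          f"span {c.span} bp")
summary = cluster_finder.cluster_summary(clusters, n_total_dnms=len(calls))
print(f"{summary['n_clusters']} clusters; mean size "
      f"{summary['mean_cluster_size']:.2f}; "
      f"{summary['fraction_dnms_clustered']:.2f} of DNMs clustered")
# 100k/115k chain (gap 15 kb; the 25-kb gap to 140k breaks the chain) and
# 500k/510k/525k chain into a 25-kb-span cluster of three
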