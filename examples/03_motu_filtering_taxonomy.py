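"""MOTU-table quality filtering and similarity-threshold taxonomy.

Filters: per-sample entries under 0.1% of the sample's reads are zeroed
(index-hopping artefacts), MOTUs with fewer than 3 reads in total or seen in
a single sample are dropped. Taxonomy: best-hit identity >= 98% resolves a
species, > 96.5% a family, > 95% an order; tied best hits are downgraded to
their deepest shared rank.
"""

import pandas as pd

from nicheoverlap import MotuTable, assign_taxonomy, filter_counts

counts = pd.DataFrame(
    {
        "tiny":      [9, 50, 60],     # 9 reads < 0.1% of s0's 10,000 -> zeroed
        "low_total": [0, 2, 0],       # 2 reads in total -> dropped
        "single":    [0, 0, 400],     # detected in one sample -> dropped
        "keep":      [9991, 948, 540],
    },
    index=["s0", "s1", "s2"],
)
table = MotuTable(counts=counts,
                  species_of_sample=pd.Series(["A", "A", "B"], index=counts.index))
filtered, report = filter_counts(table)
print("retained MOTUs:", list(filtered.counts.columns))
print("entries zeroed:", report.entries_zeroed,
      "| dropped (total<3):", report.motus_dropped_low_total,
      "| dropped (1 sample):", report.motus_dropped_low_prevalence)

hit = lambda sp, sim: {"order": "Lepidoptera", "family": "Noctuidae",
                       "species": sp, "similarity": sim}
print(assign_taxonomy("m1", [hit("Agrotis ipsilon", 99.1)]).assigned_name,
      "<- single 99.1% hit (species level)")
rec = assign_taxonomy("m2", [hit("Agrotis ipsilon", 98.6), hit("Xestia c-nigrum", 98.6)])
print(rec.assigned_name, "<- two species tied at 98.6% (downgraded to family)")
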