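"""Per-variable niche overlap with permutation null models, composites.

For each axis the overlap NO = 1 - 0.5 ∫|f_A - f_B| (kernel densities, or
category proportions for categorical axes) is compared against a null built
by re-assigning species labels at random: a significantly smaller-than-null
overlap means the species partition that axis. Variables average into
per-dimension composites and one overall overlap; p-values are Holm-adjusted.
"""

from nicheoverlap import (
    analyze,
    breeding_variables,
    default_config,
    diet_variables,
    filter_counts,
    generate,
    nestsite_variables,
    taxonomy_map,
)
from nicheoverlap.report import format_mean_sd

ds = generate(default_config(seed=1))
table, _ = filter_counts(ds.motu_table)
variables = (
    breeding_variables(ds.breeding_records)
    + nestsite_variables(ds.nest_sites, ds.nestsite_kinds)
    + diet_variables(table, taxonomy_map(ds.taxonomy, "order"))
)
result = analyze(variables, n_perm=300, seed=1)

print("variable overlaps (first 6):")
print(result.to_dataframe().head(6).round(3).to_string(index=False))

print("\ncomposites:")
for name, c in {**result.composites, "overall": result.overall}.items():
    star = "*" if c.p_adjusted < 0.05 else ""
    print(f"  {name:14s} {format_mean_sd(c.mean, c.sd)}{star}")
# An asterisk marks a dimension whose observed overlap is significantly
# smaller than the label-permutation null (Holm-adjusted): niche
# differentiation. The generated species differ in breeding time and diet
# but share nest sites, and the analysis recovers exactly that.
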