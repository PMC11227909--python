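# nicheoverlap

Quantifying how two sympatric species partition their ecological niche —
breeding time, nest sites, and diet — from field phenology records, nest-site
measurements, and DNA-metabarcoding diet tables.

The motivating system is a pair of secondary cavity-nesting birds breeding in
the same nest-box population: a resident tit (*Parus minor*) and a migrant
flycatcher (*Ficedula zanthopygia*). Niche theory predicts such ecologically
similar neighbours coexist by differentiating on at least one niche
dimension; this package provides the statistical machinery to test that
prediction on any two-species dataset of the same shape, plus a synthetic
generator with analytically known ground truth so the whole pipeline can be
validated end to end.

## The statistics at the core

**Niche overlap index.** For each niche axis the overlap between species A
and B is

```
NO = 1 − ½ ∫ |f̂_A(x) − f̂_B(x)| dx      (continuous; Gaussian KDE per group)
NO = 1 − ½ Σ_j |p_Aj − p_Bj|            (categorical; proportions over categories)
```

NO = 1 means the species use the axis identically, NO = 0 means complete
partitioning. Variables average into per-dimension composites (mean ± SD) and
one overall overlap.

**Null model.** Species labels are randomly re-assigned (group sizes
preserved), the overlap recomputed per relabelling, and the observed overlap
referred to that null distribution via a one-sided Student-t tail probability
of `(NO_obs − mean_null)/sd_null` (an empirical permutation p is reported as
a diagnostic). Smaller-than-null overlap ⇒ niche differentiation. Families of
tests are adjusted by sequential Bonferroni (Holm).

**Supporting metrics.** Season-day breeding arithmetic (1 April = 1, periods
inclusive of endpoints), MOTU-table quality filters (per-sample 0.1% floor,
total reads < 3, single-sample MOTUs) and similarity-threshold taxonomy
(species ≥ 98%, family > 96.5%, order > 95%, tie → deepest shared rank),
relative read abundance and percent frequency of occurrence, standardized
Levins niche breadth `B_A = (1/Σp² − 1)/(n − 1)`, incidence-based
rarefaction/extrapolation (Hill q = 0) with bootstrap CIs, and Bray–Curtis +
ANOSIM community comparison with an exact-enumeration mode for small inputs.

## Worked example

```python
from nicheoverlap import (analyze, breeding_variables, default_config,
                          diet_variables, filter_counts, generate,
                          nestsite_variables, taxonomy_map)

ds = generate(default_config(seed=1))          # 178 nests, 73 fecal samples
table, _ = filter_counts(ds.motu_table)        # MOTU quality filters
variables = (breeding_variables(ds.breeding_records)
             + nestsite_variables(ds.nest_sites, ds.nestsite_kinds)
             + diet_variables(table, taxonomy_map(ds.taxonomy, "order")))
result = analyze(variables, n_perm=300, seed=1)
print(result.composite_dataframe().round(3).to_string(index=False))
```

which prints:

```
    dimension  mean    sd  n_members  p_raw  p_adjusted
breeding_time 0.158 0.058          3    0.0         0.0
         diet 0.616 0.160         11    0.0         0.0
    nest_site 0.799 0.080         13    0.0         0.0
      overall 0.653 0.229         27    0.0         0.0
```

The generated species breed ~30 days apart (breeding-time overlap 0.16,
strongly differentiated), eat overlapping but distinct prey (0.62), and share
nest sites most of all (0.80). Each number is the mean ± SD of the member
variables' overlap indices; `result.to_dataframe()` holds the per-variable
detail (observed overlap, null mean ± SD, raw and Holm-adjusted p).

The `examples/` directory walks through each capability one script at a
time (simulation, phenology, filtering/taxonomy, diet metrics, overlap +
null models, community similarity); a thin CLI mirrors the same steps
(`nicheoverlap simulate | phenology | filter | diet | overlap | community`).

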