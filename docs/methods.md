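# Methods

This note documents the models and numerical choices behind `nicheoverlap`:
what each statistic assumes, which tunable parameters matter, what the
synthetic generator does and does not emulate, and the known limitations.

## Breeding-time arithmetic

Dates are indexed as season days with 1 April = 1, valid through 31 July;
the window covers the full breeding season of the motivating system and
avoids leap-year ambiguity because no February is involved. A species'
breeding period spans the earliest first-egg date to the latest hatching
date and is **inclusive of both endpoints** (8 April–1 July = 85 days) —
this convention is forced by the co-breeding arithmetic: a 13 May–30 June
period shared in full is 49 days and 49/85 = 57.647% of the longer period.
Years are pooled by default (per-year periods are available by filtering
records). Computational functions return full precision; `report.truncate`
reproduces the truncation used in published tables (57.64%, SD 0.010).
Hatching rate is brood size / clutch size per nest. Mixed-model comparisons
of dates between species are standard GLMM territory and are deliberately
left to general statistics packages; this module only prepares their inputs.

## MOTU filtering and taxonomy

Filters are applied in the order: (1) zero per-sample entries below 0.1% of
the sample's total reads (tag-jumping artefacts; expressed on per-sample
proportions, which is equivalent to filtering totals normalised per sample);
(2) drop MOTUs with fewer than 3 reads overall ("frequency < 3" is read as
the MOTU's total read count, the common metabarcoding interpretation);
(3) drop MOTUs detected in fewer than 2 samples. Because dropping MOTUs
shrinks sample totals, the three steps are **iterated to a fixed point**
(usually 1–2 passes; guaranteed to terminate since counts are non-increasing
integers). This makes filtering idempotent, which a single pass is not in
edge cases. Samples emptied by filtering are flagged, never silently
dropped. All three thresholds are parameters.

Taxonomy: the best-hit percent identity caps the assignable rank —
species at ≥ 98, family on (96.5, 98), order on (95, 96.5], otherwise
unidentified. Boundary semantics follow the conventional wording ("at 98%",
"> 96.5%", "> 95%"). When several candidates tie at the best identity the
rank is further downgraded to the deepest rank at which all tied candidates
agree. Database searching itself is upstream; this module consumes
similarity scores.

## Diet metrics

RRA is the mean over a species' samples of within-sample read proportions
(×100): each individual weighs equally, making the statistic robust to
uneven sequencing depth; a depth-weighted pooled variant sits behind
`pooled=True`. %FOO is the percentage of samples containing a taxon.
Levins breadth `B = 1/Σp²` is standardized as `B_A = (B − 1)/(n − 1)`; the
denominator `n` defaults to the number of categories in the supplied
proportion vector (the categories detected in the combined two-species diet
at the chosen level, when built from an RRA table) — the literature rarely
states this denominator, so it is an explicit parameter.

Rarefaction/extrapolation is sample-based (incidence, Hill q = 0):
interpolation uses the exact hypergeometric estimator
`S(t) = Σ_i [1 − C(T−Y_i, t)/C(T, t)]`; extrapolation uses the Chao2-based
asymptotic form with the bias-corrected Chao2 when no doubletons exist.
Confidence bands are percentile bootstrap over samples (default 1000
replicates, seeded). This simple resampling slightly underestimates
uncertainty in the extrapolated range relative to estimators that model
undetected species, but is transparent and adequate for coverage checks.

## Niche overlap

Continuous overlap uses per-group Gaussian KDEs evaluated on one shared
512-point grid spanning the pooled range padded by three bandwidths;
`NO = 1 − ½·trapz|f̂_A − f̂_B|`, clamped to [0, 1]. Bandwidths follow
Silverman's rule `0.9·min(sd, IQR/1.34)·n^(−1/5)` by default (Scott's rule
or a fixed float are accepted); rule-of-thumb bandwidths oversmooth slightly,
biasing overlap upward by ~0.01–0.02 at n ≈ 2000 for well-separated normals
— well inside the statistic's sampling noise at field sample sizes.
Variables with compact support (diet proportions in [0, 1], percentages in
[0, 100]) are boundary-corrected by reflecting the sample at the bounds,
which removes the mass-leak edge bias. A continuous group with zero spread
degrades to the categorical overlap of its value labels with a warning.
Compass orientation is treated as categorical (8 sectors of 45°) and
entrance inclination as continuous by default; both encodings are
switchable since raw field tables support either.

The null model pools observations and re-assigns species labels uniformly
at random, preserving group sizes (default 1000 relabellings, seeded).
The one-sided p (differentiation = smaller than null) is the Student-t tail
probability of `(NO_obs − mean_null)/sd_null` with `n_perm − 1` degrees of
freedom. Standardizing by the null SD (rather than the SE of the null mean)
is what makes the test calibrated: under exchangeability the observed
overlap is itself one draw from the null, so the statistic is approximately
standard normal and rejection at α = 0.05 occurs at close to the nominal
rate (verified by simulation in the acceptance suite). The distribution-free
empirical tail proportion `(1 + #{null ≤ obs})/(n_perm + 1)` is reported
alongside; with a degenerate null only the empirical p is returned. The
parametric p assumes an approximately normal null, which holds for the
overlap statistic away from the boundaries; near NO ≈ 1 the null is
left-skewed and the empirical diagnostic should be preferred.

Composites are the arithmetic mean ± sample SD (ddof = 1, 0 for a single
member) of member overlaps; the overall overlap averages all variables.
Composite significance reuses the per-variable permutations: replicate i of
the composite null is the mean of the member variables' i-th null overlaps
(independent relabellings per variable), and the same t-tail applies. Holm
step-down (via statsmodels) is applied within each dimension's variable
family and separately to the three composites + overall — the multiplicity
family is a genuine modelling choice and is documented rather than implied.

## Community comparison

Bray–Curtis distances come from scipy; an all-zero pair of composition
vectors has no defined distance and is reported as NaN with a warning.
ANOSIM rank-transforms the condensed distances once with mid-ranks
(tie-handling matters at small n), computes
`R = (mean between-rank − mean within-rank)/(n(n−1)/4)`, and permutes
labels for significance with the `(1 + exceedances)/(n_perm + 1)` convention
so p is never zero. When the number of distinct relabellings is ≤ 10,000
(or on request) every assignment is enumerated and p is exact — this mode
doubles as the oracle for validating the sampler. The statistic matches
scikit-bio's implementation to machine precision. NMDS ordination is
plotting plumbing and is not re-implemented.

## Synthetic generator

The generator emulates the study conditions of a two-season, two-species
nest-box campaign: 152 vs 26 breeding records, 49 vs 24 fecal samples, a
~30-day offset between phenology peaks (first egg ≈ day 25 ± 12 vs day
55 ± 7), 13 nest-site variables (11 continuous truncated normals, nest-tree
species and entrance orientation categorical), and a Dirichlet-multinomial
diet over 11 arthropod orders with Lepidoptera-dominant means (~0.35 vs
~0.55) and total concentration 30 per species — enough between-individual
variation to be realistic without making rare-order marginals degenerate.
Reads per sample are Poisson around 10,000 (post-filter scale, far below
raw sequencing depth but irrelevant to proportion-based metrics), split
multinomially over orders and then over 4 MOTUs per order with fixed
within-order weights. Continuous bounds are enforced by resampling, not
clipping, so densities stay smooth. Dates are generated as season days and
exported as calendar dates.

Ground truth per axis is the analytic overlap of the generating
distributions, computed exactly from CDFs by splitting the support at
density crossings (`1 − TV`): normals (with convolved variance for the
derived incubation/hatching dates, treating day-rounding as negligible
against 7–12-day SDs), truncated normals, categorical probability vectors,
and the Beta marginals `Beta(α_i, α_0 − α_i)` of the Dirichlet diet. This
handles integrable singularities (Beta shapes < 1) that defeat naive
quadrature.

What passing recovery tests show — and what they do not: estimates at
n = 500/group recover truth within 0.05 for continuous axes, categorical
axes, and diet orders whose Beta marginals are bounded at zero (both
concentrations ≥ 1). Rare orders with α ≪ 1 concentrate unbounded density
at 0; no fixed-bandwidth KDE tracks that spike, and their overlap estimates
carry a systematic error of up to ~0.1 — a property of the estimator, not
of the generator, and one that equally affects real zero-inflated diet
data. The plug-in categorical overlap likewise carries an O(n^(−1/2))
downward bias for near-identical multi-category distributions, so recovery
is assessed on the estimator's mean over replicate datasets. Real data
features deliberately not emulated: within-season renesting (second
broods), spatial autocorrelation among nest boxes, chimeric or contaminant
MOTUs, and taxonomic mis-assignment.

## Problem sizes and defaults

Null-model tests default to 1000 relabellings (p resolution ~0.001 before
adjustment); the calibration suite uses 100 null datasets of n = 50/group
and 40 strongly separated datasets, and parameter recovery averages 5
replicate datasets at n = 500/group — sizes chosen to estimate rejection
rates and estimator bias to within a few percent. Rarefaction bootstrap
defaults to 1000 replicates. The KDE grid is 512 points (doubling it
changes overlaps by < 1e-3 in typical use).
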