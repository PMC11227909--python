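"""End-to-end niche-overlap analysis across breeding time, nest site, diet.

Builds the per-variable :class:`~nicheoverlap.overlap.NicheVariable` list from
the three input tables, runs the per-variable overlap and null-model tests,
averages variables into per-dimension composites and an overall overlap, and
applies the sequential Bonferroni (Holm) adjustment — within each dimension's
variable family, and separately to the composite + overall family.

Composite significance uses the same permutation machinery: because each
variable's null replicate i is an independent relabelling, the mean across
member variables of the i-th null overlaps is a valid null replicate of the
composite mean, and the composite p is the Student-t tail probability of the
observed mean against that composite null.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diet import rra_sample_proportions
from .motus import MotuTable, TaxonomyRecord, taxonomy_map
from .overlap import (
    CompositeResult,
    NicheVariable,
    OverlapResult,
    null_model_test,
    sequential_bonferroni,
)
from .phenology import BreedingRecord, to_julian

__all__ = [
    "breeding_variables",
    "nestsite_variables",
    "diet_variables",
    "PipelineResult",
    "analyze",
]


def breeding_variables(records: Sequence[BreedingRecord]) -> list[NicheVariable]:
    """Three breeding-time variables (season days): first egg, incubation, hatching."""
    species = sorted({r.species for r in records})
    if len(species) != 2:
        raise ValueError(f"expected exactly 2 species, got {species}")
    a, b = species
    out = []
    for name, attr in (
        ("first_egg", "first_egg"),
        ("incubation_start", "incubation_start"),
        ("hatching", "hatching"),
    ):
        va = [to_julian(getattr(r, attr)) for r in records if r.species == a]
        vb = [to_julian(getattr(r, attr)) for r in records if r.species == b]
        out.append(
            NicheVariable(
                name=name, dimension="breeding_time", kind="continuous",
                values_A=va, values_B=vb,
            )
        )
    return out


def nestsite_variables(
    nest_sites: pd.DataFrame,
    kinds: Mapping[str, str] | None = None,
    species_col: str = "species",
) -> list[NicheVariable]:
    """Nest-site variables from a table with a species column.

    ``kinds`` maps column -> "continuous"/"categorical"; columns not listed
    are inferred from dtype (non-numeric -> categorical). Percentage-valued
    columns (name ending in ``_pct``) get [0, 100] bounds for
    boundary-corrected KDE.
    """
    species = sorted(nest_sites[species_col].unique())
    if len(species) != 2:
        raise ValueError(f"expected exactly 2 species, got {species}")
    a, b = species
    sub_a = nest_sites[nest_sites[species_col] == a]
    sub_b = nest_sites[nest_sites[species_col] == b]
    out = []
    for col in nest_sites.columns:
        if col == species_col:
            continue
        if kinds is not None and col in kinds:
            kind = kinds[col]
        else:
            kind = (
                "continuous"
                if pd.api.types.is_numeric_dtype(nest_sites[col])
                else "categorical"
            )
        bounds = (0.0, 100.0) if (kind == "continuous" and col.endswith("_pct")) else None
        out.append(
            NicheVariable(
                name=col, dimension="nest_site", kind=kind,
                values_A=list(sub_a[col]), values_B=list(sub_b[col]),
                bounds=bounds,
            )
        )
    return out


def diet_variables(
    table: MotuTable,
    taxonomy: Sequence[TaxonomyRecord] | Mapping[str, str],
    level: str = "order",
) -> list[NicheVariable]:
    """One continuous variable per diet taxon: per-sample read proportions.

    Each taxon at the chosen level contributes one axis whose observations
    are the within-sample read proportions of that taxon, bounded in [0, 1]
    (reflected-kernel densities). Taxa never detected in one species still
    enter as all-zero vectors (handled by the zero-spread fallback).
    """
    tmap = taxonomy if isinstance(taxonomy, Mapping) else taxonomy_map(taxonomy, level)
    props = rra_sample_proportions(table, tmap)
    labels = table.species_of_sample.reindex(props.index)
    species = sorted(labels.unique())
    if len(species) != 2:
        raise ValueError(f"expected exactly 2 species, got {species}")
    a, b = species
    out = []
    for taxon in props.columns:
        out.append(
            NicheVariable(
                name=f"diet:{taxon}", dimension="diet", kind="continuous",
                values_A=props.loc[labels == a, taxon].to_numpy(),
                values_B=props.loc[labels == b, taxon].to_numpy(),
                bounds=(0.0, 1.0),
            )
        )
    return out


@dataclass
class PipelineResult:
    """Per-variable, per-dimension and overall overlap with adjusted p-values."""

    per_variable: list[OverlapResult]
    composites: dict[str, CompositeResult]
    overall: CompositeResult

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "variable": r.variable,
                "dimension": r.dimension,
                "observed": r.observed,
                "null_mean": r.null_mean,
                "null_sd": r.null_sd,
                "p_raw": r.p_raw,
                "p_adjusted": r.p_adjusted,
                "significant": r.significant,
            }
            for r in self.per_variable
        ]
        return pd.DataFrame(rows)

    def composite_dataframe(self) -> pd.DataFrame:
        rows = []
        for name, c in {**self.composites, "overall": self.overall}.items():
            rows.append(
                {
                    "dimension": name,
                    "mean": c.mean,
                    "sd": c.sd,
                    "n_members": c.n_members,
                    "p_raw": c.p_raw,
                    "p_adjusted": c.p_adjusted,
                }
            )
        return pd.DataFrame(rows)


def _composite_with_p(
    members: Sequence[OverlapResult], dimension: str
) -> CompositeResult:
    vals = np.array([m.observed for m in members])
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    comp = CompositeResult(
        dimension=dimension, mean=float(vals.mean()), sd=sd, n_members=vals.size
    )
    nulls = [m.null for m in members if m.null is not None]
    if len(nulls) == len(members) and len({n.size for n in nulls}) == 1:
        comp_null = np.mean(np.vstack(nulls), axis=0)
        nsd = comp_null.std(ddof=1)
        if nsd > 0:
            t = (comp.mean - comp_null.mean()) / nsd
            comp.p_raw = float(stats.t.cdf(t, df=comp_null.size - 1))
        else:
            comp.p_raw = float(
                (1 + np.sum(comp_null <= comp.mean)) / (comp_null.size + 1)
            )
    return comp


def analyze(
    variables: Sequence[NicheVariable],
    n_perm: int = 1000,
    seed: int | None = None,
    bandwidth="silverman",
    grid_size: int = 512,
) -> PipelineResult:
    """Run per-variable null-model tests and assemble composites.

    Holm adjustment is applied within each dimension's variable family; the
    three composites and the overall overlap form their own family.
    """
    rng = np.random.default_rng(seed)
    results = [
        null_model_test(
            v, n_perm=n_perm, rng=rng, bandwidth=bandwidth, grid_size=grid_size
        )
        for v in variables
    ]
    for dim in sorted({r.dimension for r in results}):
        members = [r for r in results if r.dimension == dim]
        adj = sequential_bonferroni([m.p_raw for m in members])
        for m, p in zip(members, adj):
            m.p_adjusted = float(p)

    composites = {}
    for dim in sorted({r.dimension for r in results}):
        members = [r for r in results if r.dimension == dim]
        composites[dim] = _composite_with_p(members, dim)
    overall = _composite_with_p(results, "overall")
    family = list(composites.values()) + [overall]
    adj = sequential_bonferroni([c.p_raw for c in family])
    for c, p in zip(family, adj):
        c.p_adjusted = float(p)
    return PipelineResult(per_variable=results, composites=composites, overall=overall)
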