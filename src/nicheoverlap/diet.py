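"""Diet composition and diversity statistics from filtered MOTU tables.

Two complementary composition summaries are provided. Relative read abundance
(RRA) is the mean across a species' samples of the within-sample read
proportion of a taxon, expressed as a percentage — it weights each individual
equally and is robust to uneven sequencing depth. Percent frequency of
occurrence (%FOO) is the percentage of a species' samples in which a taxon is
detected at all. Diversity summaries are per-individual MOTU richness, the
standardized Levins niche breadth

    B = 1 / sum_i p_i**2,     B_A = (B - 1) / (n - 1)  in [0, 1],

and sample-based (incidence) rarefaction/extrapolation of prey richness
(Hill number of order q = 0) with percentile bootstrap confidence bands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .motus import MotuTable

__all__ = [
    "aggregate_counts",
    "rra",
    "foo",
    "individual_richness",
    "NicheBreadthResult",
    "levins_ba",
    "rarefaction_extrapolation",
]


def aggregate_counts(table: MotuTable, taxonomy: Mapping[str, str]) -> pd.DataFrame:
    """Sum MOTU read counts to taxa (sample x taxon matrix).

    ``taxonomy`` maps MOTU id -> taxon name at the desired level; MOTUs
    missing from the mapping are pooled under ``"unidentified"``.
    """
    taxa = pd.Series(
        {m: taxonomy.get(m, "unidentified") for m in table.counts.columns}
    )
    return table.counts.T.groupby(taxa).sum().T


def _per_sample_proportions(agg: pd.DataFrame) -> pd.DataFrame:
    totals = agg.sum(axis=1)
    empty = totals == 0
    if empty.any():
        warnings.warn(
            f"excluding {int(empty.sum())} sample(s) with zero reads at this level"
        )
    agg = agg.loc[~empty]
    return agg.div(agg.sum(axis=1), axis=0)


def rra(
    table: MotuTable,
    taxonomy: Mapping[str, str],
    pooled: bool = False,
) -> pd.DataFrame:
    """Relative read abundance (%) per taxon and species.

    Default form: within each sample compute read proportions per taxon, then
    average those proportions over the species' samples and scale to percent
    (each individual weighted equally). ``pooled=True`` instead pools all of
    a species' reads before normalising (depth-weighted). Columns are species,
    rows taxa; each column sums to 100.
    """
    agg = aggregate_counts(table, taxonomy)
    out = {}
    for sp in sorted(table.species_of_sample.unique()):
        sub = agg.loc[table.species_of_sample.reindex(agg.index) == sp]
        if pooled:
            tot = sub.sum(axis=0)
            out[sp] = 100.0 * tot / tot.sum()
        else:
            props = _per_sample_proportions(sub)
            out[sp] = 100.0 * props.mean(axis=0)
    return pd.DataFrame(out)


def rra_sample_proportions(
    table: MotuTable, taxonomy: Mapping[str, str]
) -> pd.DataFrame:
    """Per-sample within-sample read proportions at the taxonomy level.

    Rows are samples (zero-read samples excluded with a warning), columns
    taxa; rows sum to 1. These per-sample proportion vectors are the raw
    material both for Bray–Curtis distances and for treating each taxon's
    proportion as one continuous niche variable.
    """
    return _per_sample_proportions(aggregate_counts(table, taxonomy))


def foo(presence: pd.DataFrame, species: pd.Series) -> pd.DataFrame:
    """Percent frequency of occurrence per taxon and species.

    ``presence`` is a boolean sample x taxon matrix; ``species`` labels each
    sample. %FOO(taxon) = 100 * (samples of the species containing the
    taxon) / (samples of the species).
    """
    if presence.shape[0] == 0:
        raise ValueError("presence matrix has no samples")
    out = {}
    for sp in sorted(species.unique()):
        sub = presence.loc[species.reindex(presence.index) == sp]
        if sub.shape[0] == 0:
            raise ValueError(f"no samples for species {sp!r}")
        out[sp] = 100.0 * sub.mean(axis=0)
    return pd.DataFrame(out)


def individual_richness(table: MotuTable) -> tuple[pd.Series, pd.DataFrame]:
    """Per-sample MOTU richness and a per-species mean ± SE summary.

    Richness of a sample is the number of MOTUs with at least one read.
    Returns the per-sample vector and a DataFrame with columns ``mean``,
    ``se``, ``n`` indexed by species.
    """
    richness = (table.counts > 0).sum(axis=1)
    rows = {}
    for sp in sorted(table.species_of_sample.unique()):
        vals = richness[table.species_of_sample == sp].to_numpy(dtype=float)
        se = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
        rows[sp] = {"mean": float(vals.mean()), "se": se, "n": int(vals.size)}
    return richness, pd.DataFrame(rows).T


@dataclass(frozen=True)
class NicheBreadthResult:
    """Levins niche breadth B and its standardized form B_A in [0, 1]."""

    species: str
    B: float
    B_A: float
    n_categories: int


def levins_ba(
    proportions: Sequence[float],
    species: str = "",
    n_categories: int | None = None,
    tol: float = 1e-6,
) -> NicheBreadthResult:
    """Standardized Levins niche breadth from diet category proportions.

    B = 1 / sum p_i^2 ranges from 1 (single resource) to n (uniform use of n
    categories); B_A = (B - 1)/(n - 1) standardizes it to [0, 1]. The
    denominator ``n_categories`` defaults to the length of ``proportions``
    (categories available to the species, including unused ones with p = 0).
    """
    p = np.asarray(proportions, dtype=float)
    if (p < 0).any():
        raise ValueError("proportions must be non-negative")
    if abs(p.sum() - 1.0) > tol:
        raise ValueError(f"proportions sum to {p.sum():.6f}, expected 1")
    n = int(n_categories) if n_categories is not None else p.size
    if n < 2:
        raise ValueError("need at least 2 categories for a breadth index")
    B = 1.0 / float((p**2).sum())
    B_A = (B - 1.0) / (n - 1.0)
    return NicheBreadthResult(species=species, B=B, B_A=B_A, n_categories=n)


# ---------------------------------------------------------------------------
# Incidence-based rarefaction / extrapolation (Hill q = 0)


def _log_comb(n: np.ndarray, k: np.ndarray) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _interpolated_richness(Y: np.ndarray, T: int, t: int) -> float:
    """Expected richness in t of T samples (hypergeometric form).

    S(t) = sum_i [1 - C(T - Y_i, t) / C(T, t)] over species with incidence
    frequency Y_i, exact for sample-based rarefaction without replacement.
    """
    Y = Y[Y > 0]
    keep = (T - Y) >= t
    miss = np.zeros(Y.size)
    if keep.any():
        miss[keep] = np.exp(_log_comb(T - Y[keep], t) - _log_comb(T, t))
    return float((1.0 - miss).sum())


def _chao2_unseen(Y: np.ndarray, T: int) -> tuple[float, float, float]:
    """Estimated number of unseen species (Chao2 form) plus Q1, Q2."""
    Q1 = float((Y == 1).sum())
    Q2 = float((Y == 2).sum())
    if Q2 > 0:
        Q0 = (T - 1) / T * Q1**2 / (2 * Q2)
    else:
        Q0 = (T - 1) / T * Q1 * (Q1 - 1) / 2
    return Q0, Q1, Q2


def _extrapolated_richness(Y: np.ndarray, T: int, t_star: int) -> float:
    """Expected richness at T + t_star samples (Chao2-based)."""
    S_obs = float((Y > 0).sum())
    Q0, Q1, _ = _chao2_unseen(Y, T)
    if Q1 == 0 or Q0 == 0:
        return S_obs
    return S_obs + Q0 * (1.0 - (1.0 - Q1 / (Q1 + T * Q0)) ** t_star)


def _richness_curve(Y: np.ndarray, T: int, t_values: np.ndarray) -> np.ndarray:
    out = np.empty(t_values.size)
    for i, t in enumerate(t_values):
        if t <= T:
            out[i] = _interpolated_richness(Y, T, int(t))
        else:
            out[i] = _extrapolated_richness(Y, T, int(t) - T)
    return out


def rarefaction_extrapolation(
    presence: pd.DataFrame | np.ndarray,
    t_values: Sequence[int] | None = None,
    n_boot: int = 1000,
    seed: int | None = None,
    ci: float = 0.95,
) -> pd.DataFrame:
    """Sample-based richness rarefaction/extrapolation with bootstrap CIs.

    ``presence`` is a sample x species incidence matrix (boolean or counts;
    any positive entry is a detection). Interpolation up to the observed T
    samples uses the exact hypergeometric estimator; extrapolation (default
    to 2T) uses the Chao2-based asymptotic form. Confidence bands are
    percentile bootstrap over samples (resampled with replacement), seeded.

    Returns a tidy DataFrame with columns ``t``, ``method``
    (interpolated/observed/extrapolated), ``richness``, ``lo``, ``hi``.
    """
    inc = np.asarray(presence, dtype=bool).astype(int)
    T = inc.shape[0]
    if T < 2:
        raise ValueError("need at least 2 samples for rarefaction")
    Y = inc.sum(axis=0)
    if t_values is None:
        t_values = np.arange(1, 2 * T + 1)
    t_values = np.asarray(sorted(set(int(t) for t in t_values)))
    if (t_values < 1).any():
        raise ValueError("t values must be >= 1")
    est = _richness_curve(Y, T, t_values)

    rng = np.random.default_rng(seed)
    boot = np.empty((n_boot, t_values.size))
    for b in range(n_boot):
        idx = rng.integers(0, T, size=T)
        boot[b] = _richness_curve(inc[idx].sum(axis=0), T, t_values)
    alpha = (1.0 - ci) / 2.0
    lo = np.quantile(boot, alpha, axis=0)
    hi = np.quantile(boot, 1.0 - alpha, axis=0)

    method = np.where(
        t_values < T, "interpolated", np.where(t_values == T, "observed", "extrapolated")
    )
    return pd.DataFrame(
        {"t": t_values, "method": method, "richness": est, "lo": lo, "hi": hi}
    )
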