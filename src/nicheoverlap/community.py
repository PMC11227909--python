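"""Diet-composition similarity between groups: Bray–Curtis and ANOSIM.

Bray–Curtis dissimilarity between two non-negative composition vectors u, v
is sum|u_i - v_i| / sum(u_i + v_i), bounded in [0, 1] for proportions. The
ANOSIM (analysis of similarities) statistic contrasts the mean rank of
between-group distances with the mean rank of within-group distances,

    R = (mean_rank_between - mean_rank_within) / (n (n - 1) / 4),

so R near 0 means groups are interchangeable and R near 1 means all
between-group distances exceed within-group ones. Significance comes from
permuting group labels; for small inputs every distinct relabelling can be
enumerated exactly.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from math import comb, factorial

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

__all__ = ["DistanceMatrix", "AnosimResult", "bray_curtis", "anosim"]


@dataclass
class DistanceMatrix:
    """Symmetric sample-by-sample distances with ids; zero diagonal."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.ids):
            raise ValueError("distance matrix must be square and match ids")
        finite = np.isfinite(v)
        if not np.allclose(v[finite], v.T[finite.T]):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("distance matrix diagonal must be zero")
        self.values = v

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


@dataclass(frozen=True)
class AnosimResult:
    """ANOSIM statistic R in [-1, 1] with its permutation p-value."""

    R: float
    p: float
    n_perm: int
    exact: bool = False


def bray_curtis(profiles: pd.DataFrame) -> DistanceMatrix:
    """Pairwise Bray–Curtis dissimilarities between composition rows.

    ``profiles`` is a sample x taxon matrix of non-negative values (read
    counts or proportions). A pair in which both vectors are all-zero has an
    undefined distance; such entries are reported as NaN with a warning.
    """
    x = profiles.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("composition vectors must be non-negative")
    with np.errstate(invalid="ignore", divide="ignore"):
        d = squareform(pdist(x, metric="braycurtis"), checks=False)
    np.fill_diagonal(d, 0.0)
    if np.isnan(d).any():
        warnings.warn("all-zero sample pair(s): Bray-Curtis undefined, set to NaN")
    return DistanceMatrix(ids=[str(i) for i in profiles.index], values=d)


def _anosim_r(ranks: np.ndarray, within_mask: np.ndarray, n: int) -> float:
    rw = ranks[within_mask].mean()
    rb = ranks[~within_mask].mean()
    return float((rb - rw) / (n * (n - 1) / 4.0))


def _within_mask(labels: np.ndarray, n: int) -> np.ndarray:
    i, j = np.triu_indices(n, k=1)
    return labels[i] == labels[j]


def anosim(
    dist: DistanceMatrix,
    labels,
    n_perm: int = 999,
    seed: int | None = None,
    exact: bool | None = None,
) -> AnosimResult:
    """ANOSIM test of compositional difference between labelled groups.

    Distances are rank-transformed once with mid-ranks for ties. The
    p-value is the proportion of relabellings whose R is at least the
    observed R. With ``exact=True`` (or by default when the number of
    distinct relabellings is at most 10,000) every distinct assignment of
    labels to samples is enumerated and p = #{R_perm >= R_obs} / #assignments
    (the identity assignment makes p strictly positive). Otherwise ``n_perm``
    random relabellings are drawn with the seeded generator and
    p = (1 + #{R_perm >= R_obs}) / (n_perm + 1).
    """
    labels = np.asarray([str(l) for l in labels])
    n = len(dist.ids)
    if labels.size != n:
        raise ValueError("labels length must match distance matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2 or (counts < 2).any():
        raise ValueError("need >= 2 groups with >= 2 samples each")
    condensed = dist.condensed()
    if np.isnan(condensed).any():
        raise ValueError("distance matrix contains undefined (NaN) entries")
    ranks = rankdata(condensed)
    within = _within_mask(labels, n)
    r_obs = _anosim_r(ranks, within, n)

    n_distinct = factorial(n) // int(np.prod([factorial(int(c)) for c in counts]))
    if exact is None:
        exact = n_distinct <= 10_000

    if exact:
        hits = 0
        for perm in set(itertools.permutations(labels)):
            mask = _within_mask(np.asarray(perm), n)
            if _anosim_r(ranks, mask, n) >= r_obs - 1e-12:
                hits += 1
        return AnosimResult(R=r_obs, p=hits / n_distinct, n_perm=n_distinct, exact=True)

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        mask = _within_mask(rng.permutation(labels), n)
        if _anosim_r(ranks, mask, n) >= r_obs - 1e-12:
            hits += 1
    return AnosimResult(R=r_obs, p=(1 + hits) / (n_perm + 1), n_perm=n_perm, exact=False)
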