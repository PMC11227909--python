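"""MOTU count tables: quality filtering and similarity-threshold taxonomy.

A MOTU (molecular operational taxonomic unit) is a 97%-identity sequence
cluster standing in for a prey taxon in a COI metabarcoding diet study. This
module consumes a post-clustering sample x MOTU read-count matrix and applies
the standard downstream hygiene:

* a per-sample relative-abundance floor (entries below 0.1% of the sample's
  reads are zeroed — tag-jumping / index-hopping artefacts),
* a global minimum read count per MOTU (< 3 reads total -> dropped),
* a prevalence floor (MOTUs detected in a single sample -> dropped),

followed by threshold-based taxonomy assignment from reference-database
similarity scores (species > 98%, family > 96.5%, order > 95%), with the
usual downgrade-to-common-rank rule for tied best hits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MotuTable",
    "FilterReport",
    "TaxonomyRecord",
    "filter_counts",
    "rank_from_similarity",
    "assign_taxonomy",
    "read_motu_tsv",
    "write_motu_tsv",
    "read_taxonomy_tsv",
    "write_taxonomy_tsv",
    "taxonomy_map",
]

#: Taxonomic ranks from finest to coarsest resolution used for assignment.
RANKS = ("species", "family", "order")


@dataclass
class MotuTable:
    """Sample x MOTU read-count matrix with per-sample species labels.

    ``counts`` is a DataFrame indexed by sample id with one integer column per
    MOTU; ``species_of_sample`` maps each sample id to its host species label.
    """

    counts: pd.DataFrame
    species_of_sample: pd.Series

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("sample ids must be unique")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("read counts must be non-negative")
        self.species_of_sample = self.species_of_sample.reindex(self.counts.index)
        if self.species_of_sample.isna().any():
            missing = list(self.counts.index[self.species_of_sample.isna()])
            raise ValueError(f"samples without a species label: {missing}")
        self.counts = self.counts.astype(np.int64)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def motu_ids(self) -> list[str]:
        return list(self.counts.columns)

    def subset_species(self, species: str) -> pd.DataFrame:
        """Count sub-matrix of the samples belonging to one species."""
        mask = self.species_of_sample == species
        return self.counts.loc[mask]


@dataclass
class FilterReport:
    """What each filtering step removed, accumulated over passes."""

    entries_zeroed: int = 0
    motus_dropped_low_total: list[str] = field(default_factory=list)
    motus_dropped_low_prevalence: list[str] = field(default_factory=list)
    empty_samples: list[str] = field(default_factory=list)
    n_passes: int = 0


def filter_counts(
    table: MotuTable,
    min_rel_abund: float = 0.001,
    min_total: int = 3,
    min_samples: int = 2,
) -> tuple[MotuTable, FilterReport]:
    """Apply the three count-table quality filters, iterated to a fixed point.

    Each pass applies, in order: (1) zero any entry below ``min_rel_abund``
    of its sample's current total; (2) drop MOTUs with total reads below
    ``min_total``; (3) drop MOTUs detected in fewer than ``min_samples``
    samples. Dropping MOTUs shrinks sample totals, which can push further
    entries under the relative-abundance floor, so passes repeat until the
    table stops changing — this makes the operation idempotent. Samples left
    with zero reads are flagged in the report, not dropped.
    """
    counts = table.counts.copy()
    report = FilterReport()
    while True:
        report.n_passes += 1
        arr = counts.to_numpy(dtype=np.float64)
        totals = arr.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            below = (arr > 0) & (arr < min_rel_abund * totals)
        report.entries_zeroed += int(below.sum())
        arr[below] = 0
        counts = pd.DataFrame(
            arr.astype(np.int64), index=counts.index, columns=counts.columns
        )

        low_total = counts.columns[counts.sum(axis=0) < min_total]
        report.motus_dropped_low_total.extend(low_total)
        counts = counts.drop(columns=low_total)

        low_prev = counts.columns[(counts > 0).sum(axis=0) < min_samples]
        report.motus_dropped_low_prevalence.extend(low_prev)
        counts = counts.drop(columns=low_prev)

        if not below.any() and len(low_total) == 0 and len(low_prev) == 0:
            break

    report.empty_samples = list(counts.index[counts.sum(axis=1) == 0])
    if counts.to_numpy().sum() == 0:
        warnings.warn("filtering removed every read; output table is empty")
    return MotuTable(counts=counts, species_of_sample=table.species_of_sample), report


# ---------------------------------------------------------------------------
# Taxonomy assignment


@dataclass
class TaxonomyRecord:
    """Taxonomy assigned to one MOTU from reference-database best hits.

    ``candidates`` holds the hits considered, each a mapping with keys
    ``order``, ``family``, ``species`` and ``similarity`` (percent identity).
    """

    motu_id: str
    best_similarity: float
    candidates: list[dict]
    assigned_rank: str
    assigned_name: str


def rank_from_similarity(similarity: float) -> str:
    """Finest admissible rank for a best-hit percent identity.

    >= 98 -> species; (96.5, 98) -> family; (95, 96.5] -> order; <= 95 ->
    unidentified.
    """
    if not 0 <= similarity <= 100:
        raise ValueError(f"similarity {similarity} outside [0, 100]")
    if similarity >= 98:
        return "species"
    if similarity > 96.5:
        return "family"
    if similarity > 95:
        return "order"
    return "unidentified"


def _common_rank(cands: Sequence[Mapping]) -> str:
    """Finest rank at which all candidates name the same taxon."""
    for rank in RANKS:
        names = {c.get(rank) for c in cands}
        if len(names) == 1 and None not in names:
            return rank
    return "unidentified"


_RANK_ORDER = {"species": 0, "family": 1, "order": 2, "unidentified": 3}


def assign_taxonomy(motu_id: str, candidates: Sequence[Mapping]) -> TaxonomyRecord:
    """Assign a rank and name to one MOTU from its database hits.

    The similarity of the best hit sets a ceiling on resolution
    (:func:`rank_from_similarity`). When several candidates tie at the best
    similarity, resolution is further downgraded to the finest rank at which
    all tied candidates agree. The assigned name is the tied candidates'
    shared taxon at the final rank, or ``"unidentified"``.
    """
    if not candidates:
        raise ValueError(f"MOTU {motu_id}: empty candidate list")
    for c in candidates:
        if not 0 <= c["similarity"] <= 100:
            raise ValueError(f"MOTU {motu_id}: similarity outside [0, 100]")
    best = max(c["similarity"] for c in candidates)
    tied = [c for c in candidates if abs(c["similarity"] - best) < 1e-9]
    sim_rank = rank_from_similarity(best)
    agree_rank = _common_rank(tied)
    rank = max((sim_rank, agree_rank), key=_RANK_ORDER.__getitem__)
    if rank == "unidentified":
        name = "unidentified"
    else:
        name = tied[0][rank]
    return TaxonomyRecord(
        motu_id=motu_id,
        best_similarity=float(best),
        candidates=[dict(c) for c in candidates],
        assigned_rank=rank,
        assigned_name=name,
    )


# ---------------------------------------------------------------------------
# I/O: plain-text TSV interchange


def read_motu_tsv(path, species_of_sample: Mapping[str, str] | None = None) -> MotuTable:
    """Read a sample x MOTU count TSV (first column sample_id).

    The species label per sample may be given either as a ``species`` column
    in the file or via ``species_of_sample``.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "species" in df.columns:
        species = df.pop("species").astype(str)
    elif species_of_sample is not None:
        species = pd.Series({s: species_of_sample[s] for s in df.index})
    else:
        raise ValueError("no species column in TSV and no species_of_sample given")
    return MotuTable(counts=df, species_of_sample=species)


def write_motu_tsv(table: MotuTable, path) -> None:
    out = table.counts.copy()
    out.insert(0, "species", table.species_of_sample)
    out.to_csv(path, sep="\t", index_label="sample_id")


def write_taxonomy_tsv(records: Sequence[TaxonomyRecord], path) -> None:
    """Write taxonomy records as TSV with semicolon-delimited best lineage."""
    rows = []
    for r in records:
        best = max(r.candidates, key=lambda c: c["similarity"])
        lineage = ";".join(str(best.get(k, "")) for k in ("order", "family", "species"))
        rows.append(
            {
                "motu_id": r.motu_id,
                "best_similarity": r.best_similarity,
                "lineage": lineage,
                "assigned_rank": r.assigned_rank,
                "assigned_name": r.assigned_name,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_taxonomy_tsv(path) -> list[TaxonomyRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"motu_id": str})
    records = []
    for row in df.itertuples(index=False):
        order, family, species = (str(row.lineage).split(";") + ["", "", ""])[:3]
        cand = {
            "order": order or None,
            "family": family or None,
            "species": species or None,
            "similarity": float(row.best_similarity),
        }
        records.append(
            TaxonomyRecord(
                motu_id=str(row.motu_id),
                best_similarity=float(row.best_similarity),
                candidates=[cand],
                assigned_rank=str(row.assigned_rank),
                assigned_name=str(row.assigned_name),
            )
        )
    return records


def taxonomy_map(records: Sequence[TaxonomyRecord], level: str) -> dict[str, str]:
    """MOTU id -> taxon name at ``level`` ("order" or "family").

    MOTUs whose assigned resolution is coarser than ``level`` map to
    ``"<class or 'unidentified'>_others"``-style buckets only when the caller
    aggregates; here they simply map to ``"unidentified"`` at that level.
    A species-level assignment carries its full candidate lineage, so order
    and family are taken from the best candidate.
    """
    if level not in ("order", "family"):
        raise ValueError("level must be 'order' or 'family'")
    out: dict[str, str] = {}
    level_idx = _RANK_ORDER[level]
    for r in records:
        best = max(r.candidates, key=lambda c: c["similarity"])
        if _RANK_ORDER[r.assigned_rank] <= level_idx and best.get(level):
            out[r.motu_id] = str(best[level])
        else:
            out[r.motu_id] = "unidentified"
    return out
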