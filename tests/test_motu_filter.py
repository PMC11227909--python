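"""MOTU count filtering rules and similarity-threshold taxonomy assignment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nicheoverlap.motus import (
    MotuTable,
    assign_taxonomy,
    filter_counts,
    rank_from_similarity,
    read_motu_tsv,
    read_taxonomy_tsv,
    taxonomy_map,
    write_motu_tsv,
    write_taxonomy_tsv,
)


def make_table(counts: dict, species=None):
    df = pd.DataFrame(counts)
    df.index = [f"s{i}" for i in range(len(df))]
    sp = pd.Series(species or ["A"] * len(df), index=df.index)
    return MotuTable(counts=df, species_of_sample=sp)


def test_low_relative_abundance_entry_zeroed():
    # s0 has 10,000 reads; a 9-read entry is < 0.1% and is zeroed, but the
    # MOTU survives because two other samples carry it comfortably.
    t = make_table({"X": [9, 50, 60], "Y": [9991, 950, 940]})
    filtered, report = filter_counts(t)
    assert filtered.counts.loc["s0", "X"] == 0
    assert filtered.counts.loc["s1", "X"] == 50
    assert report.entries_zeroed == 1


def test_low_total_and_single_sample_motus_dropped():
    t = make_table(
        {"low": [2, 0, 0], "single": [0, 500, 0], "keep": [500, 500, 500]}
    )
    filtered, report = filter_counts(t)
    assert list(filtered.counts.columns) == ["keep"]
    assert "low" in report.motus_dropped_low_total
    assert "single" in report.motus_dropped_low_prevalence


def test_clean_table_unchanged():
    t = make_table({"X": [50, 50], "Y": [950, 950]})
    filtered, report = filter_counts(t)
    assert filtered.counts.equals(t.counts)
    assert report.entries_zeroed == 0


def test_all_zero_table_warns_not_raises():
    t = make_table({"X": [1, 1]})
    with pytest.warns(UserWarning, match="empty"):
        filtered, report = filter_counts(t)
    assert filtered.counts.shape[1] == 0
    assert report.empty_samples == ["s0", "s1"]


@settings(max_examples=50, deadline=None)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_filtering_idempotent_and_contractive(seed):
    rng = np.random.default_rng(seed)
    counts = rng.integers(0, 200, size=(6, 10)) * rng.integers(0, 2, size=(6, 10))
    t = make_table({f"m{j}": counts[:, j] for j in range(10)})
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        once, _ = filter_counts(t)
        twice, rep2 = filter_counts(once)
    assert once.counts.equals(twice.counts)
    assert rep2.entries_zeroed == 0
    # retained entries are a zero-or-equal submatrix of the input
    common = once.counts.columns
    assert (once.counts[common].to_numpy() <= t.counts[common].to_numpy()).all()


@pytest.mark.parametrize(
    "similarity, rank",
    [
        (99.1, "species"),
        (98.0, "species"),
        (97.9, "family"),
        (96.6, "family"),
        (96.5, "order"),
        (96.0, "order"),
        (95.1, "order"),
        (95.0, "unidentified"),
        (94.0, "unidentified"),
    ],
)
def test_similarity_thresholds(similarity, rank):
    assert rank_from_similarity(similarity) == rank


def test_rank_monotone_in_similarity():
    order = {"unidentified": 0, "order": 1, "family": 2, "species": 3}
    sims = np.linspace(0, 100, 401)
    ranks = [order[rank_from_similarity(s)] for s in sims]
    assert all(a <= b for a, b in zip(ranks, ranks[1:]))


def _cand(order, family, species, sim):
    return {"order": order, "family": family, "species": species, "similarity": sim}


def test_single_best_hit_species_level():
    rec = assign_taxonomy("m1", [_cand("Lepidoptera", "Noctuidae", "Agrotis ipsilon", 99.1)])
    assert rec.assigned_rank == "species"
    assert rec.assigned_name == "Agrotis ipsilon"


def test_tie_same_family_downgrades_to_family():
    cands = [
        _cand("Lepidoptera", "Noctuidae", "Agrotis ipsilon", 98.6),
        _cand("Lepidoptera", "Noctuidae", "Xestia c-nigrum", 98.6),
    ]
    rec = assign_taxonomy("m1", cands)
    assert rec.assigned_rank == "family"
    assert rec.assigned_name == "Noctuidae"


def test_tie_different_families_downgrades_to_order():
    cands = [
        _cand("Lepidoptera", "Noctuidae", "Agrotis ipsilon", 99.0),
        _cand("Lepidoptera", "Erebidae", "Lymantria dispar", 99.0),
    ]
    assert assign_taxonomy("m1", cands).assigned_rank == "order"


def test_tie_agreement_capped_by_similarity():
    # candidates agree at species level but similarity only supports order
    cands = [_cand("Diptera", "Muscidae", "Musca domestica", 96.0)] * 2
    rec = assign_taxonomy("m1", cands)
    assert rec.assigned_rank == "order"
    assert rec.assigned_name == "Diptera"


def test_low_similarity_unidentified():
    rec = assign_taxonomy("m1", [_cand("Diptera", "Muscidae", "Musca domestica", 94.0)])
    assert rec.assigned_rank == "unidentified"
    assert rec.assigned_name == "unidentified"


def test_empty_candidates_rejected():
    with pytest.raises(ValueError):
        assign_taxonomy("m1", [])


def test_tsv_round_trip(tmp_path):
    t = make_table({"X": [5, 6], "Y": [7, 8]}, species=["A", "B"])
    write_motu_tsv(t, tmp_path / "motus.tsv")
    back = read_motu_tsv(tmp_path / "motus.tsv")
    assert back.counts.equals(t.counts)
    assert (back.species_of_sample == t.species_of_sample).all()

    recs = [
        assign_taxonomy("X", [_cand("Lepidoptera", "Noctuidae", "A b", 99.0)]),
        assign_taxonomy("Y", [_cand("Diptera", "Muscidae", "C d", 96.0)]),
    ]
    write_taxonomy_tsv(recs, tmp_path / "tax.tsv")
    back_recs = read_taxonomy_tsv(tmp_path / "tax.tsv")
    tmap = taxonomy_map(back_recs, "order")
    assert tmap == {"X": "Lepidoptera", "Y": "Diptera"}
    # family level: the order-rank MOTU is unresolved at family
    fmap = taxonomy_map(back_recs, "family")
    assert fmap == {"X": "Noctuidae", "Y": "unidentified"}
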