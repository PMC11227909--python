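"""RRA, %FOO, individual richness, Levins breadth, incidence rarefaction."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nicheoverlap.diet import (
    foo,
    individual_richness,
    levins_ba,
    rarefaction_extrapolation,
    rra,
    rra_sample_proportions,
)
from nicheoverlap.motus import MotuTable


def make_table(counts, species):
    df = pd.DataFrame(counts)
    df.index = [f"s{i}" for i in range(len(df))]
    return MotuTable(counts=df, species_of_sample=pd.Series(species, index=df.index))


IDENTITY_TAX = {"X": "X", "Y": "Y"}


def test_rra_is_mean_of_per_sample_proportions():
    # two samples: all-X and all-Y -> RRA 50/50 even with unequal depths
    t = make_table({"X": [1000, 0], "Y": [0, 10]}, ["A", "A"])
    r = rra(t, IDENTITY_TAX)
    assert r.loc["X", "A"] == pytest.approx(50.0)
    assert r.loc["Y", "A"] == pytest.approx(50.0)
    # pooled form weights by depth instead
    rp = rra(t, IDENTITY_TAX, pooled=True)
    assert rp.loc["X", "A"] == pytest.approx(100 * 1000 / 1010)


def test_rra_sums_to_100_per_species():
    rng = np.random.default_rng(5)
    counts = rng.integers(0, 100, size=(8, 4))
    counts[:, 0] += 1  # no empty samples
    t = make_table({f"m{j}": counts[:, j] for j in range(4)}, ["A"] * 4 + ["B"] * 4)
    r = rra(t, {f"m{j}": f"t{j % 2}" for j in range(4)})
    assert r.sum(axis=0).to_numpy() == pytest.approx([100.0, 100.0])


def test_rra_excludes_empty_samples_with_warning():
    t = make_table({"X": [10, 0], "Y": [10, 0]}, ["A", "A"])
    with pytest.warns(UserWarning, match="zero reads"):
        r = rra(t, IDENTITY_TAX)
    assert r.loc["X", "A"] == pytest.approx(50.0)


def test_foo_counts_presence_fraction():
    presence = pd.DataFrame(
        {"X": [True, True, True, False], "Y": [True] * 4, "Z": [False] * 4},
        index=[f"s{i}" for i in range(4)],
    )
    species = pd.Series(["A"] * 4, index=presence.index)
    f = foo(presence, species)
    assert f.loc["X", "A"] == 75.0
    assert f.loc["Y", "A"] == 100.0
    assert f.loc["Z", "A"] == 0.0


def test_individual_richness_counts_and_summary():
    t = make_table({"X": [5, 0, 3], "Y": [0, 0, 5], "Z": [2, 0, 0]}, ["A", "A", "B"])
    per_sample, summary = individual_richness(t)
    assert list(per_sample) == [2, 0, 2]
    assert summary.loc["A", "mean"] == 1.0
    assert summary.loc["B", "mean"] == 2.0
    # two samples with richness 3 and 5 -> mean 4, SE 1
    t2 = make_table(
        {f"m{j}": [1 if j < 3 else 0, 1] for j in range(5)}, ["A", "A"]
    )
    _, s2 = individual_richness(t2)
    assert s2.loc["A", "mean"] == 4.0
    assert s2.loc["A", "se"] == pytest.approx(1.0)


@pytest.mark.parametrize(
    "p, expected_B, expected_BA",
    [
        ([0.25, 0.25, 0.25, 0.25], 4.0, 1.0),
        ([1.0, 0.0, 0.0], 1.0, 0.0),
        ([0.5, 0.25, 0.25], 1 / 0.375, (1 / 0.375 - 1) / 2),
    ],
)
def test_levins_breadth_known_values(p, expected_B, expected_BA):
    res = levins_ba(p)
    assert res.B == pytest.approx(expected_B)
    assert res.B_A == pytest.approx(expected_BA)


def test_levins_invariances_and_validation():
    base = levins_ba([0.5, 0.3, 0.2]).B_A
    assert levins_ba([0.2, 0.5, 0.3]).B_A == pytest.approx(base)
    # concentrating mass strictly reduces breadth
    assert levins_ba([0.7, 0.2, 0.1]).B_A < base
    with pytest.raises(ValueError):
        levins_ba([1.0])
    with pytest.raises(ValueError):
        levins_ba([0.5, 0.6])
    with pytest.raises(ValueError):
        levins_ba([1.2, -0.2])


@settings(max_examples=30, deadline=None)
@given(st.lists(st.floats(0.01, 1.0), min_size=2, max_size=10))
def test_levins_bounds_property(weights):
    p = np.asarray(weights) / np.sum(weights)
    res = levins_ba(p)
    assert 1.0 <= res.B <= res.n_categories + 1e-9
    assert -1e-9 <= res.B_A <= 1 + 1e-9


TOY_INCIDENCE = np.array(
    [[1, 1, 0, 0, 1], [0, 1, 1, 0, 0], [1, 0, 1, 1, 0]]
)


def test_rarefaction_endpoint_identities():
    df = rarefaction_extrapolation(TOY_INCIDENCE, n_boot=50, seed=0)
    est = df.set_index("t")["richness"]
    assert est[3] == pytest.approx(5.0)  # observed richness at t = T
    assert est[1] == pytest.approx(TOY_INCIDENCE.sum(axis=1).mean())


def test_rarefaction_t2_matches_pair_enumeration():
    pairs = [
        len(np.nonzero(TOY_INCIDENCE[list(c)].sum(axis=0))[0])
        for c in itertools.combinations(range(3), 2)
    ]
    df = rarefaction_extrapolation(TOY_INCIDENCE, n_boot=50, seed=0)
    assert df.set_index("t")["richness"][2] == pytest.approx(np.mean(pairs))


def test_rarefaction_monotone_concave_interpolation():
    rng = np.random.default_rng(8)
    inc = rng.random((12, 30)) < 0.3
    df = rarefaction_extrapolation(inc, n_boot=20, seed=0)
    r = df["richness"].to_numpy()
    t = df["t"].to_numpy()
    interp = r[t <= 12]
    diffs = np.diff(interp)
    assert (diffs >= -1e-9).all()
    assert (np.diff(diffs) <= 1e-9).all()  # concave
    assert (np.diff(r) >= -1e-9).all()  # extrapolation keeps rising


def test_rarefaction_ci_brackets_estimate_and_needs_two_samples():
    df = rarefaction_extrapolation(TOY_INCIDENCE, n_boot=200, seed=1)
    assert (df["lo"] <= df["richness"] + 1e-9).all()
    assert (df["hi"] >= df["richness"] - 1e-9).all()
    with pytest.raises(ValueError):
        rarefaction_extrapolation(TOY_INCIDENCE[:1])
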