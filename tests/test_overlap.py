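"""Overlap indices, null-model permutation test, Holm adjustment, composites."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nicheoverlap.overlap import (
    NicheVariable,
    categorical_overlap,
    composite,
    continuous_overlap,
    null_model_test,
    overlap_for_variable,
    sequential_bonferroni,
    silverman_bandwidth,
)
from nicheoverlap.synthetic import normal_overlap


def test_identical_samples_full_overlap():
    x = np.random.default_rng(0).normal(0, 1, 200)
    assert continuous_overlap(x, x) == pytest.approx(1.0, abs=1e-6)


def test_disjoint_samples_no_overlap():
    rng = np.random.default_rng(1)
    a = rng.normal(0, 1, 500)
    b = rng.normal(100, 1, 500)
    assert continuous_overlap(a, b) < 0.01


def test_continuous_overlap_recovers_analytic_normal_value():
    rng = np.random.default_rng(2)
    a = rng.normal(0, 1, 2000)
    b = rng.normal(3, 1, 2000)
    true = normal_overlap(0, 1, 3, 1)
    assert true == pytest.approx(0.13361, abs=1e-4)  # 2*Phi(-1.5)
    assert continuous_overlap(a, b) == pytest.approx(true, abs=0.03)


def test_continuous_overlap_symmetric_and_bounded():
    rng = np.random.default_rng(3)
    a = rng.normal(0, 1, 150)
    b = rng.normal(1, 2, 80)
    o1 = continuous_overlap(a, b)
    o2 = continuous_overlap(b, a)
    assert o1 == pytest.approx(o2, abs=1e-12)
    assert 0.0 <= o1 <= 1.0


def test_continuous_overlap_input_validation():
    with pytest.raises(ValueError):
        continuous_overlap([], [1.0, 2.0, 3.0])
    with pytest.raises(ValueError):
        continuous_overlap([1.0, 2.0], [1.0, 2.0, 3.0])
    with pytest.raises(ValueError):
        continuous_overlap([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def test_bounded_support_reflection_keeps_unit_mass():
    # proportions piled near 0: plain KDE would leak mass below 0
    rng = np.random.default_rng(4)
    a = rng.beta(2, 8, 400)
    assert continuous_overlap(a, a, bounds=(0, 1)) == pytest.approx(1.0, abs=1e-6)


def test_categorical_overlap_hand_values():
    assert categorical_overlap(["a", "a", "b", "b"], ["a", "a", "b", "b"]) == 1.0
    assert categorical_overlap(["a"] * 5, ["b"] * 3) == 0.0
    # p_A = (0.5, 0.5, 0), p_B = (0.25, 0.25, 0.5) -> 0.5
    a = ["x", "x", "y", "y"]
    b = ["x", "y", "z", "z"]
    assert categorical_overlap(a, b) == pytest.approx(0.5)
    assert categorical_overlap(b, a) == pytest.approx(0.5)


def test_zero_spread_falls_back_to_categorical():
    v = NicheVariable("flat", "nest_site", "continuous", [2.0] * 10, [2.0] * 5 + [3.0] * 5)
    with pytest.warns(UserWarning, match="zero-spread"):
        assert overlap_for_variable(v) == pytest.approx(0.5)


@settings(max_examples=30, deadline=None)
@given(
    st.lists(st.sampled_from("abcd"), min_size=1, max_size=20),
    st.lists(st.sampled_from("abcd"), min_size=1, max_size=20),
)
def test_categorical_overlap_properties(a, b):
    o = categorical_overlap(a, b)
    assert 0.0 <= o <= 1.0
    assert o == pytest.approx(categorical_overlap(b, a))
    assert categorical_overlap(a, a) == pytest.approx(1.0)


def test_silverman_bandwidth_formula():
    rng = np.random.default_rng(5)
    x = rng.normal(0, 2, 100)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    expect = 0.9 * min(x.std(ddof=1), iqr / 1.34) * 100 ** (-0.2)
    assert silverman_bandwidth(x) == pytest.approx(expect)


# ---------------------------------------------------------------------------
# Null model


def test_identity_relabelling_reproduces_observed():
    rng = np.random.default_rng(6)
    v = NicheVariable("x", "d", "continuous", rng.normal(0, 1, 30), rng.normal(1, 1, 20))
    obs = overlap_for_variable(v)
    same = NicheVariable("x", "d", "continuous", v.values_A, v.values_B)
    assert overlap_for_variable(same) == pytest.approx(obs, abs=1e-12)


def test_null_model_detects_strong_separation():
    rng = np.random.default_rng(7)
    v = NicheVariable("x", "d", "continuous", rng.normal(0, 1, 50), rng.normal(5, 1, 50))
    res = null_model_test(v, n_perm=300, seed=1)
    assert res.observed < 0.1
    assert res.null_mean > res.observed
    assert res.p_raw < 0.01
    assert res.p_empirical < 0.05
    assert res.null.size == 300


def test_null_model_same_distribution_not_significant():
    rng = np.random.default_rng(8)
    v = NicheVariable("x", "d", "continuous", rng.normal(0, 1, 50), rng.normal(0, 1, 50))
    res = null_model_test(v, n_perm=300, seed=2)
    assert res.p_raw > 0.05


def test_null_model_categorical_variable():
    rng = np.random.default_rng(9)
    a = list(rng.choice(["x", "y"], 40, p=[0.9, 0.1]))
    b = list(rng.choice(["x", "y"], 40, p=[0.1, 0.9]))
    v = NicheVariable("c", "d", "categorical", a, b)
    res = null_model_test(v, n_perm=300, seed=3)
    assert res.p_raw < 0.01


def test_null_model_requires_enough_permutations():
    v = NicheVariable("x", "d", "continuous", np.arange(5.0), np.arange(5.0) + 1)
    with pytest.raises(ValueError):
        null_model_test(v, n_perm=10)


# ---------------------------------------------------------------------------
# Holm and composites


def test_holm_hand_example():
    adj = sequential_bonferroni([0.01, 0.04, 0.03])
    assert adj == pytest.approx([0.03, 0.06, 0.06])


def test_holm_edge_cases():
    assert sequential_bonferroni([0.2]) == pytest.approx([0.2])
    assert sequential_bonferroni([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])
    with pytest.raises(ValueError):
        sequential_bonferroni([0.5, 1.5])


@settings(max_examples=30, deadline=None)
@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12))
def test_holm_dominates_raw_and_capped(ps):
    adj = sequential_bonferroni(ps)
    assert (adj >= np.asarray(ps) - 1e-12).all()
    assert (adj <= 1.0 + 1e-12).all()


def test_composite_mean_sd():
    c = composite([0.448, 0.428, 0.444], dimension="breeding_time")
    assert c.mean == pytest.approx(0.44)
    assert c.sd == pytest.approx(np.std([0.448, 0.428, 0.444], ddof=1))
    single = composite([0.7])
    assert single.sd == 0.0
    with pytest.raises(ValueError):
        composite([])
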