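"""The Monte Carlo alignment test: null scheme, p-values, effect sizes, filters."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import dyad_session, exact_match_rate_distribution, series_from_langs

from langalign.alignment_mc import (
    ExclusionReason,
    alignment_gap,
    apply_inclusion_filters,
    cohens_h,
    expected_rate_analytic,
    mc_p_value,
    permutation_null,
    run_alignment_test,
    run_series_test,
)
from langalign.core import Language, relabel_languages
from langalign.turn_extraction import Direction, extract_turns

A, B = Language.A, Language.B


# --- analytic independence rate ------------------------------------------------


@pytest.mark.parametrize(
    "prev, resp, expected",
    [
        ((0.5, 0.5), (0.5, 0.5), 0.5),
        ((1.0, 0.0), (1.0, 0.0), 1.0),
        ((0.8, 0.2), (0.6, 0.4), 0.56),
    ],
)
def test_expected_rate_analytic(prev, resp, expected):
    assert expected_rate_analytic(prev, resp) == pytest.approx(expected)


def test_expected_rate_rejects_non_distribution():
    with pytest.raises(ValueError, match="sum to 1"):
        expected_rate_analytic((0.8, 0.1), (0.5, 0.5))


# --- Cohen's h -----------------------------------------------------------------


def test_cohens_h_examples():
    assert cohens_h(0.77, 0.57) == pytest.approx(0.43, abs=0.005)
    assert cohens_h(0.4, 0.4) == 0.0
    assert cohens_h(1.0, 0.0) == pytest.approx(math.pi)
    with pytest.raises(ValueError):
        cohens_h(1.2, 0.5)


def test_alignment_gap_in_percentage_points():
    assert alignment_gap(0.77, 0.57) == pytest.approx(20.0)
    assert alignment_gap(0.75, 0.53) == pytest.approx(22.0)


# --- Monte Carlo p-value -------------------------------------------------------


def test_mc_p_value_add_one_estimator():
    null = np.linspace(0, 0.9, 9999)
    assert mc_p_value(1.0, null) == pytest.approx(1 / 10_000)
    assert mc_p_value(-0.1, null) == 1.0
    # all replicates tie with the observed value -> p = 1
    assert mc_p_value(0.5, np.full(1000, 0.5)) == 1.0


# --- permutation null ----------------------------------------------------------


def test_permutation_preserves_marginals_exactly():
    series = series_from_langs([A, A, A, B, B], [A, B, B, B, B])
    rng = np.random.default_rng(0)
    prev = np.array([0, 0, 0, 1, 1])
    n_b_resp = 4
    null = permutation_null(series, n_iterations=500, seed=rng)
    # every replicate's rate must be achievable with exactly 1 A / 4 B responses
    achievable = set()
    import itertools

    for perm in set(itertools.permutations([0, 1, 1, 1, 1])):
        achievable.add(round(float((np.array(perm) == prev).mean()), 10))
    assert {round(float(r), 10) for r in null.rates} <= achievable
    assert null.n_turns == 5 and n_b_resp == 4


def test_small_series_null_equals_exact_enumeration():
    series = series_from_langs([A, B, A], [A, A, B])
    exact = exact_match_rate_distribution(series)
    null = permutation_null(series, n_iterations=30_000, seed=1)
    mc = {
        rate: float((np.isclose(null.rates, rate)).mean()) for rate in exact
    }
    tv = 0.5 * sum(abs(mc[r] - exact[r]) for r in exact)
    assert sum(mc.values()) == pytest.approx(1.0)
    assert tv < 0.02


def test_null_mean_approaches_analytic_rate():
    rng = np.random.default_rng(5)
    prev = [A if rng.random() < 0.6 else B for _ in range(100)]
    resp = [A if rng.random() < 0.7 else B for _ in range(100)]
    series = series_from_langs(prev, resp)
    null = permutation_null(series, n_iterations=10_000, seed=2)
    p_prev = prev.count(A) / 100
    p_resp = resp.count(A) / 100
    analytic = expected_rate_analytic((p_prev, 1 - p_prev), (p_resp, 1 - p_resp))
    assert abs(null.mean - analytic) < 0.01


def test_permuting_both_sequences_is_equivalent_for_the_match_statistic():
    series = series_from_langs(
        [A, A, B, A, B, B, A, A] * 5, [A, B, B, A, A, B, A, B] * 5
    )
    one = permutation_null(series, n_iterations=20_000, seed=3)
    both = permutation_null(series, n_iterations=20_000, seed=4, permute_both=True)
    assert abs(one.mean - both.mean) < 0.01
    assert abs(one.sd - both.sd) < 0.01


def test_empty_series_is_an_error():
    series = series_from_langs([], [])
    with pytest.raises(ValueError, match="at least one turn"):
        permutation_null(series, 100, seed=0)


# --- inclusion filters ---------------------------------------------------------


def _balanced_series(n):
    prev = [A, B] * (n // 2) + [A] * (n % 2)
    resp = [B, A] * (n // 2) + [B] * (n % 2)
    return series_from_langs(prev, resp)


def test_turn_count_boundary_at_thirty():
    included, reason = apply_inclusion_filters(_balanced_series(29))
    assert (included, reason) == (False, ExclusionReason.TOO_FEW_TURNS)
    included, reason = apply_inclusion_filters(_balanced_series(30))
    assert (included, reason) == (True, ExclusionReason.NONE)


def test_dominance_boundary_at_eighty_percent():
    # 100 turns; responses 80% language A -> excluded, 79% -> included
    prev = [A, B] * 50
    resp80 = [A] * 80 + [B] * 20
    resp79 = [A] * 79 + [B] * 21
    assert apply_inclusion_filters(series_from_langs(prev, resp80)) == (
        False,
        ExclusionReason.DOMINANCE,
    )
    assert apply_inclusion_filters(series_from_langs(prev, resp79)) == (
        True,
        ExclusionReason.NONE,
    )


def test_dominance_checks_both_roles():
    prev85 = [A] * 85 + [B] * 15
    resp_balanced = [A, B] * 50
    assert apply_inclusion_filters(series_from_langs(prev85, resp_balanced))[1] == (
        ExclusionReason.DOMINANCE
    )


def test_double_exclusion_reported_as_both():
    series = series_from_langs([A] * 10, [A] * 9 + [B])
    included, reason = apply_inclusion_filters(series)
    assert not included and reason == ExclusionReason.BOTH


# --- end-to-end test behaviour -------------------------------------------------


def test_all_match_series_with_mixed_marginals_hits_p_floor():
    # 40 turns, 60/40 marginals, every turn a match
    langs = [A] * 24 + [B] * 16
    series = series_from_langs(langs, langs)
    result = run_series_test(series, n_iterations=999, seed=7)
    assert result.observed_rate == 1.0
    assert result.null_mean < 1.0
    assert result.cohens_h > 0
    assert result.p_value == pytest.approx(1 / 1000)


def test_same_seed_gives_identical_results(simple_session):
    session = dyad_session([A, A, B, A, B, B, A, A, B, B, A, A])
    kwargs = dict(
        direction=Direction.CHILD_RESPONDS, n_iterations=500, seed=123
    )
    first = run_alignment_test(session, ("cg", "ch"), **kwargs)
    second = run_alignment_test(session, ("cg", "ch"), **kwargs)
    assert first == second


def test_zero_turn_session_yields_null_statistics_and_exclusion():
    session = dyad_session(["mixed", None])
    result = run_alignment_test(session, ("cg", "ch"), n_iterations=100, seed=0)
    assert result.n_turns == 0
    assert result.p_value is None
    assert not result.included
    assert result.exclusion_reason == ExclusionReason.TOO_FEW_TURNS


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_relabeling_symmetry_of_the_full_test(seed):
    rng = np.random.default_rng(seed)
    langs = [A if rng.random() < 0.6 else B for _ in range(24)]
    session = dyad_session(langs)
    swapped = relabel_languages(session)
    r1 = run_alignment_test(session, ("cg", "ch"), n_iterations=400, seed=seed % 1000)
    r2 = run_alignment_test(swapped, ("cg", "ch"), n_iterations=400, seed=seed % 1000)
    assert r1.observed_rate == r2.observed_rate
    assert r1.p_value == r2.p_value
    assert r1.null_mean == r2.null_mean
    if r1.cohens_h is not None:
        assert abs(r1.cohens_h) == pytest.approx(abs(r2.cohens_h))


@settings(max_examples=20, deadline=None, derandomize=True)
@given(
    st.lists(st.sampled_from([A, B]), min_size=2, max_size=12),
    st.integers(min_value=0, max_value=10_000),
)
def test_replicates_always_preserve_response_multiset(langs, seed):
    prev = list(reversed(langs))
    series = series_from_langs(prev, langs)
    null = permutation_null(series, n_iterations=50, seed=seed)
    n = len(langs)
    n_a_resp = sum(1 for lang in langs if lang == A)
    n_a_prev = sum(1 for lang in prev if lang == A)
    # achievable match counts are fixed by the two marginals: the number of
    # A-A pairings k ranges over the hypergeometric support
    k_min = max(0, n_a_prev + n_a_resp - n)
    k_max = min(n_a_prev, n_a_resp)
    achievable = {
        (2 * k - n_a_prev - n_a_resp + n) / n for k in range(k_min, k_max + 1)
    }
    for rate in null.rates:
        assert any(math.isclose(rate, a) for a in achievable)
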