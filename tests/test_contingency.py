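"""Per-comparison mathematics: exact test, indices, quotients, power."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import fragility as fr


@st.composite
def tables(draw, max_n=20):
    na = draw(st.integers(1, max_n))
    nb = draw(st.integers(1, max_n))
    return fr.FourfoldTable(draw(st.integers(0, na)), na,
                            draw(st.integers(0, nb)), nb)


# ---------------------------------------------------------------- Fisher p

@pytest.mark.parametrize("cells, expected", [
    ((0, 5, 5, 5), 2 / 252),        # exhaustive hypergeometric enumeration
    ((3, 10, 3, 10), 1.0),          # identical arms
    ((5, 10, 5, 10), 1.0),
])
def test_fisher_exact_p_enumerated_values(cells, expected):
    assert fr.fisher_exact_p(fr.FourfoldTable(*cells)) == pytest.approx(
        expected, rel=1e-12)


def test_fisher_p_of_small_hypothetical_trial_rounds_to_0_02():
    p = fr.fisher_exact_p(fr.FourfoldTable(1, 100, 9, 100))
    assert round(p, 2) == 0.02


@settings(deadline=None, derandomize=True, max_examples=60)
@given(tables())
def test_fisher_p_matches_scipy_and_is_symmetric(t):
    """Minimum-likelihood two-sided P agrees with the reference
    implementation and is invariant under arm swap and joint
    event/non-event relabelling."""
    p = fr.fisher_exact_p(t)
    ref = stats.fisher_exact(
        [[t.events_a, t.size_a - t.events_a],
         [t.events_b, t.size_b - t.events_b]]).pvalue
    assert p == pytest.approx(ref, abs=1e-10)
    swapped = fr.FourfoldTable(t.events_b, t.size_b, t.events_a, t.size_a)
    relabel = fr.FourfoldTable(t.size_a - t.events_a, t.size_a,
                               t.size_b - t.events_b, t.size_b)
    assert fr.fisher_exact_p(swapped) == pytest.approx(p, abs=1e-12)
    assert fr.fisher_exact_p(relabel) == pytest.approx(p, abs=1e-12)
    assert 0 < p <= 1


def test_table_invariants_rejected():
    with pytest.raises(fr.ValidationError):
        fr.FourfoldTable(6, 5, 0, 5)
    with pytest.raises(fr.ValidationError):
        fr.FourfoldTable(0, 0, 0, 5)
    with pytest.raises(fr.ValidationError):
        fr.FourfoldTable(-1, 5, 0, 5)


# ---------------------------------------------------------------- S-value

@pytest.mark.parametrize("p, expected", [
    (0.039, 4.68), (1.0, 0.0), (0.003, 8.38), (0.5, 1.0),
])
def test_s_value_examples(p, expected):
    assert round(fr.s_value(p), 2) == expected


@pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
def test_s_value_domain(bad):
    with pytest.raises(fr.ValidationError):
        fr.s_value(bad)


@settings(deadline=None, derandomize=True)
@given(st.floats(1e-150, 1.0), st.floats(1e-150, 1.0))
def test_s_value_additive_and_decreasing(p, q):
    assert fr.s_value(p * q) == pytest.approx(
        fr.s_value(p) + fr.s_value(q), rel=1e-9, abs=1e-9)
    if p < q:
        assert fr.s_value(p) > fr.s_value(q)


# ---------------------------------------------------------------- RR

@pytest.mark.parametrize("cells, expected", [
    ((1, 100, 9, 100), 1 / 9),
    ((200, 4000, 250, 4000), 0.8),
    ((3, 10, 3, 10), 1.0),
])
def test_relative_risk(cells, expected):
    assert fr.relative_risk(fr.FourfoldTable(*cells)) == pytest.approx(
        expected)


def test_relative_risk_undefined_without_control_events():
    with pytest.raises(fr.ValidationError):
        fr.relative_risk(fr.FourfoldTable(3, 10, 0, 10))


# ---------------------------------------------------------------- FI

def test_fragility_index_stepwise_example():
    res = fr.fragility_index(fr.FourfoldTable(0, 5, 5, 5))
    assert res.index == 2
    assert res.quotient == pytest.approx(20.0)
    assert res.p_trajectory == pytest.approx(
        (2 / 252, 12 / 252, 42 / 252))
    assert res.terminal_table == fr.FourfoldTable(2, 5, 5, 5)
    assert not res.saturated
    # collapse structure: all but last below alpha, last at/above
    assert all(p < 0.05 for p in res.p_trajectory[:-1])
    assert res.p_trajectory[-1] >= 0.05


def test_fragility_index_zero_when_baseline_nonsignificant():
    res = fr.fragility_index(fr.FourfoldTable(3, 10, 3, 10))
    assert res.index == 0 and res.quotient == 0.0
    assert res.p_trajectory == (1.0,)


def test_fragility_index_small_trial_is_one():
    assert fr.fragility_index(fr.FourfoldTable(1, 100, 9, 100)).index == 1


def test_fragility_index_preserves_total_n():
    res = fr.fragility_index(fr.FourfoldTable(0, 30, 20, 30))
    assert res.terminal_table.total_n == 60


@settings(deadline=None, derandomize=True, max_examples=40)
@given(tables(max_n=15))
def test_fragility_index_non_decreasing_in_alpha(t):
    """Raising alpha can only lengthen the collapse walk: nonsignificant
    baselines give 0, and a significant walk must push P above a higher
    bar, so the index never shrinks as alpha grows."""
    ks = []
    for alpha in (0.01, 0.05, 0.2):
        res = fr.fragility_index(t, alpha)
        ks.append(math.inf if res.index is None else res.index)
    assert ks[0] <= ks[1] <= ks[2]


def test_fragility_index_grows_with_alpha_on_collapse_example():
    t = fr.FourfoldTable(0, 5, 5, 5)
    assert [fr.fragility_index(t, a).index
            for a in (0.03, 0.05, 0.2)] == [1, 2, 3]


# ---------------------------------------------------------------- RFI

@pytest.mark.parametrize("cells, expected", [
    ((2, 5, 5, 5), 1),      # (1/5 vs 5/5) has P = 12/252 < 0.05
    ((0, 5, 5, 5), 0),      # already significant
    ((5, 10, 5, 10), 5),    # nearest significant table is (0/10 vs 5/10)
])
def test_reverse_fragility_examples(cells, expected):
    assert fr.reverse_fragility_index(
        fr.FourfoldTable(*cells)).index == expected


def test_reverse_fragility_not_attainable_on_tiny_grid():
    res = fr.reverse_fragility_index(fr.FourfoldTable(1, 2, 1, 2))
    assert res.index is None and res.quotient is None
    assert not res.attainable


def test_reverse_fragility_trajectory_crosses_alpha_at_the_end():
    res = fr.reverse_fragility_index(fr.FourfoldTable(5, 10, 5, 10))
    assert all(p >= 0.05 for p in res.p_trajectory[:-1])
    assert res.p_trajectory[-1] < 0.05
    assert len(res.p_trajectory) == res.index + 1


@settings(deadline=None, derandomize=True, max_examples=30)
@given(tables(max_n=12))
def test_greedy_rfi_upper_bounds_exact_rfi(t):
    exact = fr.reverse_fragility_index(t, strategy="exact")
    greedy = fr.reverse_fragility_index(
        t, strategy="greedy-toward-separation")
    if greedy.index is not None:
        assert exact.index is not None
        assert exact.index <= greedy.index


# ---------------------------------------------------------------- quotient

@pytest.mark.parametrize("index, n, expected", [
    (2, 10, 20.0), (0, 50, 0.0), (1, 30, pytest.approx(100 / 30)),
])
def test_fragility_quotient(index, n, expected):
    assert fr.fragility_quotient(index, n) == expected


def test_fragility_quotient_sentinel_and_bounds():
    assert fr.fragility_quotient(None, 10) is None
    with pytest.raises(fr.ValidationError):
        fr.fragility_quotient(1, 1)


@settings(deadline=None, derandomize=True, max_examples=30)
@given(tables(max_n=15))
def test_attained_quotients_lie_in_0_100(t):
    for res in (fr.fragility_index(t), fr.reverse_fragility_index(t)):
        if res.quotient is not None:
            assert 0.0 <= res.quotient <= 100.0


# ---------------------------------------------------------------- power

def test_power_degenerate_rates_is_one():
    assert float(fr.posthoc_power(fr.PowerInput(5, 5, 0.0, 1.0))) == 1.0


def test_power_enumerated_example():
    assert float(fr.posthoc_power(fr.PowerInput(5, 5, 0.1, 0.9))
                 ) == pytest.approx(0.7360989, abs=1e-6)


@pytest.mark.parametrize("n", [5, 10, 20])
def test_power_at_equal_rates_never_exceeds_alpha(n):
    # attained size of an exact test
    assert float(fr.posthoc_power(fr.PowerInput(n, n, 0.5, 0.5))) <= 0.05


@pytest.mark.parametrize("na, nb, ra, rb", [
    (5, 8, 0.2, 0.7), (6, 6, 0.1, 0.4), (4, 9, 0.35, 0.9),
])
def test_power_symmetries(na, nb, ra, rb):
    base = float(fr.posthoc_power(fr.PowerInput(na, nb, ra, rb)))
    swap = float(fr.posthoc_power(fr.PowerInput(nb, na, rb, ra)))
    flip = float(fr.posthoc_power(fr.PowerInput(na, nb, 1 - ra, 1 - rb)))
    assert swap == pytest.approx(base, abs=1e-12)
    assert flip == pytest.approx(base, abs=1e-12)


def test_power_monte_carlo_fallback_is_seeded():
    big = fr.PowerInput(2500, 2500, 0.05, 0.0625)
    r1 = fr.posthoc_power(big, seed=7)
    r2 = fr.posthoc_power(big, seed=7)
    assert r1.method == "monte-carlo"
    assert float(r1) == float(r2)
    assert r1.n_draws == 100_000 and r1.seed == 7


def test_power_input_validation():
    with pytest.raises(fr.ValidationError):
        fr.PowerInput(5, 5, 1.2, 0.5)
    with pytest.raises(fr.ValidationError):
        fr.PowerInput(0, 5, 0.2, 0.5)
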