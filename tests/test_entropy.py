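"""SampEn/ApEn kernel tests: hand-enumerated counts, oracle agreement,
and the exact combinatorial invariants of Chebyshev template matching."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from msentropy import (EntropyParams, SignalSpec, approximate_entropy,
                       brute_force_sample_entropy, embed, generate,
                       sample_entropy, theoretical_sampen_gaussian)
from msentropy.exceptions import (InvalidInputError, OracleSizeExceededError,
                                  SeriesTooShortError)

MICRO = [0.0, 1.0, 0.2, 1.1, 0.15, 3.0]
PERIODIC = [1, 2, 3, 1, 2, 3, 1, 2, 3]


def test_embed_enumerates_all_windows():
    assert embed([1, 2, 3, 4], 2).tolist() == [[1, 2], [2, 3], [3, 4]]
    assert embed([5, 6, 7], 1).tolist() == [[5], [6], [7]]
    with pytest.raises(SeriesTooShortError):
        embed([1, 2], 3)


@pytest.mark.parametrize("fn", [sample_entropy, brute_force_sample_entropy])
def test_hand_enumerated_micro_example(fn):
    # all ordered template pairs enumerated by hand: 8 m-matches, 4 of
    # which extend to (m+1)-matches, so SampEn = -log(4/8) = ln 2
    res = fn(MICRO, EntropyParams(m=1, r_abs=0.25))
    assert (res.a_count, res.b_count) == (4, 8)
    assert res.value == pytest.approx(math.log(2), abs=1e-15)
    assert res.defined


@pytest.mark.parametrize("fn", [sample_entropy, brute_force_sample_entropy])
def test_exactly_periodic_series_has_zero_sampen(fn):
    # every m-match extends: the conditional probability is forced to 1
    res = fn(PERIODIC, EntropyParams(m=1, r_abs=0.5))
    assert res.a_count == res.b_count == 14
    assert res.value == 0.0


def test_apen_self_match_bias_on_periodic_series():
    # independent literal enumeration of Phi^m including self-matches
    def phi(u, m, r):
        nt = len(u) - m + 1
        acc = 0.0
        for i in range(nt):
            c = sum(
                1 for j in range(nt)
                if max(abs(u[i + k] - u[j + k]) for k in range(m)) <= r
            )
            acc += math.log(c / nt)
        return acc / nt

    expected = phi(PERIODIC, 1, 0.5) - phi(PERIODIC, 2, 0.5)
    res = approximate_entropy(PERIODIC, EntropyParams(m=1, r_abs=0.5))
    assert res.value == pytest.approx(expected, abs=1e-12)
    # self-matching pulls ApEn away from the exact 0 that SampEn reports
    # (for this short periodic series the artifact is in fact negative)
    assert res.value != 0.0
    assert sample_entropy(PERIODIC, EntropyParams(m=1, r_abs=0.5)).value == 0.0


def test_apen_of_constant_series_is_zero():
    res = approximate_entropy([3.0] * 30, EntropyParams(m=2, r_abs=0.2))
    assert res.value == 0.0


def test_kernel_matches_oracle_on_random_series(rng):
    for i in range(24):
        x = rng.normal(size=100)
        m = [1, 2, 3][i % 3]
        r = [0.1, 0.15, 0.2, 0.5][i % 4]
        params = EntropyParams(m=m, r_abs=r)
        fast = sample_entropy(x, params)
        slow = brute_force_sample_entropy(x, params)
        assert (fast.a_count, fast.b_count) == (slow.a_count, slow.b_count)


def test_gaussian_sampen_matches_closed_form(gaussian_20k):
    res = sample_entropy(gaussian_20k, EntropyParams(m=2, r_abs=0.15))
    assert res.value == pytest.approx(theoretical_sampen_gaussian(1, 0.15),
                                      abs=0.05)


def test_sampen_is_independent_of_m_for_iid_input(gaussian_20k):
    values = [sample_entropy(gaussian_20k, EntropyParams(m=m, r_abs=0.15)).value
              for m in (1, 2, 3)]
    assert max(values) - min(values) < 0.1


def test_undefined_result_is_flagged_not_raised():
    res = sample_entropy([0.0, 5.0, 0.001, 9.0, 30.0, 31.0],
                         EntropyParams(m=1, r_abs=0.01))
    assert res.b_count > 0 and res.a_count == 0
    assert not res.defined
    assert math.isnan(res.value)


def test_input_validation():
    params = EntropyParams(m=2, r_abs=0.2)
    with pytest.raises(SeriesTooShortError):
        sample_entropy([1.0, 2.0, 3.0], params)
    with pytest.raises(InvalidInputError):
        sample_entropy([1.0, np.nan, 2.0, 3.0, 4.0], params)
    with pytest.raises(SeriesTooShortError):
        approximate_entropy([1.0, 2.0], params)
    with pytest.raises(InvalidInputError):
        EntropyParams(m=0, r_abs=0.2)
    with pytest.raises(InvalidInputError):
        EntropyParams(m=2, r_abs=0.0)


def test_oracle_refuses_quadratic_blowup():
    with pytest.raises(OracleSizeExceededError):
        brute_force_sample_entropy(np.zeros(2001), EntropyParams(m=1, r_abs=0.1))


# integer-valued series scaled to a 0.1 grid keep Chebyshev distances
# well away from the tolerances below, so match counts are fp-stable
grid_series = st.lists(st.integers(-50, 50), min_size=8, max_size=40).map(
    lambda ints: np.asarray(ints, dtype=float) * 0.1)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(x=grid_series, m=st.sampled_from([1, 2]))
def test_counts_monotone_in_r_and_nested(x, m):
    prev_a = prev_b = 0
    for r in (0.15, 0.3, 0.75):
        res = sample_entropy(x, EntropyParams(m=m, r_abs=r))
        # an (m+1)-match implies an m-match
        assert res.a_count <= res.b_count
        # enlarging the tolerance can only add matches
        assert res.a_count >= prev_a and res.b_count >= prev_b
        prev_a, prev_b = res.a_count, res.b_count


@settings(max_examples=60, derandomize=True, deadline=None)
@given(x=grid_series, m=st.sampled_from([1, 2]),
       c=st.sampled_from([0.5, 2.0, 8.0]))
def test_scale_invariance_is_exact_for_power_of_two_factors(x, m, c):
    base = sample_entropy(x, EntropyParams(m=m, r_abs=0.3))
    scaled = sample_entropy(c * x, EntropyParams(m=m, r_abs=c * 0.3))
    assert (scaled.a_count, scaled.b_count) == (base.a_count, base.b_count)
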