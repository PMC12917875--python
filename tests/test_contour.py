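"""Contour enumeration, posterior distribution over contours, trigger, q."""

import itertools
from math import comb

import numpy as np
import pytest
from scipy import stats

from doseinsert import (BetaPosteriorGrid, DegenerateDistributionError,
                        below_target_prob, contour_distribution,
                        enumerate_contours, insertion_triggered,
                        overdose_measure)


def brute_force_monotone(I, J):
    """All binary I x J matrices monotone nondecreasing in both directions."""
    mats = []
    for bits in itertools.product((0, 1), repeat=I * J):
        M = np.array(bits).reshape(I, J)
        if np.all(np.diff(M, axis=0) >= 0) and np.all(np.diff(M, axis=1) >= 0):
            mats.append(M)
    return mats


@pytest.mark.parametrize("I,J,expected", [(3, 3, 20), (1, 1, 2), (2, 3, 10)])
def test_contour_counts(I, J, expected):
    assert len(enumerate_contours(I, J)) == expected
    assert expected == comb(I + J, I)


def test_enumeration_matches_brute_force():
    for I, J in [(1, 1), (2, 2), (2, 3), (3, 3), (3, 4)]:
        cs = enumerate_contours(I, J)
        brute = brute_force_monotone(I, J)
        assert len(cs) == len(brute)
        got = {tuple(m.ravel()) for m in cs}
        want = {tuple(m.ravel()) for m in brute}
        assert got == want


def test_counts_formula_up_to_5x5():
    for I in range(1, 6):
        for J in range(1, 6):
            assert len(enumerate_contours(I, J)) == comb(I + J, I)


def test_canonical_order_and_extremes():
    cs = enumerate_contours(3, 3)
    flat = cs.matrices.reshape(len(cs), -1)
    assert np.array_equal(flat, flat[np.lexsort(flat.T[::-1])])  # lexicographic
    assert not flat[0].any()       # all-zeros first
    assert flat[-1].all()          # all-ones last
    assert len({tuple(f) for f in flat}) == len(cs)


def test_invalid_dimension_rejected():
    with pytest.raises(ValueError):
        enumerate_contours(0, 3)


@pytest.mark.parametrize("n,y,a,b,theta,expected", [
    (0, 0, 1.0, 1.0, 0.3, 0.3),                 # uniform prior CDF
    (12, 0, 1.0, 1.0, 0.3, 1 - 0.7 ** 13),      # Beta(1, 13) closed form
    (3, 3, 1.0, 1.0, 0.3, 0.3 ** 4),            # Beta(4, 1) closed form
])
def test_below_target_prob_closed_forms(n, y, a, b, theta, expected):
    assert below_target_prob(n, y, a, b, theta) == pytest.approx(expected, abs=1e-12)


def test_below_target_prob_rejects_bad_counts():
    with pytest.raises(ValueError):
        below_target_prob(3, 4, 1, 1, 0.3)


def _grid_from_p(p, theta=0.3):
    """BetaPosteriorGrid whose below-target probabilities equal p exactly."""
    # use Beta(1, b) with CDF 1-(1-theta)^b at theta: solve b
    b = np.log1p(-np.asarray(p)) / np.log1p(-theta)
    return BetaPosteriorGrid(a=np.ones_like(b), b=np.maximum(b, 1e-12), theta=theta)


def brute_force_distribution(p, contours):
    w = []
    for C in contours:
        prod = 1.0
        for i in range(p.shape[0]):
            for j in range(p.shape[1]):
                prod *= (1 - p[i, j]) if C[i, j] else p[i, j]
        w.append(prod)
    w = np.array(w)
    return w / w.sum()


def test_distribution_matches_brute_force_oracle():
    rng = np.random.default_rng(42)
    contours = enumerate_contours(3, 3)
    for _ in range(20):
        p = rng.uniform(0.01, 0.99, (3, 3))
        est = contour_distribution(_grid_from_p(p), contours, p=p)
        oracle = brute_force_distribution(p, contours)
        np.testing.assert_allclose(est.full_distribution, oracle, atol=1e-12)
        assert est.full_distribution.sum() == pytest.approx(1.0, abs=1e-9)
        assert est.probability == est.full_distribution.max()


def test_uniform_p_gives_uniform_distribution():
    p = np.full((3, 3), 0.5)
    est = contour_distribution(_grid_from_p(p), p=p)
    np.testing.assert_allclose(est.full_distribution, np.full(20, 0.05), atol=1e-12)


def test_argmax_contour_for_clear_partition():
    p = np.array([[0.99, 0.99, 0.01], [0.99, 0.01, 0.01], [0.01, 0.01, 0.01]])
    est = contour_distribution(_grid_from_p(p), p=p)
    expected = np.array([[0, 0, 1], [0, 1, 1], [1, 1, 1]])
    np.testing.assert_array_equal(est.contour, expected)


def test_transpose_invariance():
    rng = np.random.default_rng(7)
    p = rng.uniform(0.05, 0.95, (2, 3))
    est = contour_distribution(_grid_from_p(p), p=p)
    est_t = contour_distribution(_grid_from_p(p.T), p=p.T)
    # distributions agree after matching transposed contours
    cs = enumerate_contours(2, 3)
    cs_t = enumerate_contours(3, 2)
    lookup = {tuple(m.ravel()): k for k, m in enumerate(cs_t.matrices)}
    for s, C in enumerate(cs.matrices):
        k = lookup[tuple(C.T.ravel())]
        assert est.full_distribution[s] == pytest.approx(est_t.full_distribution[k],
                                                         abs=1e-12)


def test_complement_symmetry_at_half():
    """p -> 1-p with contours flipped and reversed leaves the law invariant."""
    rng = np.random.default_rng(3)
    p = rng.uniform(0.05, 0.95, (3, 3))
    cs = enumerate_contours(3, 3)
    p2 = (1 - p)[::-1, ::-1]
    d1 = contour_distribution(_grid_from_p(p, 0.5), cs, p=p)
    d2 = contour_distribution(_grid_from_p(p2, 0.5), cs, p=p2)
    lookup = {tuple(m.ravel()): k for k, m in enumerate(cs.matrices)}
    for s, C in enumerate(cs.matrices):
        flipped = (1 - C)[::-1, ::-1]
        k = lookup[tuple(flipped.ravel())]
        assert d1.full_distribution[s] == pytest.approx(d2.full_distribution[k],
                                                        abs=1e-12)


def test_degenerate_distribution_raises():
    # (0,0) certainly above but (1,1) certainly below: no monotone contour
    # is compatible, so every weight vanishes
    p = np.array([[0.0, 0.5], [0.5, 1.0]])
    grid = BetaPosteriorGrid(a=np.ones((2, 2)), b=np.ones((2, 2)), theta=0.3)
    with pytest.raises(DegenerateDistributionError):
        contour_distribution(grid, p=p)


@pytest.mark.parametrize("prob,lam,expected", [
    (0.68, 0.6, True),
    (0.09, 0.6, False),
    (1.0, 1.0, False),  # strict inequality: lambda = 1 turns insertions off
])
def test_insertion_trigger_boundaries(prob, lam, expected):
    est = contour_distribution(_grid_from_p(np.full((2, 2), 0.5)))
    est.probability = prob
    assert insertion_triggered(est, lam) is expected


def test_overdose_measure_uniform_and_concentrated():
    cs = enumerate_contours(3, 3)
    est = contour_distribution(_grid_from_p(np.full((3, 3), 0.5)))
    q = overdose_measure(est, cs)
    # brute-force count: only the all-ones contour has the lowest combination
    # above it (monotonicity forces the whole grid up), so q_11 = 1/20
    n_lowest = sum(C[0, 0] for C in cs.matrices)
    n_highest = sum(C[-1, -1] for C in cs.matrices)
    assert q[0, 0] == pytest.approx(n_lowest / 20) and n_lowest == 1
    assert q[-1, -1] == pytest.approx(n_highest / 20) and n_highest == 19
    # concentrate on the all-ones contour
    est.full_distribution = np.zeros(20)
    est.full_distribution[int(np.argmax([C.all() for C in cs.matrices]))] = 1.0
    np.testing.assert_allclose(overdose_measure(est, cs), np.ones((3, 3)))


def test_overdose_measure_monotone():
    rng = np.random.default_rng(11)
    cs = enumerate_contours(3, 3)
    for _ in range(10):
        p = rng.uniform(0.05, 0.95, (3, 3))
        q = overdose_measure(contour_distribution(_grid_from_p(p), cs, p=p), cs)
        assert np.all(np.diff(q, axis=0) >= -1e-12)
        assert np.all(np.diff(q, axis=1) >= -1e-12)
        assert q[0, 0] <= q.min() + 1e-12 and q[-1, -1] >= q.max() - 1e-12
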