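"""NODF, Barber modularity, module detection, and the degree sort."""

import numpy as np
import pytest

from ehvnet import (
    InfectionMatrix,
    ValidationError,
    brute_force_modules,
    degree_sort,
    detect_modules,
    nodf,
    qb,
)
from ehvnet.network import ModulePartition


def nodf_oracle(a):
    """Literal pair-by-pair NODF enumeration, independent of the fast path."""
    a = np.asarray(a)
    n, m = a.shape
    total = 0.0
    for axis_matrix in (a, a.T):
        rows = [set(np.flatnonzero(r)) for r in axis_matrix]
        for i in range(len(rows)):
            for j in range(len(rows)):
                if i == j:
                    continue
                ki, kj = len(rows[i]), len(rows[j])
                if ki > kj > 0:
                    total += len(rows[i] & rows[j]) / kj
    return total / (n * (n - 1) / 2 + m * (m - 1) / 2)


def staircase(n):
    return np.tril(np.ones((n, n), dtype=int))


def test_staircase_is_perfectly_nested():
    assert nodf(staircase(13)).value == pytest.approx(1.0)


def test_equal_rows_score_zero():
    """All marginals tie, so strict decreasing fill zeroes every pair."""
    a = np.tile([1, 0, 1, 0], (4, 1))
    assert nodf(a).value == 0.0


def test_nodf_matches_oracle_on_random_matrices():
    rng = np.random.default_rng(8)
    for _ in range(100):
        shape = rng.integers(2, 6, size=2)
        a = (rng.random(shape) < rng.uniform(0.2, 0.8)).astype(int)
        assert nodf(a).value == pytest.approx(nodf_oracle(a), abs=1e-12)


def test_nodf_transpose_symmetry():
    rng = np.random.default_rng(9)
    for _ in range(20):
        a = (rng.random((5, 7)) < 0.4).astype(int)
        assert nodf(a).value == pytest.approx(nodf(a.T).value, abs=1e-12)


def test_nodf_invariant_under_permutation():
    rng = np.random.default_rng(10)
    a = (rng.random((6, 8)) < 0.4).astype(int)
    base = nodf(a).value
    for _ in range(10):
        p = rng.permutation(6)
        q = rng.permutation(8)
        assert nodf(a[np.ix_(p, q)]).value == pytest.approx(base, abs=1e-12)


def test_nodf_percent_scale():
    a = staircase(5)
    assert nodf(a, scale="percent").value == pytest.approx(100.0)


def test_nodf_rejects_degenerate():
    with pytest.raises(ValidationError):
        nodf(np.ones((1, 5), dtype=int))
    with pytest.raises(ValidationError):
        nodf(np.array([[0, 2], [1, 0]]))


def two_block(k):
    a = np.zeros((2 * k, 2 * k), dtype=int)
    a[:k, :k] = 1
    a[k:, k:] = 1
    return a


def test_qb_single_module_is_zero():
    rng = np.random.default_rng(11)
    for _ in range(10):
        a = (rng.random((5, 6)) < 0.5).astype(int)
        if a.sum() == 0:
            continue
        part = ModulePartition(np.zeros(5, int), np.zeros(6, int), 1, 0.0)
        assert qb(a, part).value == pytest.approx(0.0, abs=1e-12)


def test_qb_perfect_two_block_hand_value():
    """4x4 equal diagonal blocks: Qb = (8 - 4)/8 = 1/2 by direct formula."""
    a = two_block(2)
    part = ModulePartition(np.array([0, 0, 1, 1]), np.array([0, 0, 1, 1]), 2, 0.5)
    assert qb(a, part).value == pytest.approx(0.5, abs=1e-12)


def test_qb_matches_brute_formula_on_random_partitions():
    rng = np.random.default_rng(12)
    for _ in range(20):
        a = (rng.random((4, 5)) < 0.5).astype(int)
        m = a.sum()
        if m == 0:
            continue
        g = rng.integers(0, 3, 4)
        h = rng.integers(0, 3, 5)
        labels = np.unique(np.concatenate([g, h]))
        remap = {l: i for i, l in enumerate(labels)}
        g = np.array([remap[x] for x in g])
        h = np.array([remap[x] for x in h])
        # independent literal evaluation of the Barber sum
        k, d = a.sum(1), a.sum(0)
        expected = sum(
            (a[i, j] - k[i] * d[j] / m)
            for i in range(4) for j in range(5) if g[i] == h[j]
        ) / m
        part = ModulePartition(g, h, len(labels), float(expected))
        assert qb(a, part).value == pytest.approx(expected, abs=1e-12)


def test_detect_recovers_planted_blocks():
    a = two_block(3)
    part = detect_modules(a)
    assert part.n_modules == 2
    assert len(set(part.row_assignments[:3])) == 1
    assert len(set(part.row_assignments[3:])) == 1
    assert part.row_assignments[0] != part.row_assignments[3]
    assert (part.row_assignments[:3] == part.column_assignments[:3]).all()
    assert part.qb == pytest.approx(0.5, abs=1e-12)


def test_detect_all_ones_single_module():
    part = detect_modules(np.ones((4, 4), dtype=int))
    assert part.n_modules == 1
    assert part.qb == pytest.approx(0.0, abs=1e-12)


def test_detect_never_negative():
    rng = np.random.default_rng(13)
    for _ in range(20):
        a = (rng.random((6, 6)) < 0.5).astype(int)
        if a.sum() == 0:
            continue
        assert detect_modules(a).qb >= -1e-12


def test_brute_force_identity_matrix():
    a = np.eye(2, dtype=int)
    part = brute_force_modules(a)
    assert part.n_modules == 2
    assert part.qb == pytest.approx(0.5)
    assert part.row_assignments[0] == part.column_assignments[0]
    assert part.row_assignments[1] == part.column_assignments[1]


def test_brute_force_single_module_forced():
    a = (np.random.default_rng(1).random((3, 3)) < 0.6).astype(int)
    part = brute_force_modules(a, max_modules=1)
    assert part.n_modules == 1
    assert part.qb == pytest.approx(0.0, abs=1e-12)


def test_brute_force_size_guard():
    with pytest.raises(ValidationError):
        brute_force_modules(np.ones((7, 7), dtype=int))


def test_detect_close_to_brute_force_on_small_corpus():
    rng = np.random.default_rng(14)
    for trial in range(40):
        shape = [(5, 5), (4, 4), (6, 6), (4, 8), (3, 7)][trial % 5]
        a = (rng.random(shape) < 0.4).astype(int)
        if a.sum() == 0:
            continue
        det = detect_modules(a)
        opt = brute_force_modules(a)
        assert opt.qb >= det.qb - 1e-9
        if opt.qb > 1e-12:
            assert det.qb >= 0.95 * opt.qb


def test_degree_sort():
    m = InfectionMatrix(
        ("h1", "h2", "h3"), ("v1", "v2"),
        np.array([[0, 1], [1, 1], [0, 0]]),
    )
    s = degree_sort(m)
    assert s.hosts == ("h2", "h1", "h3")
    already = degree_sort(s)
    assert already == s


def test_degree_sort_preserves_nodf():
    rng = np.random.default_rng(15)
    for _ in range(100):
        vals = (rng.random((5, 6)) < 0.4).astype(int)
        m = InfectionMatrix(
            tuple(f"h{i}" for i in range(5)),
            tuple(f"v{j}" for j in range(6)),
            vals,
        )
        assert nodf(degree_sort(m)).value == pytest.approx(
            nodf(m).value, abs=1e-12
        )
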