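"""Structure statistics of the binary infection matrix.

Two classic bipartite-network metrics:

* **NODF nestedness** — paired overlap with strict decreasing fill.  For an
  ordered row pair (i, j) with marginal sums k_i > k_j > 0 the paired term is
  |shared 1-columns| / k_j; pairs with k_i <= k_j or k_j = 0 contribute
  nothing.  The same rule applies to column pairs, and the total is divided
  by n(n-1)/2 + m(m-1)/2 so a perfectly nested matrix with distinct
  marginals scores 1.  Reported on a 0-1 scale by default (0-100 optional).

* **Barber bipartite modularity Qb** — for a partition assigning every host
  and virus to a module,

      Qb = (1/m) * sum_ij (A_ij - k_i d_j / m) * [g_i == h_j]

  with k_i row sums, d_j column sums and m the total number of interactions.
  Modules are found with a leading-eigenvector-style detector: recursive
  spectral bipartitioning on the dominant singular vectors of the modularity
  matrix B = A - k d^T / m, followed by a greedy single-node refinement pass.
  A small exhaustive-search oracle (`brute_force_modules`) gives the global
  optimum for matrices with at most 12 total nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .data import InfectionMatrix, ValidationError


@dataclass(frozen=True)
class StructureScore:
    """A single structure metric value with its matrix context."""

    metric: str
    value: float
    matrix_shape: tuple[int, int]
    fill: int


@dataclass(frozen=True)
class ModulePartition:
    """Joint module assignment of rows (hosts) and columns (viruses)."""

    row_assignments: np.ndarray = field(repr=False)
    column_assignments: np.ndarray = field(repr=False)
    n_modules: int
    qb: float

    def __post_init__(self) -> None:
        rows = np.asarray(self.row_assignments, dtype=int)
        cols = np.asarray(self.column_assignments, dtype=int)
        labels = np.concatenate([rows, cols])
        if labels.size and (
            labels.min() < 0
            or labels.max() >= self.n_modules
            or len(np.unique(labels)) != self.n_modules
        ):
            raise ValidationError("module indices must be contiguous from 0")
        object.__setattr__(self, "row_assignments", rows)
        object.__setattr__(self, "column_assignments", cols)


def _binary_values(matrix: InfectionMatrix | np.ndarray) -> np.ndarray:
    if isinstance(matrix, InfectionMatrix):
        return matrix.values.astype(float)
    arr = np.asarray(matrix, dtype=float)
    if not np.isin(arr, (0, 1)).all():
        raise ValidationError("matrix entries must be 0/1")
    return arr


def _nodf_axis_sum(a: np.ndarray) -> float:
    """Sum of paired-overlap terms over ordered row pairs of ``a``."""
    k = a.sum(axis=1)
    shared = a @ a.T
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(k > 0, shared / np.where(k > 0, k, 1), 0.0)
    # term (i, j) counts only when k_i > k_j > 0 (strict decreasing fill)
    decreasing = (k[:, None] > k[None, :]) & (k[None, :] > 0)
    return float(frac[decreasing.nonzero()].sum())


def nodf(matrix: InfectionMatrix | np.ndarray, scale: str = "unit") -> StructureScore:
    """NODF nestedness of a binary matrix.

    scale="unit" reports on 0-1 (1 = perfectly nested); scale="percent"
    multiplies by 100 as in the older nestedness literature.
    """
    a = _binary_values(matrix)
    n, m = a.shape
    if n < 2 or m < 2:
        raise ValidationError(
            f"NODF needs at least 2 rows and 2 columns, got {a.shape}"
        )
    total = _nodf_axis_sum(a) + _nodf_axis_sum(a.T)
    denom = n * (n - 1) / 2 + m * (m - 1) / 2
    value = total / denom
    if scale == "percent":
        value *= 100.0
    elif scale != "unit":
        raise ValueError(f"unknown scale {scale!r}")
    return StructureScore("NODF", value, (n, m), int(a.sum()))


def _barber_matrix(a: np.ndarray) -> tuple[np.ndarray, float]:
    m = a.sum()
    if m < 1:
        raise ValidationError("modularity undefined for an empty matrix")
    k = a.sum(axis=1)
    d = a.sum(axis=0)
    return a - np.outer(k, d) / m, float(m)


def _qb_value(b: np.ndarray, m: float, rows: np.ndarray, cols: np.ndarray) -> float:
    """Qb of assignment vectors against a precomputed modularity matrix."""
    return float((b * (rows[:, None] == cols[None, :])).sum() / m)


def qb(matrix: InfectionMatrix | np.ndarray, partition: ModulePartition) -> StructureScore:
    """Barber bipartite modularity of a given partition."""
    a = _binary_values(matrix)
    n, m_cols = a.shape
    if partition.row_assignments.size != n or partition.column_assignments.size != m_cols:
        raise ValidationError(
            f"partition sizes {partition.row_assignments.size}x"
            f"{partition.column_assignments.size} do not match matrix {a.shape}"
        )
    b, m = _barber_matrix(a)
    value = _qb_value(b, m, partition.row_assignments, partition.column_assignments)
    return StructureScore("Qb", value, a.shape, int(a.sum()))


_TOL = 1e-12


def _dominant_singular(sub: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    u, s, vt = np.linalg.svd(sub, full_matrices=False)
    u1, v1 = u[:, 0], vt[0, :]
    # fix the sign so the split is deterministic across BLAS builds
    pivot = np.concatenate([u1, v1])
    idx = int(np.argmax(np.abs(pivot)))
    if pivot[idx] < 0:
        u1, v1 = -u1, -v1
    return u1, v1


def _spectral_division(b: np.ndarray, m: float) -> tuple[np.ndarray, np.ndarray]:
    """Recursive sign-split on dominant singular vectors of restricted B."""
    n, mc = b.shape
    rows = np.zeros(n, dtype=int)
    cols = np.zeros(mc, dtype=int)
    current_q = 0.0

    def try_split(module: int) -> list[int]:
        nonlocal rows, cols, current_q
        r_idx = np.flatnonzero(rows == module)
        c_idx = np.flatnonzero(cols == module)
        if r_idx.size == 0 or c_idx.size == 0:
            return []
        sub = b[np.ix_(r_idx, c_idx)]
        if not np.any(sub):
            return []
        u1, v1 = _dominant_singular(sub)
        r_side = u1 >= 0
        c_side = v1 >= 0
        if (r_side.all() and c_side.all()) or ((~r_side).all() and (~c_side).all()):
            return []
        new_label = int(max(rows.max(), cols.max()) + 1)
        cand_rows = rows.copy()
        cand_cols = cols.copy()
        cand_rows[r_idx[~r_side]] = new_label
        cand_cols[c_idx[~c_side]] = new_label
        cand_q = _qb_value(b, m, cand_rows, cand_cols)
        if cand_q > current_q + _TOL:
            rows, cols, current_q = cand_rows, cand_cols, cand_q
            return [module, new_label]
        return []

    stack = [0]
    while stack:
        module = stack.pop()
        stack.extend(try_split(module))
    return rows, cols


def _alternating_update(
    b: np.ndarray, m: float, rows: np.ndarray, cols: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """BRIM-style alternating label updates until Qb stops improving.

    Given one side's labels, the optimal label for every node on the other
    side is the module maximising its summed modularity contribution (an
    empty module, contribution 0, is always available).  Monotone in Qb.
    """
    n_labels = max(rows.max(), cols.max()) + 2  # keep one spare empty module
    q = _qb_value(b, m, rows, cols)
    while True:
        col_onehot = np.zeros((cols.size, n_labels))
        col_onehot[np.arange(cols.size), cols] = 1.0
        row_scores = b @ col_onehot  # n x labels
        new_rows = np.argmax(row_scores, axis=1)
        # a node whose best module is negative is better off alone
        new_rows[row_scores.max(axis=1) < 0] = n_labels - 1
        row_onehot = np.zeros((new_rows.size, n_labels))
        row_onehot[np.arange(new_rows.size), new_rows] = 1.0
        col_scores = b.T @ row_onehot
        new_cols = np.argmax(col_scores, axis=1)
        new_cols[col_scores.max(axis=1) < 0] = n_labels - 1
        q_new = _qb_value(b, m, new_rows, new_cols)
        if q_new <= q + _TOL:
            return rows, cols, q
        rows, cols, q = new_rows, new_cols, q_new
        n_labels = max(rows.max(), cols.max()) + 2


def _greedy_refine(
    b: np.ndarray, m: float, rows: np.ndarray, cols: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Single-node reassignment pass: rows then columns, fixed label order.

    Candidate targets are every occupied module plus one fresh module; a
    move is kept only when Qb strictly improves.
    """
    rows, cols = rows.copy(), cols.copy()
    current_q = _qb_value(b, m, rows, cols)
    improved = True
    while improved:
        improved = False
        fresh = int(max(rows.max(), cols.max()) + 1)
        labels = list(np.unique(np.concatenate([rows, cols]))) + [fresh]
        for i in range(rows.size):
            best_q, best_l = current_q, rows[i]
            for lab in labels:
                if lab == rows[i]:
                    continue
                cand = rows.copy()
                cand[i] = lab
                q_new = _qb_value(b, m, cand, cols)
                if q_new > best_q + _TOL:
                    best_q, best_l = q_new, lab
            if best_l != rows[i]:
                rows[i] = best_l
                current_q = best_q
                improved = True
        for j in range(cols.size):
            best_q, best_l = current_q, cols[j]
            for lab in labels:
                if lab == cols[j]:
                    continue
                cand = cols.copy()
                cand[j] = lab
                q_new = _qb_value(b, m, rows, cand)
                if q_new > best_q + _TOL:
                    best_q, best_l = q_new, lab
            if best_l != cols[j]:
                cols[j] = best_l
                current_q = best_q
                improved = True
    return rows, cols, current_q


_N_RESTARTS = 12


def detect_modules(
    matrix: InfectionMatrix | np.ndarray, rng: np.random.Generator | None = None
) -> ModulePartition:
    """Leading-eigenvector module detection with local refinement.

    The primary initialisation recursively bipartitions modules by the sign
    pattern of the dominant singular vectors of the Barber modularity matrix
    restricted to them, accepting a split only when Qb strictly increases.
    Each candidate partition (the spectral one plus a small set of seeded
    random restarts) is polished by alternating label updates and a greedy
    single-row/column reassignment pass; the best partition found is
    returned.  Deterministic for a fixed ``rng`` seed (default seed 0); the
    trivial one-module partition (Qb = 0) is the floor, so the result never
    has negative modularity.
    """
    a = _binary_values(matrix)
    n, mc = a.shape
    b, m = _barber_matrix(a)
    if rng is None:
        rng = np.random.default_rng(0)

    candidates = [_spectral_division(b, m)]
    q_max = max(1, min(n, mc))
    for _ in range(_N_RESTARTS):
        candidates.append(
            (rng.integers(0, q_max, size=n), rng.integers(0, q_max, size=mc))
        )

    best_q = 0.0
    best_rows = np.zeros(n, dtype=int)
    best_cols = np.zeros(mc, dtype=int)
    for rows0, cols0 in candidates:
        rows1, cols1, _ = _alternating_update(
            b, m, np.asarray(rows0, dtype=int), np.asarray(cols0, dtype=int)
        )
        rows2, cols2, q2 = _greedy_refine(b, m, rows1, cols1)
        if q2 > best_q + _TOL:
            best_q, best_rows, best_cols = q2, rows2, cols2

    rows, cols, n_mod = _relabel(best_rows, best_cols)
    return ModulePartition(rows, cols, n_mod, float(best_q))


def _relabel(rows: np.ndarray, cols: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Map labels to contiguous 0..q-1 in order of first appearance."""
    joint = np.concatenate([rows, cols])
    mapping: dict[int, int] = {}
    for lab in joint:
        if lab not in mapping:
            mapping[lab] = len(mapping)
    rows = np.array([mapping[l] for l in rows], dtype=int)
    cols = np.array([mapping[l] for l in cols], dtype=int)
    return rows, cols, len(mapping)


def _restricted_growth_strings(n: int, max_blocks: int) -> Iterator[np.ndarray]:
    """All set partitions of n items into at most max_blocks blocks.

    Yielded as canonical (restricted-growth) label vectors in lexicographic
    order, which makes the brute-force tie-break deterministic.
    """
    labels = np.zeros(n, dtype=int)

    def rec(pos: int, n_used: int) -> Iterator[np.ndarray]:
        if pos == n:
            yield labels.copy()
            return
        top = min(n_used + 1, max_blocks)
        for lab in range(top):
            labels[pos] = lab
            yield from rec(pos + 1, max(n_used, lab + 1))

    yield from rec(0, 0)


def brute_force_modules(
    matrix: InfectionMatrix | np.ndarray, max_modules: int | None = None
) -> ModulePartition:
    """Globally optimal Qb by exhaustive search (test oracle, <= 12 nodes).

    Exact factorisation of the search: Qb separates over rows once the
    column labels are fixed, so it suffices to enumerate set partitions of
    one side (the smaller one) and give every node on the other side its
    best module.  Modules containing only one side contribute zero, so a
    single shared spare module (when the module budget allows) covers every
    node whose best same-module contribution is negative; restricting to at
    most min(n_rows, n_cols) + 1 modules therefore still reaches the global
    optimum.  Deterministic: the first optimum in enumeration order wins and
    ties on the free side go to the lowest label.
    """
    a = _binary_values(matrix)
    n, mc = a.shape
    if n + mc > 12:
        raise ValidationError(
            f"exhaustive search limited to 12 total nodes, got {n + mc}"
        )
    if max_modules is None:
        max_modules = min(n, mc) + 1
    if max_modules < 1:
        raise ValueError("max_modules must be >= 1")
    b, m = _barber_matrix(a)

    transposed = mc > n
    bb = b.T if transposed else b  # enumerate over the second axis of bb
    n_free, n_enum = bb.shape

    best_q = -np.inf
    best_enum: np.ndarray | None = None
    best_free: np.ndarray | None = None
    for labels in _restricted_growth_strings(n_enum, max_modules):
        q_used = int(labels.max()) + 1
        onehot = np.zeros((n_enum, q_used))
        onehot[np.arange(n_enum), labels] = 1.0
        scores = bb @ onehot  # free-side node x module contribution
        free = np.argmax(scores, axis=1)
        top = scores[np.arange(n_free), free]
        if q_used < max_modules:
            # spare empty module for nodes better off alone
            free = np.where(top < 0, q_used, free)
            top = np.maximum(top, 0.0)
        q = float(top.sum() / m)
        if q > best_q + _TOL:
            best_q, best_enum, best_free = q, labels, free
    assert best_enum is not None and best_free is not None
    if transposed:
        rows_raw, cols_raw = best_enum, best_free
    else:
        rows_raw, cols_raw = best_free, best_enum
    rows, cols, n_mod = _relabel(rows_raw, cols_raw)
    return ModulePartition(rows, cols, n_mod, float(best_q))


def degree_sort(matrix: InfectionMatrix) -> InfectionMatrix:
    """Reorder rows and columns by decreasing marginal sums (ties by label).

    Pure relabelling/permutation: NODF is unchanged, since paired terms are
    defined by marginal comparison, not by position.
    """
    a = matrix.values
    row_order = sorted(
        range(len(matrix.hosts)), key=lambda i: (-int(a[i].sum()), matrix.hosts[i])
    )
    col_order = sorted(
        range(len(matrix.viruses)),
        key=lambda j: (-int(a[:, j].sum()), matrix.viruses[j]),
    )
    return InfectionMatrix(
        tuple(matrix.hosts[i] for i in row_order),
        tuple(matrix.viruses[j] for j in col_order),
        a[np.ix_(row_order, col_order)],
    )
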