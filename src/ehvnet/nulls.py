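"""Equiprobable null-matrix ensemble and permutation significance.

The equiprobable null keeps only the number of interactions (the fill) and
scatters them uniformly over the cells of the matrix; marginal sums are not
preserved.  Significance of an observed NODF or Qb is the one-tailed
empirical p against an ensemble of such nulls (default 100), with the
(r + 1)/(n + 1) correction so p is never exactly zero, plus a z-score
against the null mean and sd.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .data import InfectionMatrix
from .network import detect_modules, nodf

DEFAULT_N_NULL = 100


@dataclass(frozen=True)
class NullEnsembleResult:
    """Observed metric vs an equiprobable null ensemble."""

    metric: str
    observed: float
    null_values: np.ndarray = field(repr=False)
    null_mean: float
    null_sd: float
    z: float  # NaN when the null ensemble is degenerate (sd = 0)
    p_empirical: float
    n_null: int
    seed: int | None
    tail: str = "greater"

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "observed": self.observed,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "z": None if np.isnan(self.z) else self.z,
            "p_empirical": self.p_empirical,
            "n_null": self.n_null,
            "seed": self.seed,
            "tail": self.tail,
            "null_values": [float(v) for v in self.null_values],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)
            fh.write("\n")


def equiprobable_null(
    matrix: InfectionMatrix, rng: np.random.Generator
) -> InfectionMatrix:
    """Same shape and fill, 1s placed uniformly at random over all cells."""
    n, m = matrix.shape
    flat = np.zeros(n * m, dtype=np.int8)
    idx = rng.choice(n * m, size=matrix.fill, replace=False)
    flat[idx] = 1
    return InfectionMatrix(matrix.hosts, matrix.viruses, flat.reshape(n, m))


def _metric_fn(metric: str) -> Callable[[InfectionMatrix, np.random.Generator], float]:
    name = metric.lower()
    if name == "nodf":
        return lambda mat, rng: nodf(mat).value
    if name == "qb":
        return lambda mat, rng: detect_modules(mat, rng).qb
    raise ValueError(f"unknown metric {metric!r} (expected 'NODF' or 'Qb')")


def significance(
    matrix: InfectionMatrix,
    metric: str = "NODF",
    n_null: int = DEFAULT_N_NULL,
    seed: int | None = None,
    tail: str = "greater",
) -> NullEnsembleResult:
    """Empirical significance of NODF or Qb against equiprobable nulls.

    Per-null randomness (null placement and, for Qb, module detection) uses
    child seeds spawned from ``seed`` via a counter, so a fixed seed gives a
    bit-identical null_values vector.
    """
    if n_null < 1:
        raise ValueError(f"n_null must be >= 1, got {n_null}")
    if tail not in ("greater", "two-sided"):
        raise ValueError(f"unknown tail {tail!r}")
    fn = _metric_fn(metric)
    master = np.random.SeedSequence(seed)
    observed = fn(matrix, np.random.default_rng(master.spawn(1)[0]))
    nulls = np.empty(n_null)
    for i in range(n_null):
        child = np.random.default_rng(
            np.random.SeedSequence(entropy=master.entropy, spawn_key=(1, i))
        )
        null_mat = equiprobable_null(matrix, child)
        nulls[i] = fn(null_mat, child)
    null_mean = float(nulls.mean())
    null_sd = float(nulls.std(ddof=1)) if n_null > 1 else 0.0
    z = (observed - null_mean) / null_sd if null_sd > 0 else float("nan")
    r_ge = int((nulls >= observed).sum())
    p = (r_ge + 1) / (n_null + 1)
    if tail == "two-sided":
        r_le = int((nulls <= observed).sum())
        p = min(1.0, 2.0 * min(p, (r_le + 1) / (n_null + 1)))
    return NullEnsembleResult(
        metric=metric,
        observed=float(observed),
        null_values=nulls,
        null_mean=null_mean,
        null_sd=null_sd,
        z=float(z),
        p_empirical=float(p),
        n_null=n_null,
        seed=seed,
        tail=tail,
    )
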