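"""Statistical screens: Pearson correlation and one-way ANOVA.

Both tests are computed from the defining formulas (scipy is used only for
the t and F distribution tail areas), so independent library implementations
can serve as cross-checks.  The screen battery encodes the standard set of
phenotype comparisons — resistance vs growth, viral production vs resistance
and growth, generalist vs specialist production, and the pre/post-2009
"domestication" grouping — as a declarative list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _dist

from .data import StrainMetadata
from .phenotypes import PhenotypeTable, split_generalists_specialists

DEFAULT_YEAR_CUTOFF = 2009


@dataclass(frozen=True)
class TestResult:
    """Outcome of one screen: statistic (r or F), df, two-sided p, n."""

    statistic: float
    df: tuple[int, ...]
    p: float
    n: int
    test: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 or np.isnan(self.p)):
            raise ValueError(f"p-value {self.p} outside [0, 1]")


def pearson(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Sample Pearson correlation with the two-sided t-transform p-value.

    t = r * sqrt((n - 2) / (1 - r^2)) with n - 2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 paired observations, got {n}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite value in input")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = float(np.sqrt((xc * xc).sum()))
    sy = float(np.sqrt((yc * yc).sum()))
    if sx == 0.0 or sy == 0.0:
        raise ValueError("correlation undefined for a constant vector")
    r = float((xc * yc).sum() / (sx * sy))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * _dist.t.sf(abs(t), n - 2))
    return TestResult(statistic=r, df=(n - 2,), p=p, n=n, test="pearson")


def one_way_anova(groups: Sequence[Sequence[float]]) -> TestResult:
    """One-way fixed-effects ANOVA: F = MS_between / MS_within.

    Degrees of freedom (k - 1, n - k); p from the F distribution.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrays)
    if k < 2:
        raise ValueError(f"need at least 2 groups, got {k}")
    for i, g in enumerate(arrays):
        if g.size < 2:
            raise ValueError(f"group {i} has fewer than 2 values")
        if not np.isfinite(g).all():
            raise ValueError(f"non-finite value in group {i}")
    n = sum(g.size for g in arrays)
    grand = sum(g.sum() for g in arrays) / n
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in arrays)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in arrays)
    df_b, df_w = k - 1, n - k
    ms_between = ss_between / df_b
    ms_within = ss_within / df_w
    if ms_within == 0.0:
        if ms_between == 0.0:
            raise ValueError("all observations identical; F undefined")
        f, p = float("inf"), 0.0
    else:
        f = float(ms_between / ms_within)
        p = float(_dist.f.sf(f, df_b, df_w))
    return TestResult(statistic=f, df=(df_b, df_w), p=p, n=n, test="anova")


def split_by_year(
    metadata: StrainMetadata,
    cutoff_year: int = DEFAULT_YEAR_CUTOFF,
    role: str = "host",
) -> tuple[list[str], list[str], list[str]]:
    """Partition strains into (older, younger, unknown-year) by isolation year.

    ``older``: isolation_year < cutoff; ``younger``: >= cutoff (the boundary
    year counts as younger).  Strains without a year are excluded and
    returned separately; empty partitions trigger a warning.
    """
    sub = metadata.table[metadata.table["role"] == role]
    years = pd.to_numeric(sub["isolation_year"], errors="coerce")
    older = sub.loc[years < cutoff_year, "strain_id"].tolist()
    younger = sub.loc[years >= cutoff_year, "strain_id"].tolist()
    unknown = sub.loc[years.isna(), "strain_id"].tolist()
    if not older or not younger:
        warnings.warn(
            f"empty year partition at cutoff {cutoff_year} "
            f"(older={len(older)}, younger={len(younger)})",
            stacklevel=2,
        )
    return older, younger, unknown


#: the standard screen battery: (name, kind, host-table x column, y column)
STANDARD_SCREEN = [
    ("R1 ~ mu", "pearson", "mu", "r1"),
    ("R2 ~ mu", "pearson", "mu", "r2"),
    ("Vp ~ mu", "pearson", "mu", "avg_vp_host"),
    ("Vp ~ R1", "pearson", "r1", "avg_vp_host"),
    ("maxVp ~ R2", "pearson", "r2", "max_vp_host"),
]

#: per-host phenotypes compared across the isolation-year groups
YEAR_SCREEN_COLUMNS = ["max_vp_host", "mu", "r1", "r2"]


def run_screen(
    phenos: PhenotypeTable,
    metadata: StrainMetadata | None = None,
    year_cutoff: int = DEFAULT_YEAR_CUTOFF,
    k_split: int = 5,
) -> pd.DataFrame:
    """Run the full comparison battery; one row per test.

    Columns: comparison, test, statistic, df1, df2, p, n.
    """
    rows = []

    def _add(name: str, res: TestResult) -> None:
        df1 = res.df[0]
        df2 = res.df[1] if len(res.df) > 1 else np.nan
        rows.append(
            {
                "comparison": name,
                "test": res.test,
                "statistic": res.statistic,
                "df1": df1,
                "df2": df2,
                "p": res.p,
                "n": res.n,
            }
        )

    hosts = phenos.hosts
    for name, kind, xcol, ycol in STANDARD_SCREEN:
        _add(name, pearson(hosts[xcol], hosts[ycol]))

    # generalist vs specialist average viral production
    k = min(k_split, len(phenos.viruses) // 2)
    gen, spec = split_generalists_specialists(phenos.viruses["host_range"], k)
    if k >= 2:
        res = one_way_anova(
            [
                phenos.viruses.loc[gen, "avg_vp"].to_numpy(),
                phenos.viruses.loc[spec, "avg_vp"].to_numpy(),
            ]
        )
        _add("generalist vs specialist Vp", res)

    if metadata is not None:
        older, younger, _ = split_by_year(metadata, year_cutoff)
        older = [h for h in older if h in hosts.index]
        younger = [h for h in younger if h in hosts.index]
        if len(older) >= 2 and len(younger) >= 2:
            for col in YEAR_SCREEN_COLUMNS:
                res = one_way_anova(
                    [
                        hosts.loc[older, col].to_numpy(),
                        hosts.loc[younger, col].to_numpy(),
                    ]
                )
                _add(f"{col} by year group (<{year_cutoff} vs >={year_cutoff})", res)

    return pd.DataFrame(rows)
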