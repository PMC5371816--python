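"""Pearson and one-way ANOVA against reference implementations and their
analytic identities."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from ehvnet import (
    StrainMetadata,
    one_way_anova,
    pearson,
    run_screen,
    split_by_year,
)


def test_pearson_perfect_linear():
    x = np.arange(10.0)
    assert pearson(x, 2 * x + 1).statistic == pytest.approx(1.0)
    assert pearson(x, -x).statistic == pytest.approx(-1.0)


def test_pearson_matches_scipy():
    rng = np.random.default_rng(42)
    for _ in range(20):
        x = rng.normal(size=20)
        y = 0.4 * x + rng.normal(size=20)
        res = pearson(x, y)
        ref_r, ref_p = sps.pearsonr(x, y)
        assert res.statistic == pytest.approx(ref_r, abs=1e-10)
        assert res.p == pytest.approx(ref_p, abs=1e-10)
        assert res.df == (18,)


def test_pearson_symmetry():
    rng = np.random.default_rng(3)
    x, y = rng.normal(size=15), rng.normal(size=15)
    assert pearson(x, y).statistic == pearson(y, x).statistic


@pytest.mark.parametrize(
    "x,y",
    [(np.ones(5), np.arange(5.0)), (np.arange(3.0), np.arange(4.0)),
     (np.arange(2.0), np.arange(2.0))],
)
def test_pearson_rejects_degenerate(x, y):
    with pytest.raises(ValueError):
        pearson(x, y)


def test_anova_zero_f_for_equal_means():
    groups = [[1.0, 2.0, 3.0], [1.5, 2.0, 2.5], [2.0, 2.0, 2.0]]
    # shift groups so the means coincide exactly
    groups = [np.asarray(g) - np.mean(g) for g in groups]
    res = one_way_anova(groups)
    assert res.statistic == pytest.approx(0.0, abs=1e-12)


def test_anova_equals_pooled_t_squared():
    rng = np.random.default_rng(7)
    a, b = rng.normal(size=8), rng.normal(1.0, 1.0, size=11)
    f = one_way_anova([a, b]).statistic
    t = sps.ttest_ind(a, b, equal_var=True).statistic
    assert f == pytest.approx(t * t, rel=1e-10)


def test_anova_matches_scipy():
    rng = np.random.default_rng(12)
    for _ in range(20):
        groups = [rng.normal(loc, 1.0, size=n)
                  for loc, n in zip((0.0, 0.5, 1.0), (6, 9, 7))]
        res = one_way_anova(groups)
        ref = sps.f_oneway(*groups)
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-10)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-10)
        assert res.df == (2, 19)


@given(shift=st.floats(-100, 100), scale=st.floats(0.01, 100))
@settings(deadline=None, max_examples=30, derandomize=True)
def test_anova_invariant_to_affine_rescaling(shift, scale):
    rng = np.random.default_rng(5)
    groups = [rng.normal(size=6), rng.normal(0.8, 1.0, size=6)]
    base = one_way_anova(groups).statistic
    moved = one_way_anova([scale * g + shift for g in groups]).statistic
    assert moved == pytest.approx(base, rel=1e-8)


def test_anova_rejects_degenerate():
    with pytest.raises(ValueError):
        one_way_anova([[1.0, 2.0]])
    with pytest.raises(ValueError):
        one_way_anova([[1.0], [2.0, 3.0]])
    with pytest.raises(ValueError):
        one_way_anova([[2.0, 2.0], [2.0, 2.0]])


def _meta(years):
    return StrainMetadata(
        pd.DataFrame(
            {
                "strain_id": [f"h{i}" for i in range(len(years))],
                "role": "host",
                "isolation_year": years,
                "origin": "Atlantic",
            }
        )
    )


def test_split_by_year_boundary_goes_young():
    older, younger, unknown = split_by_year(_meta([2005, 2009, 2012]), 2009)
    assert older == ["h0"]
    assert younger == ["h1", "h2"]
    assert unknown == []


def test_split_by_year_all_unknown_warns():
    with pytest.warns(UserWarning):
        older, younger, unknown = split_by_year(_meta([None, None]), 2009)
    assert older == [] and younger == []
    assert unknown == ["h0", "h1"]


def test_planted_year_effect_detected(small_experiment):
    """A strong burst-size shift after 2009 shows up in the Vp ANOVA."""
    from ehvnet import SimulationConfig, phenotype_table, simulate_experiment

    cfg = SimulationConfig(n_hosts=20, n_viruses=6, year_effect=5.0, seed=99)
    counts, metadata, _ = simulate_experiment(cfg)
    phenos = phenotype_table(counts)
    screen = run_screen(phenos, metadata)
    row = screen[screen["comparison"].str.startswith("max_vp_host by year")]
    assert len(row) == 1
    assert row["p"].iloc[0] < 0.05


def test_screen_battery_shape(default_experiment):
    counts, metadata, _ = default_experiment
    from ehvnet import phenotype_table

    screen = run_screen(phenotype_table(counts), metadata)
    names = set(screen["comparison"])
    for expected in ("R1 ~ mu", "R2 ~ mu", "Vp ~ mu", "Vp ~ R1", "maxVp ~ R2",
                     "generalist vs specialist Vp"):
        assert expected in names
    assert screen["p"].between(0, 1).all()
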