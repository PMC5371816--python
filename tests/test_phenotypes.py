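"""Per-strain phenotype metrics and binary lysis/progeny calls."""

import math

import numpy as np
import pandas as pd
import pytest

from ehvnet import (
    growth_rate,
    phenotype_table,
    r1_overall,
    r1_pair,
    split_generalists_specialists,
    vp_pair,
)
from ehvnet.phenotypes import lysis_matrix, progeny_matrix

from conftest import one_host_counts


@pytest.mark.parametrize(
    "n1,n2,t,expected",
    [
        (1e5, 1e5, 3.0, 0.0),
        (1e5, 1e5 * math.e**3, 3.0, 1.0),
        (2e5, 1e5, 1.0, math.log(0.5)),  # declining control stays negative
    ],
)
def test_growth_rate_values(n1, n2, t, expected):
    assert growth_rate(n1, n2, t) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("bad", [(0, 1e5, 3), (1e5, -1, 3), (1e5, 1e5, 0)])
def test_growth_rate_rejects_nonpositive(bad):
    with pytest.raises(ValueError):
        growth_rate(*bad)


def test_growth_rate_exact_on_noise_free_exponential():
    mu = 0.73
    n2 = 1e5 * math.exp(mu * 3.0)
    assert growth_rate(1e5, n2, 3.0) == pytest.approx(mu, rel=1e-14)


@pytest.mark.parametrize(
    "infected,control,expected",
    [(5e5, 1e6, 0.5), (2e6, 1e6, 1.0), (0.0, 1e6, 0.0)],
)
def test_r1_pair(infected, control, expected):
    assert r1_pair(infected, control) == expected


def test_r1_pair_rejects_nonpositive_control():
    with pytest.raises(ValueError):
        r1_pair(1e5, 0.0)


def test_r1_overall_matches_hand_mean():
    """Spreadsheet-style oracle: mean of 13 per-pair ratios on one host."""
    finals = {f"V{i:02d}": 1e6 * frac for i, frac in
              enumerate([0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8,
                         0.9, 1.0, 1.2, 0.05, 0.15])}
    counts = one_host_counts(finals, control_final=1e6)
    expected = [min(1.0, f / 1e6) for f in finals.values()]
    mean, sd = r1_overall(counts, "H1")
    assert mean == pytest.approx(np.mean(expected), rel=1e-12)
    assert sd == pytest.approx(np.std(expected, ddof=1), rel=1e-12)


def test_r1_extremes():
    resistant = one_host_counts({f"V{i}": 1e6 for i in range(13)})
    assert r1_overall(resistant, "H1")[0] == pytest.approx(1.0)
    lysed = one_host_counts({f"V{i}": 0.0 for i in range(13)})
    assert r1_overall(lysed, "H1")[0] == pytest.approx(0.0)


def test_vp_pair_signed():
    assert vp_pair(5e7, 1e6) == pytest.approx(4.9e7)
    assert vp_pair(1e6, 1e6) == 0.0
    assert vp_pair(5e5, 1e6) == -5e5  # viral decay retained


def test_vp_summaries_match_enumeration():
    """3 hosts x 2 viruses hand matrix against exhaustive enumeration."""
    from conftest import build_counts
    from ehvnet.data import CONTROL
    from ehvnet.phenotypes import vp_summaries

    vp = {("H1", "V1"): 1e6, ("H1", "V2"): -2e5,
          ("H2", "V1"): 3e6, ("H2", "V2"): 0.0,
          ("H3", "V1"): 5e5, ("H3", "V2"): 7e6}
    rows = []
    for h in ("H1", "H2", "H3"):
        rows += [(h, CONTROL, 1, 0.0, 1e5, np.nan),
                 (h, CONTROL, 1, 72.0, 1e6, np.nan)]
        for v in ("V1", "V2"):
            rows += [(h, v, 1, 0.0, 1e5, 1e6),
                     (h, v, 1, 72.0, 1e5, 1e6 + vp[(h, v)])]
    counts = build_counts(rows)
    per_virus, per_host = vp_summaries(counts)
    for v in ("V1", "V2"):
        vals = [vp[(h, v)] for h in ("H1", "H2", "H3")]
        assert per_virus.loc[v, "avg_vp"] == pytest.approx(np.mean(vals))
        assert per_virus.loc[v, "max_vp"] == pytest.approx(max(vals))
        assert per_virus.loc[v, "max_vp"] >= per_virus.loc[v, "avg_vp"]
    for h in ("H1", "H2", "H3"):
        vals = [vp[(h, v)] for v in ("V1", "V2")]
        assert per_host.loc[h, "max_vp_host"] == pytest.approx(max(vals))


def test_lysis_and_progeny_calls_extremes():
    from ehvnet import call_lysis, call_progeny

    counts = one_host_counts({"V1": 1e5, "V2": 1e6},
                             v_finals={"V1": 1e8, "V2": 1e6})
    assert call_lysis(counts, "H1", "V1") == 1  # 0.1x control
    assert call_lysis(counts, "H1", "V2") == 0  # equals control
    assert call_progeny(counts, "H1", "V1") == 1  # 100x inoculum
    assert call_progeny(counts, "H1", "V2") == 0  # no production


def test_threshold_monotonicity(small_experiment):
    """Raising theta only adds lysis 1s; raising rho only removes progeny 1s."""
    counts, _, _ = small_experiment
    lo = lysis_matrix(counts, theta=0.5).values
    hi = lysis_matrix(counts, theta=0.9).values
    assert (hi >= lo).all()
    loose = progeny_matrix(counts, rho=1.2).values
    strict = progeny_matrix(counts, rho=5.0).values
    assert (loose >= strict).all()


def test_row_column_sum_self_consistency(small_experiment):
    counts, _, _ = small_experiment
    phenos = phenotype_table(counts)
    assert (phenos.hosts["r2"].to_numpy()
            == phenos.progeny.values.sum(axis=1)).all()
    assert (phenos.viruses["host_range"].to_numpy()
            == phenos.lysis.values.sum(axis=0)).all()
    assert phenos.hosts["r2"].between(0, len(phenos.viruses)).all()
    assert phenos.hosts["r1"].between(0, 1).all()


def test_split_generalists_specialists_rule():
    ranges = pd.Series({"a": 10, "b": 9, "c": 8, "d": 2, "e": 1, "f": 1})
    top, bottom = split_generalists_specialists(ranges, 2)
    assert top == ["a", "b"]
    assert bottom == ["e", "f"]  # tie at range 1 broken lexicographically
    assert split_generalists_specialists(ranges, 0) == ([], [])
    with pytest.raises(ValueError):
        split_generalists_specialists(ranges, 4)


def test_split_recovers_widest_planted_ranges(default_experiment):
    counts, _, truth = default_experiment
    ranges = pd.Series(
        truth.interaction.values.sum(axis=0),
        index=list(truth.interaction.viruses),
    )
    phenos = phenotype_table(counts)
    top, _ = split_generalists_specialists(phenos.viruses["host_range"], 5)
    expected_top, _ = split_generalists_specialists(ranges, 5)
    assert set(top) == set(expected_top)
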