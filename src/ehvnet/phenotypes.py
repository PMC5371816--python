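"""Per-strain phenotype metrics from the two-timepoint challenge design.

For each host strain the uninfected control wells give an exponential growth
rate mu = ln(N2/N1)/t (per day).  Resistance is quantified two ways: R1, the
fraction of cells surviving viral challenge relative to the uninfected
control, averaged over all virus strains; and R2, the number of virus strains
that produced progeny on the host.  Viral production Vp for a host-virus pair
is the difference between final and initial virion concentrations; per-virus
averages and maxima summarise infectivity, and the per-virus host range
(column sum of lysis calls) separates generalists from specialists.

Binary calls are threshold rules on replicate means: lysis when the infected
culture retains fewer than ``theta`` (default 0.75) of the control's cells,
progeny when final virions exceed ``rho`` (default 1.5) times the measured
inoculum.  Both thresholds are configurable; raising ``theta`` can only add
lysis calls and raising ``rho`` can only remove progeny calls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .data import CONTROL, ExperimentCounts, InfectionMatrix

#: default lysis-call threshold: infected / control final-cell ratio
DEFAULT_THETA = 0.75
#: default progeny-call threshold: fold increase over measured inoculum
DEFAULT_RHO = 1.5
#: nominal inoculum used when a t0 virion count is absent (particles/mL)
NOMINAL_VIRUS_INIT = 1e6


@dataclass(frozen=True)
class PhenotypeTable:
    """Per-host and per-virus phenotype summaries.

    ``hosts`` columns: mu, mu_sd, r1, r1_sd, r2, avg_vp_host, max_vp_host.
    ``viruses`` columns: host_range, avg_vp, max_vp.
    """

    hosts: pd.DataFrame
    viruses: pd.DataFrame
    lysis: InfectionMatrix
    progeny: InfectionMatrix


def growth_rate(n1: float, n2: float, t: float) -> float:
    """Exponential growth rate ln(n2/n1)/t, per day for t in days.

    May be negative for a declining control culture.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError(f"cell concentrations must be positive, got {n1}, {n2}")
    if t <= 0:
        raise ValueError(f"incubation time must be positive, got {t}")
    return math.log(n2 / n1) / t


def r1_pair(infected_final: float, control_final: float) -> float:
    """Surviving-cell fraction for one host-virus pair, clipped to [0, 1]."""
    if control_final <= 0:
        raise ValueError(
            f"control final concentration must be positive, got {control_final}"
        )
    return min(1.0, infected_final / control_final)


def vp_pair(v_final: float, v_initial: float) -> float:
    """Viral production: final minus initial virions (signed; decay allowed)."""
    return float(v_final) - float(v_initial)


def _host_mu(counts: ExperimentCounts, host: str) -> tuple[float, float]:
    """Per-replicate growth rates of the control series: (mean, sd)."""
    t0, t1 = counts.timepoints
    t_days = (t1 - t0) / 24.0
    sub = counts.series(host, CONTROL)
    rates = []
    for _, rep in sub.groupby("replicate"):
        n1 = float(rep.loc[rep["timepoint_h"] == t0, "cell_conc"].iloc[0])
        n2 = float(rep.loc[rep["timepoint_h"] == t1, "cell_conc"].iloc[0])
        rates.append(growth_rate(n1, n2, t_days))
    arr = np.asarray(rates)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return float(arr.mean()), sd


def r1_overall(counts: ExperimentCounts, host: str) -> tuple[float, float]:
    """Unweighted mean and sd of the per-virus surviving-cell ratios."""
    t0, t1 = counts.timepoints
    control = counts.replicate_mean(host, CONTROL, "cell_conc", t1)
    vals = []
    for virus in counts.viruses:
        infected = counts.replicate_mean(host, virus, "cell_conc", t1)
        vals.append(r1_pair(infected, control))
    arr = np.asarray(vals)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return float(arr.mean()), sd


def _pair_vp(counts: ExperimentCounts, host: str, virus: str) -> float:
    t0, t1 = counts.timepoints
    v_final = counts.replicate_mean(host, virus, "virus_conc", t1)
    v_init = counts.replicate_mean(host, virus, "virus_conc", t0)
    if math.isnan(v_init):
        v_init = NOMINAL_VIRUS_INIT
    return vp_pair(v_final, v_init)


def vp_matrix(counts: ExperimentCounts) -> pd.DataFrame:
    """Signed viral production for every host x virus pair (particles/mL)."""
    hosts, viruses = counts.hosts, counts.viruses
    out = pd.DataFrame(index=hosts, columns=viruses, dtype=float)
    for host in hosts:
        for virus in viruses:
            out.loc[host, virus] = _pair_vp(counts, host, virus)
    return out


def vp_summaries(counts: ExperimentCounts) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-virus (avg_vp, max_vp over hosts) and per-host (avg, max over viruses)."""
    vp = vp_matrix(counts)
    per_virus = pd.DataFrame(
        {"avg_vp": vp.mean(axis=0), "max_vp": vp.max(axis=0)}
    )
    per_host = pd.DataFrame(
        {"avg_vp_host": vp.mean(axis=1), "max_vp_host": vp.max(axis=1)}
    )
    return per_virus, per_host


def call_lysis(
    counts: ExperimentCounts,
    host: str,
    virus: str,
    theta: float = DEFAULT_THETA,
    method: str = "ratio",
    alpha: float = 0.05,
) -> int:
    """Binary lysis call for one pair.

    ``ratio`` (default): 1 iff mean infected final cells < theta x mean
    control final cells.  ``welch``: one-sided Welch t-test of infected vs
    control final-cell replicates at level ``alpha``.
    """
    t0, t1 = counts.timepoints
    control = counts.replicate_mean(host, CONTROL, "cell_conc", t1)
    if control <= 0:
        raise ValueError(f"control mean is non-positive for host {host}")
    if method == "ratio":
        infected = counts.replicate_mean(host, virus, "cell_conc", t1)
        return int(infected < theta * control)
    if method == "welch":
        inf_sub = counts.series(host, virus)
        ctl_sub = counts.series(host, CONTROL)
        x = inf_sub.loc[inf_sub["timepoint_h"] == t1, "cell_conc"].to_numpy()
        y = ctl_sub.loc[ctl_sub["timepoint_h"] == t1, "cell_conc"].to_numpy()
        res = _stats.ttest_ind(x, y, equal_var=False, alternative="less")
        return int(res.pvalue < alpha)
    raise ValueError(f"unknown lysis-call method {method!r}")


def call_progeny(
    counts: ExperimentCounts, host: str, virus: str, rho: float = DEFAULT_RHO
) -> int:
    """1 iff mean final virions >= rho x mean initial virions."""
    t0, t1 = counts.timepoints
    v_init = counts.replicate_mean(host, virus, "virus_conc", t0)
    if math.isnan(v_init):
        v_init = NOMINAL_VIRUS_INIT
    if v_init <= 0:
        raise ValueError(
            f"initial virion concentration non-positive for ({host}, {virus})"
        )
    v_final = counts.replicate_mean(host, virus, "virus_conc", t1)
    return int(v_final >= rho * v_init)


def lysis_matrix(
    counts: ExperimentCounts, theta: float = DEFAULT_THETA, method: str = "ratio"
) -> InfectionMatrix:
    hosts, viruses = counts.hosts, counts.viruses
    vals = np.zeros((len(hosts), len(viruses)), dtype=np.int8)
    for i, host in enumerate(hosts):
        for j, virus in enumerate(viruses):
            vals[i, j] = call_lysis(counts, host, virus, theta, method=method)
    return InfectionMatrix(tuple(hosts), tuple(viruses), vals)


def progeny_matrix(
    counts: ExperimentCounts, rho: float = DEFAULT_RHO
) -> InfectionMatrix:
    hosts, viruses = counts.hosts, counts.viruses
    vals = np.zeros((len(hosts), len(viruses)), dtype=np.int8)
    for i, host in enumerate(hosts):
        for j, virus in enumerate(viruses):
            vals[i, j] = call_progeny(counts, host, virus, rho)
    return InfectionMatrix(tuple(hosts), tuple(viruses), vals)


def r2(counts: ExperimentCounts, host: str, rho: float = DEFAULT_RHO) -> int:
    """Number of virus strains that produced progeny on the host."""
    return sum(call_progeny(counts, host, v, rho) for v in counts.viruses)


def host_range(
    counts: ExperimentCounts, virus: str, theta: float = DEFAULT_THETA
) -> int:
    """Number of host strains lysed by the virus."""
    return sum(call_lysis(counts, h, virus, theta) for h in counts.hosts)


def split_generalists_specialists(
    host_ranges: pd.Series, k: int
) -> tuple[list[str], list[str]]:
    """Top-k (generalist) and bottom-k (specialist) virus ids by host range.

    Ties are broken lexicographically by strain id, so the split is
    deterministic.
    """
    n = len(host_ranges)
    if k < 0 or k > n // 2:
        raise ValueError(f"k={k} out of range for {n} viruses")
    order = sorted(host_ranges.items(), key=lambda kv: (-kv[1], kv[0]))
    generalists = [sid for sid, _ in order[:k]]
    order_asc = sorted(host_ranges.items(), key=lambda kv: (kv[1], kv[0]))
    specialists = [sid for sid, _ in order_asc[:k]]
    return generalists, specialists


def phenotype_table(
    counts: ExperimentCounts,
    theta: float = DEFAULT_THETA,
    rho: float = DEFAULT_RHO,
) -> PhenotypeTable:
    """Compute every per-host and per-virus metric plus both binary matrices."""
    hosts, viruses = counts.hosts, counts.viruses
    lys = lysis_matrix(counts, theta)
    prog = progeny_matrix(counts, rho)
    per_virus_vp, per_host_vp = vp_summaries(counts)

    host_rows = {}
    for i, host in enumerate(hosts):
        mu, mu_sd = _host_mu(counts, host)
        r1, r1_sd = r1_overall(counts, host)
        host_rows[host] = {
            "mu": mu,
            "mu_sd": mu_sd,
            "r1": r1,
            "r1_sd": r1_sd,
            "r2": int(prog.values[i].sum()),
            "avg_vp_host": per_host_vp.loc[host, "avg_vp_host"],
            "max_vp_host": per_host_vp.loc[host, "max_vp_host"],
        }
    host_df = pd.DataFrame.from_dict(host_rows, orient="index")
    host_df.index.name = "host_id"

    virus_df = pd.DataFrame(
        {
            "host_range": lys.values.sum(axis=0),
            "avg_vp": per_virus_vp["avg_vp"].to_numpy(),
            "max_vp": per_virus_vp["max_vp"].to_numpy(),
        },
        index=list(viruses),
    )
    virus_df.index.name = "virus_id"
    return PhenotypeTable(host_df, virus_df, lys, prog)
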