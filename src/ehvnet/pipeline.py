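"""One-call orchestration: simulate/load -> phenotypes -> screen -> network
-> null significance -> report.

Outputs are deterministic for a fixed config: the same seed and inputs give
byte-identical files.  Log lines go to stderr; results never do.  Any stage
failure aborts the run, names the stage, and removes partial outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import association, phenotypes
from .data import (
    ExperimentCounts,
    StrainMetadata,
    read_counts,
    read_matrix,
    read_metadata,
    write_counts,
    write_matrix,
    write_metadata,
)
from .network import degree_sort, detect_modules, nodf
from .nulls import DEFAULT_N_NULL, significance
from .simulate import GroundTruth, SimulationConfig, simulate_experiment

logger = logging.getLogger("ehvnet")

#: the five standing hypotheses on phenotype trade-offs, mapped to screens;
#: the last field is the effect direction the hypothesis predicts
HYPOTHESES = [
    (1, "Resistance is associated with reduced growth rates (cost of resistance)",
     "R1 ~ mu", -1),
    (2, "Host strains with higher growth rate produce more viruses",
     "Vp ~ mu", +1),
    (3, "Host strains with higher growth rate are infected by more viral strains",
     "R2 ~ mu", +1),
    (4, "Host strains with higher resistance produce fewer viruses",
     "Vp ~ R1", -1),
    (5, "Specialist viruses have higher viral production than generalists",
     "generalist vs specialist Vp", -1),  # sign of (generalist - specialist)
]


@dataclass
class RunConfig:
    """Configuration for a full pipeline run."""

    out_dir: str | Path = "ehvnet_out"
    seed: int | None = None
    counts_path: str | Path | None = None
    metadata_path: str | Path | None = None
    simulate: SimulationConfig | None = None
    theta: float = phenotypes.DEFAULT_THETA
    rho: float = phenotypes.DEFAULT_RHO
    n_null: int = DEFAULT_N_NULL
    metrics: tuple[str, ...] = ("NODF", "Qb")
    year_cutoff: int = association.DEFAULT_YEAR_CUTOFF

    def __post_init__(self) -> None:
        if not (0 < self.theta):
            raise ValueError("theta must be positive")
        if self.rho <= 0:
            raise ValueError("rho must be positive")
        if self.simulate is None and self.counts_path is None:
            raise ValueError("either counts_path or a simulate block is required")
        needs_seed = self.simulate is not None or self.n_null > 0
        if needs_seed and self.seed is None:
            raise ValueError("seed is mandatory for any stochastic step")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        if sim is not None:
            sim = SimulationConfig(**sim)
        cfg = cls(simulate=sim, **raw)
        if cfg.simulate is not None and cfg.simulate.seed is None:
            cfg.simulate.seed = cfg.seed
        return cfg


def _json_dump(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def run_all(config: RunConfig) -> dict:
    """Run every stage and write the report bundle to ``config.out_dir``.

    Returns a dict of the in-memory results keyed by stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "setup"

    def _track(path: Path) -> Path:
        written.append(path)
        return path

    try:
        # -- inputs --------------------------------------------------------
        stage = "simulate" if config.simulate is not None else "load"
        truth: GroundTruth | None = None
        if config.simulate is not None:
            sim_cfg = config.simulate
            if sim_cfg.seed is None:
                sim_cfg.seed = config.seed
            logger.info("stage=simulate design=%dx%d structure=%s",
                        sim_cfg.n_hosts, sim_cfg.n_viruses, sim_cfg.structure)
            counts, metadata, truth = simulate_experiment(sim_cfg)
            write_counts(counts, _track(out / "counts.csv"))
            write_metadata(metadata, _track(out / "metadata.csv"))
            write_matrix(truth.interaction, _track(out / "truth_matrix.csv"))
            truth.to_json(_track(out / "ground_truth.json"))
        else:
            logger.info("stage=load counts=%s", config.counts_path)
            counts = read_counts(config.counts_path)
            metadata = (
                read_metadata(config.metadata_path)
                if config.metadata_path
                else None
            )

        # -- phenotypes ----------------------------------------------------
        stage = "phenotypes"
        logger.info("stage=phenotypes theta=%g rho=%g", config.theta, config.rho)
        phenos = phenotypes.phenotype_table(counts, config.theta, config.rho)
        phenos.hosts.to_csv(_track(out / "phenotypes_hosts.csv"))
        phenos.viruses.to_csv(_track(out / "phenotypes_viruses.csv"))
        write_matrix(phenos.lysis, _track(out / "lysis_matrix.csv"))
        write_matrix(phenos.progeny, _track(out / "progeny_matrix.csv"))

        # -- screens -------------------------------------------------------
        stage = "screen"
        logger.info("stage=screen")
        screen = association.run_screen(
            phenos, metadata, year_cutoff=config.year_cutoff
        )
        screen.to_csv(_track(out / "screen.csv"), index=False)

        # -- network structure ----------------------------------------------
        stage = "network"
        matrix = phenos.lysis
        logger.info("stage=network fill=%d", matrix.fill)
        score = nodf(matrix)
        part = detect_modules(matrix)
        net = {
            "nodf": score.value,
            "qb": part.qb,
            "n_modules": part.n_modules,
            "fill": matrix.fill,
            "shape": list(matrix.shape),
            "row_assignments": dict(
                zip(matrix.hosts, map(int, part.row_assignments))
            ),
            "column_assignments": dict(
                zip(matrix.viruses, map(int, part.column_assignments))
            ),
        }
        _json_dump(net, _track(out / "network.json"))
        write_matrix(degree_sort(matrix), _track(out / "sorted_matrix.csv"))

        # -- null-model significance ----------------------------------------
        stage = "nulls"
        null_results = {}
        for metric in config.metrics:
            logger.info("stage=nulls metric=%s n_null=%d", metric, config.n_null)
            res = significance(
                matrix, metric=metric, n_null=config.n_null, seed=config.seed
            )
            res.to_json(_track(out / f"nulls_{metric.lower()}.json"))
            null_results[metric] = res

        # -- report ----------------------------------------------------------
        stage = "report"
        report = _render_report(screen, net, null_results, truth, phenos)
        (_track(out / "report.md")).write_text(report)
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc

    return {
        "counts": counts,
        "metadata": metadata,
        "phenotypes": phenos,
        "screen": screen,
        "network": net,
        "nulls": null_results,
        "truth": truth,
    }


def _render_report(screen, net, null_results, truth, phenos) -> str:
    from .phenotypes import split_generalists_specialists

    lines = ["# Cross-infectivity analysis report", ""]
    lines.append("## Hypothesis screens")
    lines.append("")
    by_name = {row["comparison"]: row for _, row in screen.iterrows()}
    for num, text, comparison, expected_sign in HYPOTHESES:
        row = by_name.get(comparison)
        if row is None:
            lines.append(f"{num}. {text}: comparison '{comparison}' not available.")
            continue
        if row["test"] == "pearson":
            stat_name = "r"
            observed_sign = np.sign(row["statistic"])
        else:
            stat_name = "F"
            k = min(5, len(phenos.viruses) // 2)
            gen, spec = split_generalists_specialists(
                phenos.viruses["host_range"], k
            )
            diff = (phenos.viruses.loc[gen, "avg_vp"].mean()
                    - phenos.viruses.loc[spec, "avg_vp"].mean())
            observed_sign = np.sign(diff)
        if row["p"] >= 0.05:
            verdict = "not supported"
        elif observed_sign == expected_sign:
            verdict = "supported"
        else:
            verdict = "significant in the opposite direction"
        lines.append(
            f"{num}. {text}: {comparison} -> {stat_name} = "
            f"{row['statistic']:.4g}, p = {row['p']:.4g} ({verdict} at alpha=0.05)."
        )
    lines.append("")
    lines.append("## Infection-network structure")
    lines.append("")
    lines.append(
        f"- Lysis matrix {net['shape'][0]} hosts x {net['shape'][1]} viruses, "
        f"fill {net['fill']}."
    )
    lines.append(f"- NODF nestedness = {net['nodf']:.4f} (0-1 scale).")
    lines.append(
        f"- Barber modularity Qb = {net['qb']:.4f} in {net['n_modules']} modules."
    )
    for metric, res in null_results.items():
        z_txt = "undefined" if res.null_sd == 0 else f"{res.z:.2f}"
        lines.append(
            f"- {metric} vs {res.n_null} equiprobable nulls: "
            f"null mean {res.null_mean:.4f} (sd {res.null_sd:.4f}), "
            f"z = {z_txt}, empirical p = {res.p_empirical:.4f}."
        )
    if truth is not None:
        lines.append("")
        lines.append("## Ground truth (simulated run)")
        lines.append("")
        lines.append(
            f"- Planted structure: {truth.config.structure}, "
            f"fill {truth.interaction.fill}."
        )
    lines.append("")
    return "\n".join(lines)
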