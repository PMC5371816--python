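import numpy as np
import pandas as pd
import pytest

from ehvnet import SimulationConfig, simulate_experiment
from ehvnet.data import CONTROL, ExperimentCounts


@pytest.fixture(scope="session")
def default_experiment():
    """Full-scale seeded synthetic experiment (49 hosts x 13 viruses)."""
    return simulate_experiment(SimulationConfig(seed=20170322))


@pytest.fixture(scope="session")
def small_experiment():
    """Small seeded experiment for fast end-to-end checks."""
    cfg = SimulationConfig(n_hosts=10, n_viruses=5, seed=11)
    return simulate_experiment(cfg)


def build_counts(rows):
    """Tidy counts table from (host, challenge, rep, t_h, cells, virions)."""
    return ExperimentCounts(
        pd.DataFrame(
            rows,
            columns=[
                "host_id", "challenge_id", "replicate",
                "timepoint_h", "cell_conc", "virus_conc",
            ],
        )
    )


def one_host_counts(infected_finals, control_final=1e6, v_init=1e6,
                    v_finals=None, host="H1"):
    """Single-host design: one control series plus one series per virus.

    ``infected_finals`` maps virus id -> final cell concentration.
    """
    rows = [
        (host, CONTROL, 1, 0.0, 1e5, np.nan),
        (host, CONTROL, 1, 72.0, control_final, np.nan),
    ]
    for virus, cells in infected_finals.items():
        vf = (v_finals or {}).get(virus, 5e7)
        rows += [
            (host, virus, 1, 0.0, 1e5, v_init),
            (host, virus, 1, 72.0, cells, vf),
        ]
    return build_counts(rows)
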