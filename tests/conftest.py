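import numpy as np
import pandas as pd
import pytest

from alphacoupling import SimulationParams, simulate_cohort
from alphacoupling.pipeline import PipelineConfig, process_subject


@pytest.fixture(scope="session")
def tiny_params() -> SimulationParams:
    return SimulationParams(n_per_group=2, trials_per_condition=12, seed=11)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_params):
    return simulate_cohort(tiny_params)


@pytest.fixture(scope="session")
def processed_subject(tiny_params, tiny_cohort):
    """One fully preprocessed subject (trial table with alpha power and
    speed bins, behavioral summary) shared across tests."""
    recordings, _ = tiny_cohort
    cfg = PipelineConfig(simulation=tiny_params, seed=tiny_params.seed)
    table, behav = process_subject(recordings[0], cfg)
    return recordings[0], table, behav


def make_trial_table(
    rts, conditions=None, correct=None, artifact=None
) -> pd.DataFrame:
    """Hand-rolled trial table for preprocessing/coupling unit tests."""
    rts = np.asarray(rts, dtype=float)
    n = len(rts)
    return pd.DataFrame(
        {
            "trial_id": np.arange(n),
            "condition": conditions if conditions is not None else ["congruent"] * n,
            "rt": rts,
            "correct": correct if correct is not None else [True] * n,
            "artifact": artifact if artifact is not None else [False] * n,
        }
    )
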