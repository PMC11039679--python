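import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from redoxtf import (
    ExposureCondition,
    PerturbationMode,
    SimulationConfig,
    simulate_population,
    simulate_snapshot,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_config(mode="none", dose=0.0, pert="control", n=100, seed=0, **kwargs):
    return SimulationConfig(
        condition=ExposureCondition(mode=mode, dose=dose),
        perturbation=PerturbationMode.from_label(pert),
        n_cells=n,
        seed=seed,
        **kwargs,
    )


@pytest.fixture(scope="session")
def pop_bolus80():
    return simulate_population(make_config("bolus", 80.0, n=200, seed=21), id_prefix="b80_")


@pytest.fixture(scope="session")
def pop_bolus100():
    return simulate_population(make_config("bolus", 100.0, n=200, seed=22), id_prefix="b100_")


@pytest.fixture(scope="session")
def pop_high_pooled(pop_bolus80, pop_bolus100):
    return pd.concat([pop_bolus80, pop_bolus100], ignore_index=True)


@pytest.fixture(scope="session")
def pop_gox1():
    return simulate_population(make_config("continuous", 1.0, n=120, seed=23), id_prefix="g1_")


@pytest.fixture(scope="session")
def snapshot_control():
    return simulate_snapshot(make_config(n=600, seed=31), t_fix=5.0)


def synthetic_trace(cell_id, t, foxo, p53, **kwargs):
    from redoxtf.trace_io import CellTrace

    return CellTrace(
        cell_id=cell_id,
        mode=kwargs.get("mode", "bolus"),
        dose=kwargs.get("dose", 100.0),
        perturbation=kwargs.get("perturbation", "control"),
        t=np.asarray(t, dtype=float),
        foxo1_nuc_frac=np.asarray(foxo, dtype=float),
        p53_nuc=np.asarray(p53, dtype=float),
        death_time=kwargs.get("death_time"),
    )
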