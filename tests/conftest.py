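"""Shared fixtures: small synthetic studies generated at test time."""

import numpy as np
import pandas as pd
import pytest

from glyconet import simulate as sim
from glyconet.datatypes import FluidMatrix
from glyconet.preprocess import FluidPreprocessor


def small_sim_config(
    n_cases=150,
    n_controls=150,
    sizes=None,
    edge_density=0.02,
    seed=0,
    duplication=False,
):
    """A small but fully featured simulation config for fast tests."""
    cfg = sim.SimulationConfig(seed=seed)
    cfg.cohort.n_cases = n_cases
    cfg.cohort.n_controls = n_controls
    cfg.panel.sizes = sizes or {"saliva": 20, "plasma": 30, "urine": 30}
    if not duplication:
        cfg.panel.n_shared_triples = 0
        cfg.panel.n_shared_pairs = 0
    else:
        cfg.panel.n_shared_triples = 4
        cfg.panel.n_shared_pairs = 6
    cfg.network.edge_density = edge_density
    return cfg


@pytest.fixture(scope="session")
def small_study():
    return sim.simulate_study(small_sim_config(), seed=11)


@pytest.fixture(scope="session")
def preprocessed(small_study):
    return {
        fluid: FluidPreprocessor(min_detections=20).fit_transform(fm)
        for fluid, fm in small_study.fluids.items()
    }


@pytest.fixture(scope="session")
def cohort369():
    return sim.generate_cohort(sim.CohortConfig(seed=2))


def toy_fluid(values, fluid="plasma", run_day=None, osmolality=None, measures=None):
    """Build a FluidMatrix from a plain array for unit tests."""
    values = np.asarray(values, float)
    n, m = values.shape
    idx = pd.Index([f"QM{i + 1:04d}" for i in range(n)], name="participant_id")
    cols = measures or [f"M{j + 1:03d}" for j in range(m)]
    return FluidMatrix(
        fluid=fluid,
        data=pd.DataFrame(values, index=idx, columns=cols),
        run_day=pd.Series(run_day if run_day is not None else np.ones(n, int), index=idx),
        osmolality=None if osmolality is None else pd.Series(osmolality, index=idx),
    )
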