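import numpy as np
import pandas as pd
import pytest

from cooccupancy import simulate
from cooccupancy.occupancy import ModelSpec, StudyData


@pytest.fixture(scope="session")
def study_scale():
    """One synthetic study at the field design (40 sites x 6 nights)."""
    return simulate.simulate_study(simulate.preset("study_scale"), seed=11)


@pytest.fixture(scope="session")
def study_fit(study_scale):
    """A light posterior fit of the true generating model at study scale."""
    from cooccupancy.occupancy import fit

    spec, _ = simulate.scenario_model(study_scale.scenario)
    return fit(spec, study_scale.study_data(), chains=2, iterations=700,
               warmup=250, seed=5)


@pytest.fixture()
def two_species_data():
    """Minimal covariate-free two-species container for derived-quantity tests."""
    n = 3
    return StudyData(
        y=np.zeros((2, n, 2)),
        species=("a", "b"),
        sites=tuple(f"s{i}" for i in range(n)),
        covariates=pd.DataFrame({"site_id": [f"s{i}" for i in range(n)]}),
        trail=np.zeros(n, dtype=int),
        dog_activity=np.zeros((n, 2)),
    )


def constant_fit(spec: ModelSpec, theta, n_sites: int):
    """A degenerate FitResult whose draws all equal ``theta`` (for exact oracles)."""
    from cooccupancy.occupancy import FitResult

    theta = np.asarray(theta, dtype=float)
    return FitResult(
        draws=np.tile(theta, (2, 40, 1)),
        param_names=spec.param_names,
        spec=spec,
        seed=0,
        rhat=np.ones(len(theta)),
        pointwise=np.zeros((2, n_sites)),
        waic={},
    )
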