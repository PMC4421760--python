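import logging
import warnings

import numpy as np
import pytest

import bhpm

logging.getLogger("bhpm").setLevel(logging.ERROR)
warnings.filterwarnings("ignore", message=".*ArviZ.*")


@pytest.fixture(scope="session")
def small_study():
    """A modest synthetic study reused by stage-1/stage-2 tests."""
    truth = bhpm.SimulationTruth(n_locations=80, seed=42)
    return bhpm.simulate_study(truth)


@pytest.fixture(scope="session")
def small_stage1(small_study):
    return bhpm.fit_all_locations(small_study.panel)


def converged_subset(study, estimates):
    ok = {e.location_id for e in estimates if e.converged}
    profiles = [p for p in study.profiles if p.location_id in ok]
    coords = study.coords[study.coords["location_id"].isin(ok)][["lon", "lat"]].to_numpy()
    return profiles, coords


@pytest.fixture(scope="session")
def small_fit(small_study, small_stage1):
    profiles, _ = converged_subset(small_study, small_stage1)
    spec = bhpm.ModelSpec("both", False)
    X0, X1, n0, n1 = bhpm.build_design(profiles, spec)
    res = bhpm.run_mcmc(
        small_stage1, X0, X1, spec, n_iter=1200, n_burn=600, n_chains=2, seed=7,
        names0=n0, names1=n1,
    )
    return res, X0, X1


def rng(seed=0):
    return np.random.default_rng(seed)
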