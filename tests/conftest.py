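import numpy as np
import pandas as pd
import pytest

from stepflow.config import RunConfig
from stepflow.hmm import HmmParams
from stepflow.synthetic import SimConfig, simulate_acc, simulate_tracks


@pytest.fixture(scope="session")
def toy_hmm_params() -> HmmParams:
    return HmmParams(mu=[2.0, 25.0], sigma=[2.0, 20.0], kappa=[0.3, 2.0],
                     tpm=[[0.9, 0.1], [0.15, 0.85]])


@pytest.fixture(scope="session")
def run_config() -> RunConfig:
    return RunConfig(rng_seed=1, hmm_restarts=2)


@pytest.fixture(scope="session")
def small_sim():
    """A small but full synthetic dataset shared across tests."""
    cfg = SimConfig(n_individuals=2, n_days=4, p_missing_fix=0.03)
    rng = np.random.default_rng(2024)
    fixes, truth, timelines = simulate_tracks(cfg, rng)
    acc = simulate_acc(cfg, timelines, rng)
    return {"config": cfg, "fixes": fixes, "truth": truth,
            "timelines": timelines, "acc": acc}


def make_fixes(coords, start="2017-05-01T00:00:00Z", interval=300.0,
               individual="b1"):
    """Fix table from a coordinate list on a perfect schedule."""
    t0 = pd.Timestamp(start)
    coords = np.asarray(coords, dtype=float)
    return pd.DataFrame({
        "individual_id": individual,
        "timestamp": [t0 + pd.Timedelta(seconds=interval * i)
                      for i in range(len(coords))],
        "x": coords[:, 0], "y": coords[:, 1],
    })
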