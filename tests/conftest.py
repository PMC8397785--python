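import numpy as np
import pandas as pd
import pytest

from microcolony.io import AnalysisConfig
from microcolony.simulate import (
    SimChamberConfig,
    SubstrateParams,
    simulate_chamber,
)


def constant_rate_substrates(r: float = 0.3, p_disperse: float = 1.0):
    """A single substrate whose growth rate is effectively density-free
    above one cell (K_sat=1, no competition): r(n) ~ r for n >> 1."""
    return {
        "xylose": SubstrateParams(
            p_disperse=p_disperse, r_max=r, K_sat=1.0, c_comp=0.0,
        )
    }


@pytest.fixture(scope="session")
def analysis_config() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture(scope="session")
def small_chamber():
    """One small colonial chamber with full ground truth (shared, read-only)."""
    cfg = SimChamberConfig(n_founders=2, duration_h=14.0, seed=71)
    return simulate_chamber(cfg)


@pytest.fixture(scope="session")
def noiseless_constant_rate_chamber():
    """All daughters disperse and the density benefit is saturated, so every
    cell grows at a constant known rate: the oracle for rate estimation."""
    cfg = SimChamberConfig(
        n_founders=12,
        duration_h=10.0,
        substrate_schedule=((0.0, "xylose"),),
        substrates=constant_rate_substrates(r=0.3, p_disperse=1.0),
        interdivision_cv=0.0,
        seed=5,
    )
    return simulate_chamber(cfg)


def tiny_table(rows, columns=None):
    cols = columns or [
        "cell_id", "frame", "time_h", "x_um", "y_um", "area_um2", "parent_id",
    ]
    df = pd.DataFrame(rows, columns=cols)
    df["parent_id"] = df["parent_id"].fillna("").astype(str)
    return df


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)
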