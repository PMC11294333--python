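import numpy as np
import pandas as pd
import pytest

from tsmr import SimulationConfig, harmonize, kept_records, simulate_pair


def make_harmonized(bx, sx, by, sy, ids=None) -> pd.DataFrame:
    """Minimal harmonized frame from effect/SE arrays."""
    bx = np.asarray(bx, dtype=float)
    k = len(bx)
    return pd.DataFrame(
        {
            "snp_id": ids if ids is not None else [f"rs{i}" for i in range(k)],
            "beta_exp": bx,
            "se_exp": np.asarray(sx, dtype=float),
            "beta_out": np.asarray(by, dtype=float),
            "se_out": np.asarray(sy, dtype=float),
        }
    )


def clean_sim_config(**overrides) -> SimulationConfig:
    """Homogeneous no-pleiotropy study conditions used across tests."""
    defaults = dict(
        n_snps=30,
        theta=0.35,
        n_exposure=100_000,
        n_outcome=100_000,
        palindromic_fraction=0.0,
        scramble_alleles=False,
        seed=7,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture
def clean_pair():
    return simulate_pair(clean_sim_config())


@pytest.fixture
def clean_harmonized(clean_pair):
    exposure, outcome, _ = clean_pair
    return kept_records(harmonize(exposure, outcome))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
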