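import numpy as np
import pandas as pd
import pytest

from mcpmr.pipeline import RunConfig, run_all
from mcpmr.simulate import simulate_study


def make_sumstats(**overrides) -> pd.DataFrame:
    """Small canonical sumstats frame; columns overridable per test."""
    base = {
        "SNP": ["rs1", "rs2", "rs3"],
        "CHR": ["1", "1", "2"],
        "POS": [1000, 2000, 3000],
        "EA": ["A", "C", "A"],
        "OA": ["G", "T", "G"],
        "EAF": [0.3, 0.4, 0.2],
        "BETA": [0.1, -0.05, 0.2],
        "SE": [0.01, 0.02, 0.03],
        "P": [1e-10, 1e-3, 1e-12],
        "N": [10000, 10000, 10000],
    }
    base.update(overrides)
    return pd.DataFrame(base)


def make_pairs(beta_gx, beta_gy, se_gx=None, se_gy=None, eaf=0.3,
               n_gx=50_000, n_gy=50_000) -> pd.DataFrame:
    """Harmonized instrument frame from effect arrays."""
    beta_gx = np.asarray(beta_gx, dtype=float)
    beta_gy = np.asarray(beta_gy, dtype=float)
    k = len(beta_gx)
    se_gx = np.full(k, 0.01) if se_gx is None else np.asarray(se_gx, float)
    se_gy = np.full(k, 0.01) if se_gy is None else np.asarray(se_gy, float)
    return pd.DataFrame({
        "SNP": [f"rs{j}" for j in range(k)],
        "beta_gx": beta_gx, "se_gx": se_gx,
        "beta_gy": beta_gy, "se_gy": se_gy,
        "eaf": np.full(k, eaf), "eaf_gy": np.full(k, eaf),
        "n_gx": n_gx, "n_gy": n_gy,
    })


@pytest.fixture(scope="session")
def small_study():
    """A reduced end-to-end study reused by the pipeline tests."""
    return simulate_study(seed=3, n_proteins=6, n_causal=3,
                          n_exposure=8000, n_outcome=15000,
                          n_replication=4000, n_riskfactor_cohort=8000)


@pytest.fixture(scope="session")
def small_study_reports(small_study):
    cfg = RunConfig(seed=11, presso_n_sim=200)
    return run_all(small_study, cfg)
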