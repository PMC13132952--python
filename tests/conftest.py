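import numpy as np
import pytest

import twinsem as ts


@pytest.fixture(scope="session")
def small_discrete_ds() -> ts.TwinDataset:
    """A small realistic dataset: study missingness + ordinal discretisation."""
    sc = ts.study_scenario("riclpm", realism=True, seed=42, n_mz=60, n_dz=90)
    return ts.simulate_pairs(sc)


@pytest.fixture(scope="session")
def cholesky_study_fit():
    """One AE Cholesky fit on study-scale complete simulated wellbeing data."""
    ds = ts.simulate_pairs(ts.study_scenario("cholesky", seed=21))
    res = ts.CholeskyACE(ds).fit(n_starts=1, seed=0, compute_se=True)
    return ds, res


@pytest.fixture(scope="session")
def riclpm_study_fit():
    """One genetic RI-CLPM fit on study-scale complete simulated data."""
    ds = ts.simulate_pairs(ts.study_scenario("riclpm", seed=5))
    res = ts.GeneticRICLPM(ds).fit(n_starts=1, seed=0, compute_se=True)
    return ds, res


@pytest.fixture(scope="session")
def cholesky_recovery_report() -> ts.RecoveryReport:
    """50-replicate recovery of the AE wellbeing decomposition (1000 MZ + 1500 DZ)."""
    return ts.cholesky_recovery(n_replicates=50, seed=12)


@pytest.fixture(scope="session")
def riclpm_recovery_report() -> ts.RecoveryReport:
    """50-replicate recovery of the genetic RI-CLPM at study scale (550 MZ + 890 DZ)."""
    return ts.riclpm_recovery(n_replicates=50, seed=11)
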