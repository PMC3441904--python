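import numpy as np
import pytest

from smrfunnel import ProviderRecord, SyntheticSpec, simulate_providers


@pytest.fixture(scope="session")
def small_cohort():
    """Mixed in-control/outlier cohort with truth labels, fixed seed."""
    spec = SyntheticSpec(
        n_in_control=40, n_outliers=10, theta=2.0, lam=(5.0, 60.0), seed=20120716
    )
    return simulate_providers(spec)


@pytest.fixture
def provider_csv(tmp_path):
    path = tmp_path / "providers.csv"
    path.write_text(
        "provider_id,observed,expected\n"
        "A,18,10\n"
        "B,17,10\n"
        "C,0,1\n"
    )
    return path


@pytest.fixture
def records():
    return [
        ProviderRecord("A", 18, 10.0),
        ProviderRecord("B", 17, 10.0),
        ProviderRecord("C", 0, 1.0),
    ]


@pytest.fixture(scope="session")
def lam_grid_small():
    """λ values spanning sub-integer, small and moderate means."""
    return np.concatenate([[0.5, 0.7], np.arange(1.0, 51.0), [75.3, 120.0, 200.0]])
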