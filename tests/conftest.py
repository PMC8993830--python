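import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from mrmediation.simulate import SimConfig, simulate_study
from mrmediation.sumstats import SummaryStats

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def make_stats():
    """Factory for small SummaryStats fixtures; fills canonical defaults."""

    def _make(rows, name="trait", trait_type="quantitative", unit="SD"):
        full = []
        for i, r in enumerate(rows):
            base = {"SNP": f"rs{i + 1}", "CHR": "1", "POS": (i + 1) * 1000,
                    "EA": "A", "OA": "G", "EAF": 0.3, "BETA": 0.1, "SE": 0.01,
                    "P": 1e-10, "N": 10_000}
            base.update(r)
            full.append(base)
        return SummaryStats(name, pd.DataFrame(full), trait_type, unit)

    return _make


@pytest.fixture(scope="session")
def default_binary_study():
    """One full default-scenario study (binary outcome, calibrated baseline)."""
    return simulate_study(SimConfig(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
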