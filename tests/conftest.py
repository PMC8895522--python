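import numpy as np
import pytest
from hypothesis import settings

from loop2target import simulate

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_panel() -> simulate.GenotypePanel:
    """200 individuals, 10 blocks x 10 variants, AR(0.6) within blocks."""
    return simulate.simulate_panel(200, 10, 10, 0.6, seed=7)


@pytest.fixture(scope="session")
def nold_panel() -> simulate.GenotypePanel:
    """500 individuals, no LD (rho = 0)."""
    return simulate.simulate_panel(500, 4, 25, 0.0, seed=11)


def dosage_r2(panel: simulate.GenotypePanel, i: int, j: int) -> float:
    """Brute-force r-squared on two dosage columns (test oracle)."""
    a = panel.dosages[:, i].astype(float)
    b = panel.dosages[:, j].astype(float)
    am, bm = a - a.mean(), b - b.mean()
    return float((am @ bm) ** 2 / ((am @ am) * (bm @ bm)))
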