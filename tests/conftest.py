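import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from acehealth import SimulationConfig
from acehealth.simulate import generate_cohort

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cohort() -> pd.DataFrame:
    """A mid-size complete cohort under the default study conditions."""
    return generate_cohort(SimulationConfig(n_individuals=6000, seed=11))


def saturated_two_group_frame(
    risks: dict[tuple[int, int], float],
    cell_n: int = 1000,
    group: str = "White",
    referent: str = "Multiracial",
) -> pd.DataFrame:
    """Individual-level frame realizing an exact 2x2 risk table.

    ``risks[(g, e)]`` is the risk in the cell (group indicator g, exposure
    e); each cell contributes ``cell_n`` unit-weight rows (each its own
    cluster) with exactly ``risk * cell_n`` cases, so a saturated model
    reproduces the risks exactly and the sandwich variance matches the
    usual binomial uncertainty.
    """
    frames = []
    offset = 0
    for (g, e), risk in risks.items():
        cases = round(risk * cell_n)
        frames.append(pd.DataFrame({
            "stratum": 1,
            "cluster": offset + np.arange(cell_n),
            "weight": 1.0,
            "race": group if g else referent,
            "elevated_aces": e,
            "y": np.r_[np.ones(cases), np.zeros(cell_n - cases)],
        }))
        offset += cell_n
    return pd.concat(frames, ignore_index=True)


@pytest.fixture
def two_by_two_risks() -> pd.DataFrame:
    return saturated_two_group_frame(
        {(0, 0): 0.10, (0, 1): 0.20, (1, 0): 0.15, (1, 1): 0.40}
    )


def weighted_share_se(weights: np.ndarray, p: float) -> float:
    """Approximate SE of a weighted proportion via the design effect."""
    w = np.asarray(weights, dtype=float)
    n_eff = w.sum() ** 2 / np.sum(w**2)
    return float(np.sqrt(p * (1 - p) / n_eff))
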