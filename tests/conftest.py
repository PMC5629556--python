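import numpy as np
import pandas as pd
import pytest

from rxagsp.datatypes import ExpressionCohort
from rxagsp.synthetic_data import SimulationConfig, simulate_cohorts


@pytest.fixture(scope="session")
def small_study():
    """One small planted study shared by read-only tests."""
    cfg = SimulationConfig(n_genes=400, n_samples_per_cohort=60, seed=11)
    return simulate_cohorts(cfg)


@pytest.fixture()
def two_batch_cohort():
    """Cohort of two batches from the same generator plus a +2.0 shift on batch B."""
    rng = np.random.default_rng(5)
    n_genes, n_per = 300, 100
    genes = [f"g{i}" for i in range(n_genes)]
    samples = [f"s{i}" for i in range(2 * n_per)]
    base = rng.normal(7, 1, size=(n_genes, 2 * n_per))
    base[:, n_per:] += 2.0
    batch = pd.Series(["A"] * n_per + ["B"] * n_per, index=samples)
    status = pd.Series(rng.choice(["MA", "MN"], size=2 * n_per), index=samples)
    return ExpressionCohort(
        values=pd.DataFrame(base, index=genes, columns=samples),
        name="two_batch", platform="P1", batch=batch, mycn_status=status,
    )


def make_cohort(values, name="c1", platform="P1", status=None, batch=None):
    genes = [f"g{i}" for i in range(values.shape[0])]
    samples = [f"{name}_s{i}" for i in range(values.shape[1])]
    df = pd.DataFrame(values, index=genes, columns=samples)
    return ExpressionCohort(
        values=df,
        name=name,
        platform=platform,
        batch=pd.Series(batch if batch is not None else name, index=samples),
        mycn_status=pd.Series(
            status if status is not None else ["MA", "MN"] * (len(samples) // 2)
            + ["MA"] * (len(samples) % 2),
            index=samples,
        ),
    )
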