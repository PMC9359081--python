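import numpy as np
import pandas as pd
import pytest

from nlnc import ExpressionMatrix, SimulationConfig, simulate_cohort


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """3 genes x 2 samples with both biotypes."""
    values = pd.DataFrame(
        [[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]],
        index=["M1", "M2", "L1"],
        columns=["S1", "S2"],
    )
    biotype = pd.Series({"M1": "mRNA", "M2": "mRNA", "L1": "lncRNA"})
    return ExpressionMatrix(values, biotype)


@pytest.fixture(scope="session")
def small_cohort():
    """A compact planted cohort shared by read-only tests."""
    cfg = SimulationConfig(
        n_samples=200, n_mrna=120, n_lncrna=60, notch_set_size=20,
        n_driver_lnc=10, n_prognostic_lnc=4, driver_effect=0.5, seed=2024,
    )
    return simulate_cohort(cfg)


def random_expression(rng: np.random.Generator, n_mrna: int, n_lnc: int, n: int) -> ExpressionMatrix:
    """Unstructured random matrix helper for unit tests."""
    genes = [f"M{i}" for i in range(n_mrna)] + [f"L{i}" for i in range(n_lnc)]
    values = pd.DataFrame(
        rng.normal(size=(n_mrna + n_lnc, n)),
        index=genes, columns=[f"S{i}" for i in range(n)],
    )
    biotype = pd.Series(["mRNA"] * n_mrna + ["lncRNA"] * n_lnc, index=genes)
    return ExpressionMatrix(values, biotype)
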