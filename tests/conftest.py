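import numpy as np
import pandas as pd
import pytest

from coaction.io import ExpressionMatrix, GeneListPair
from coaction.phenotype import scale_iap
from coaction.synthetic import PlantedPair, SimulationConfig, simulate_cohort


@pytest.fixture
def toy_expr() -> ExpressionMatrix:
    """4 genes x 6 samples with one missing cell."""
    rng = np.random.default_rng(42)
    data = pd.DataFrame(
        rng.lognormal(3.0, 1.0, size=(4, 6)),
        index=["G1", "G2", "G3", "G4"],
        columns=[f"S{i}" for i in range(6)],
    )
    data.iloc[2, 1] = np.nan
    return ExpressionMatrix(data)


@pytest.fixture
def random_cohort():
    """Factory for small random cohorts (no planted structure)."""

    def make(n_samples=40, n_genes=6, seed=0):
        rng = np.random.default_rng(seed)
        genes = [f"G{i}" for i in range(n_genes)]
        samples = [f"S{i}" for i in range(n_samples)]
        expr = ExpressionMatrix(
            pd.DataFrame(
                rng.lognormal(2.0, 1.0, size=(n_genes, n_samples)),
                index=genes, columns=samples,
            )
        )
        iap_raw = pd.Series(
            rng.normal(0.0, 1.0, size=n_samples), index=samples, name="iap"
        )
        return expr, scale_iap(iap_raw)

    return make


@pytest.fixture(scope="session")
def planted_cohort():
    """A 400-sample cohort with one strong planted both-activating pair."""
    cfg = SimulationConfig(
        n_samples=400,
        n_null_genes=300,
        planted=(PlantedPair("TAPG", "ICPG", "act_act"),),
        seed=11,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def planted_lists(planted_cohort) -> GeneListPair:
    taps = ["TAPG"] + [f"NULL{i:04d}" for i in range(5)]
    icps = ["ICPG"] + [f"NULL{i:04d}" for i in range(5, 11)]
    return GeneListPair.from_lists(taps, icps, planted_cohort.expr)
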