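import numpy as np
import pandas as pd
import pytest

from trialomics.io import AlterationTable, ClinicalTable, CountMatrix
from trialomics.simulate import ExpressionConfig, SimulationConfig, simulate_cohort

# compact expression block: enough genes for filtering/normalization/NTP
# without slowing the suite down
SMALL_EXPR = ExpressionConfig(n_genes=120, markers_per_class=20, n_classes=2)


def small_config(seed: int, **kwargs) -> SimulationConfig:
    kwargs.setdefault("expression", SMALL_EXPR)
    kwargs.setdefault("n_deg_genes", 20)
    return SimulationConfig(seed=seed, **kwargs)


def null_config(seed: int, **kwargs) -> SimulationConfig:
    """All planted hazard ratios 1: no survival effect anywhere."""
    kwargs.setdefault(
        "planted_resistance_genes", tuple((f"RESG{i}", 1.0) for i in range(1, 6))
    )
    kwargs.setdefault(
        "planted_sensitivity_genes", tuple((f"SENSG{i}", 1.0) for i in range(1, 6))
    )
    return small_config(seed, **kwargs)


@pytest.fixture(scope="session")
def cohort():
    """One deterministic mid-sized synthetic cohort shared across tests."""
    return simulate_cohort(small_config(seed=11))


@pytest.fixture()
def clinical_frame():
    def make(rows):
        df = pd.DataFrame(
            rows,
            columns=[
                "patient_id", "msi_status", "ras_status", "braf_status",
                "pfs_months", "pfs_event", "best_response",
            ],
        )
        return ClinicalTable(df)

    return make


@pytest.fixture()
def alteration_frame():
    def make(records, tmb=None):
        rec = pd.DataFrame(
            records, columns=["patient_id", "gene", "alteration_class"]
        )
        if tmb is None:
            ids = sorted(set(rec["patient_id"]))
            tmb = pd.Series([5.0] * len(ids), index=ids)
        return AlterationTable(rec, tmb)

    return make


@pytest.fixture()
def count_matrix():
    def make(array, genes=None, samples=None):
        array = np.asarray(array)
        genes = genes or [f"g{i}" for i in range(array.shape[0])]
        samples = samples or [f"s{j}" for j in range(array.shape[1])]
        return CountMatrix(pd.DataFrame(array, index=genes, columns=samples))

    return make
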