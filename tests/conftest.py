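import numpy as np
import pandas as pd
import pytest

from spatimmune import CellTable, PairMode, SimulationConfig, simulate_cohort


def make_cells(records, window=(600.0, 450.0)):
    """Build a CellTable from (patient, roi, panel, x, y, phenotype, flags) dicts."""
    df = pd.DataFrame(records)
    for col, default in (("patient_id", "PT1"), ("roi_id", "R1"), ("panel", "P1")):
        if col not in df.columns:
            df[col] = default
    wins = {r: window for r in df["roi_id"].unique()}
    return CellTable(df, wins)


@pytest.fixture(scope="session")
def small_cohort():
    """Cell-level cohort small enough for per-test feature computation."""
    cfg = SimulationConfig(
        n_patients=8,
        rois_per_patient=(4, 6),
        seed=11,
        pair_modes={("PD1Tc", "PDL1"): PairMode("colocalized", sigma_range=(10, 120))},
        response_coefs={"TIL": 1.5},
    )
    return simulate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
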