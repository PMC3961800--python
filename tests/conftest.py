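import numpy as np
import pandas as pd
import pytest

from rfrs import ClinicalTable, ExpressionMatrix, SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A modest multi-study cohort shared by read-only tests."""
    return generate_cohort(
        SimulationConfig(n_samples=300, n_features=200, n_signal_features=30, seed=7)
    )


@pytest.fixture()
def toy_expression():
    """4 samples x 5 features with hand-set positive values."""
    rng = np.random.default_rng(42)
    vals = pd.DataFrame(
        rng.uniform(50, 500, size=(4, 5)),
        index=[f"s{i}" for i in range(4)],
        columns=[f"f{i}" for i in range(5)],
    )
    return ExpressionMatrix(vals, {f"f{i}": f"g{i}" for i in range(5)})


def make_clinical(rows):
    """Helper: build a ClinicalTable from (id, study, er, her2, ln, chemo,
    hormone, event, years) tuples."""
    cols = ["sample_id", "study_id", "er_clinical", "her2_clinical", "ln_status",
            "chemo", "hormone_therapy", "relapse_event", "followup_years"]
    return ClinicalTable(pd.DataFrame(rows, columns=cols))
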