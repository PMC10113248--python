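import numpy as np
import pandas as pd
import pytest

from abitraj import (
    CohortTable,
    RunConfig,
    SimulationConfig,
    Variable,
    VariableDictionary,
    run_pipeline,
    simulate_mixed_cohort,
)


@pytest.fixture(scope="session")
def tiny_dictionary() -> VariableDictionary:
    return VariableDictionary(
        [
            Variable("age", "continuous", time_invariant=True),
            Variable("crs_r", "continuous"),
            Variable(
                "feeding_modality",
                "categorical",
                ("Oral", "Parenteral", "PEG", "NG tube"),
            ),
        ]
    )


@pytest.fixture()
def tiny_cohort_csv(tmp_path, tiny_dictionary):
    """Well-formed 3-patient long-format cohort file."""
    rows = []
    for pid, gos, times in (
        ("A", 5, (20, 150, 200)),
        ("B", 3, (35, 170, 210)),
        ("C", 1, (50, 180, 230)),
    ):
        for ev, t in zip(("T0", "T1", "T2"), times):
            rows.append(
                {
                    "patient_id": pid,
                    "evaluation": ev,
                    "eval_time": t,
                    "gos": gos,
                    "age": 50 + times[0] % 7,
                    "crs_r": 5 + t / 20,
                    "feeding_modality": "PEG" if gos < 4 else "Oral",
                }
            )
    path = tmp_path / "cohort.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


@pytest.fixture(scope="session")
def default_cohort() -> CohortTable:
    """Synthetic cohort at the default study conditions."""
    return simulate_mixed_cohort(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def pipeline_report():
    """One full pipeline run at the default study conditions."""
    return run_pipeline(RunConfig(seed=1))
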