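import numpy as np
import pandas as pd
import pytest

from fundus_dca import ClassifierSpec, CohortSpec, simulate_cohort
from fundus_dca import reference as ref


@pytest.fixture(scope="session")
def screening_operating_points():
    """Per-model (sensitivity dict, specificity) from the published
    community-screening counts."""
    out = {}
    for model in ref.MODELS:
        perf = ref.screening_performance(model)
        out[model] = (perf.sensitivity_by_disease, perf.specificity)
    return out


@pytest.fixture(scope="session")
def urban_spec():
    return CohortSpec(
        diseases=ref.DISEASES,
        prevalence_by_disease=ref.ILLUSTRATIVE_PREVALENCE["urban"],
        cohort_size=ref.HYPOTHETICAL_COHORT_SIZE,
        setting_label="urban",
    )


@pytest.fixture(scope="session")
def retfound_clf(screening_operating_points):
    sens, spec = screening_operating_points["RETFound-enhanced"]
    return ClassifierSpec(sensitivity_by_disease=sens, specificity=spec,
                          model_name="RETFound-enhanced")


@pytest.fixture(scope="session")
def simulated_urban_cohort(urban_spec, retfound_clf):
    """100k-subject cohort screened at the published operating point."""
    return simulate_cohort(urban_spec, retfound_clf, seed=20260927)


@pytest.fixture()
def perfect_records():
    """Small table where every prediction equals the truth."""
    rng = np.random.default_rng(7)
    classes = np.array(["AMD", "DR", "PM", "normal"], dtype=object)
    truth = classes[rng.integers(0, 4, size=200)]
    return pd.DataFrame(
        {
            "record_id": [f"r{i}" for i in range(200)],
            "true_class": truth,
            "predicted_class": truth.copy(),
            "model_name": "oracle",
        }
    )
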