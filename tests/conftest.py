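import numpy as np
import pytest

from deprisk import risk_model as rm
from deprisk import synthetic_cohort as sc


@pytest.fixture(scope="session")
def raw_survey_fixture():
    """One raw survey draw with the packaged default flow counts."""
    return sc.generate_raw_survey(seed=3)


@pytest.fixture(scope="session")
def fitted_model_and_validation():
    """A development-model fit plus a coded validation sample.

    Session-scoped because several transport tests reuse the same pair.
    """
    dev = sc.generate_development_cohort(sc.development_spec(n=8000, seed=5))
    X = rm.encode_design(dev.data)
    y = dev.data["depressed_followup"].to_numpy(float)
    model = rm.fit_penalized(X, y, penalty=1.0)
    val = sc.generate_validation_cohort(sc.validation_spec(n=2000, seed=6))
    Xv = rm.encode_design(val.data).loc[:, list(model.terms)]
    yv = val.data["depressed_followup"].to_numpy(float)
    return model, Xv, yv


def pairwise_auc(scores, labels):
    """O(n^2) concordance oracle: all case/non-case pairs, ties count 0.5."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    cases = scores[labels == 1]
    controls = scores[labels != 1]
    total = 0.0
    for s in cases:
        total += (s > controls).sum() + 0.5 * (s == controls).sum()
    return total / (len(cases) * len(controls))
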