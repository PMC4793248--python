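import numpy as np
import pandas as pd
import pytest

from attmatch import ScenarioSpec, StudyData, generate_dataset, get_scenario


@pytest.fixture(scope="session")
def good_spec():
    return get_scenario("good")


@pytest.fixture(scope="session")
def poor_spec():
    return get_scenario("poor")


@pytest.fixture(scope="session")
def good_data(good_spec):
    return generate_dataset(good_spec, n=1000, seed=7)


@pytest.fixture(scope="session")
def randomized_spec():
    """Treatment independent of covariates: every estimator should be unbiased."""
    return ScenarioSpec(
        name="good",
        treat_coefs=(-0.5, 0.0, 0.0, 0.0, 0.0),
        out_coefs=(1.0, 2.0, 1.0, 0.7, 1.0),
        effect_coefs=(2.0, 1.0),
        noise_sd=1.0,
    )


def make_study(w_treated, w_control, y_treated=None, y_control=None, extra_cols=None):
    """Hand-built study with one covariate column 'X' (plus optional extras)."""
    w_treated = np.asarray(w_treated, dtype=float)
    w_control = np.asarray(w_control, dtype=float)
    nt, nc = len(w_treated), len(w_control)
    x = np.concatenate([w_treated, w_control])
    a = np.concatenate([np.ones(nt, int), np.zeros(nc, int)])
    if y_treated is None:
        rng = np.random.default_rng(0)
        y = rng.normal(size=nt + nc)
    else:
        y = np.concatenate([np.asarray(y_treated, float), np.asarray(y_control, float)])
    cov = pd.DataFrame({"X": x})
    if extra_cols:
        for k, v in extra_cols.items():
            cov[k] = v
    return StudyData(covariates=cov, treatment=a, outcome=y)
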