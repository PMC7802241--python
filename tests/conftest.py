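import numpy as np
import pytest

import pammkit as pk
from pammkit.simulate import CovariateEffect


@pytest.fixture(scope="session")
def toy_histories():
    """Three hand-built subjects with known episodes."""
    return [
        pk.SubjectHistory("A", 0.0, 728.0, [100.0, 250.0], {"x": 1.0}, birth_day_of_year=360),
        pk.SubjectHistory("B", 0.0, 300.0, [], {"x": 0.0}, birth_day_of_year=1),
        pk.SubjectHistory("C", 0.0, 728.0, [45.0], {"x": 0.0}, birth_day_of_year=152),
    ]


@pytest.fixture(scope="session")
def small_cohort():
    """A 120-subject cohort with a constant-HR binary covariate and frailty."""
    scn = pk.dchs_like_scenario(
        n_subjects=120,
        seed=42,
        covariates={"x": CovariateEffect(prevalence=0.5, beta1=np.log(1.5))},
    )
    hist, truth = pk.simulate_cohort(scn)
    return hist, truth


@pytest.fixture(scope="session")
def small_ped(small_cohort):
    hist, _ = small_cohort
    win = pk.StudyWindow()
    grid = pk.CutpointGrid(np.linspace(0.0, 728.0, 21))
    return pk.split_to_ped(hist, grid, win)


@pytest.fixture(scope="session")
def fitted_model1(small_ped):
    return pk.fit(small_ped, pk.ModelSpec(covariate="x", baseline_k=8, frailty=True))
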