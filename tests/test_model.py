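"""Fitting engine: analytic collapses, optimizer oracles, EDF, frailty.

Independent oracles: the closed-form Poisson MLE for the intercept-only
model, statsmodels' unpenalized GLM for the infinite-smoothing collapse,
and a generic scipy optimizer run on the same penalized objective.
"""

import numpy as np
import pandas as pd
import pytest
import scipy.optimize

import pammkit as pk
from pammkit.model import ModelSpec, build_design, _assemble_S


def test_intercept_only_closed_form(small_ped):
    """exp(b0) must equal total events / total person-time (Poisson MLE)."""
    f = pk.fit(small_ped, ModelSpec(covariate=None, baseline=False, frailty=False))
    expected = small_ped["event"].sum() / small_ped["exposure"].sum()
    assert np.exp(f.beta[0]) == pytest.approx(expected, abs=1e-8 * expected)
    assert f.edf_by_term["intercept"] == pytest.approx(1.0, abs=1e-10)


def test_infinite_smoothing_collapses_to_glm(small_ped):
    """lambda -> infinity leaves only the penalty null space: the fit must
    agree with an unpenalized GLM on [1, x, t] (coefficients of the
    parametric part and all fitted values)."""
    import statsmodels.api as sm

    f = pk.fit(
        small_ped,
        ModelSpec(covariate="x", baseline_k=8, frailty=False),
        lambdas={"f0": 1e10},
    )
    X = np.column_stack(
        [np.ones(len(small_ped)), small_ped["x"], small_ped["t_j"] / 728.0]
    )
    glm = sm.GLM(
        small_ped["event"].to_numpy(),
        X,
        family=sm.families.Poisson(),
        offset=small_ped["offset"].to_numpy(),
    ).fit(tol=1e-12)
    i1 = f.design.terms["x"].sl.start
    assert f.beta[i1] == pytest.approx(glm.params[1], abs=1e-6)
    eta_pk = f.design.X @ f.beta
    eta_glm = X @ glm.params
    assert np.max(np.abs(eta_pk - eta_glm)) < 1e-6


def test_agreement_with_generic_optimizer(small_cohort):
    """At fixed smoothing parameters the P-IRLS solution must agree with a
    quasi-Newton optimizer run on the same penalized Poisson objective."""
    hists, _ = small_cohort
    hists = hists[:30]
    grid = pk.CutpointGrid(np.linspace(0, 728, 9))
    ped = pk.split_to_ped(hists, grid, pk.StudyWindow())
    spec = ModelSpec(covariate="x", baseline_k=5, frailty=True)
    lam = {"f0": 3.0}
    sig = 0.6
    f = pk.fit(ped, spec, lambdas=lam, sigma_frailty=sig)

    d = build_design(ped, spec)
    S_d = _assemble_S(d, np.array([3.0]))
    codes = d.frailty_codes
    n_s = len(d.subjects)
    p = d.X.shape[1]

    def negobj(theta):
        beta, b = theta[:p], theta[p:]
        eta = d.offset + d.X @ beta + b[codes]
        ll = d.y @ eta - np.exp(eta).sum()
        return -(ll - 0.5 * beta @ S_d @ beta - 0.5 * (1 / sig**2) * b @ b)

    x0 = np.zeros(p + n_s)
    res = scipy.optimize.minimize(negobj, x0, method="L-BFGS-B", options={"maxiter": 2000, "ftol": 1e-15, "gtol": 1e-10})
    assert res.success
    assert np.max(np.abs(f.beta - res.x[:p])) < 1e-5
    assert np.max(np.abs(f.frailty_blups.to_numpy() - res.x[p:])) < 1e-5


def test_edf_properties(fitted_model1):
    f = fitted_model1
    # parametric columns have EDF exactly 1
    assert f.edf_by_term["intercept"] == pytest.approx(1.0, abs=1e-9)
    assert f.edf_by_term["x"] == pytest.approx(1.0, abs=1e-9)
    # smooth EDF bounded by its column count
    assert 0 < f.edf_by_term["f0"] <= f.design.terms["f0"].sl.stop - f.design.terms["f0"].sl.start
    with pytest.raises(ValueError, match="unknown"):
        pk.edf(f, "nope")


def test_edf_limit_infinite_penalty(small_ped):
    """lambda -> infinity drives the smooth's EDF to its null-space
    dimension inside the constrained term (1: the linear direction)."""
    f = pk.fit(small_ped, ModelSpec(covariate=None, baseline_k=8, frailty=False), lambdas={"f0": 1e10})
    assert f.edf_by_term["f0"] == pytest.approx(1.0, abs=1e-3)


def test_row_order_invariance(small_ped):
    """Shuffling PED rows must not change the fit."""
    spec = ModelSpec(covariate="x", baseline_k=6, frailty=True)
    lam = {"f0": 2.0}
    f1 = pk.fit(small_ped, spec, lambdas=lam, sigma_frailty=0.5)
    shuffled = small_ped.sample(frac=1.0, random_state=1).reset_index(drop=True)
    f2 = pk.fit(shuffled, spec, lambdas=lam, sigma_frailty=0.5)
    h1 = pk.hazard_curve(f1, {"x": 0.0})
    h2 = pk.hazard_curve(f2, {"x": 0.0})
    assert np.allclose(h1.estimate, h2.estimate, rtol=1e-8)
    i1, i2 = f1.design.terms["x"].sl.start, f2.design.terms["x"].sl.start
    assert f1.beta[i1] == pytest.approx(f2.beta[i2], abs=1e-8)


def test_smooth_test_zero_coefficients(fitted_model1):
    """A smooth whose coefficients are exactly zero gives statistic 0, p=1."""
    import copy

    f = copy.copy(fitted_model1)
    f.beta = fitted_model1.beta.copy()
    f.beta[f.design.terms["f0"].sl] = 0.0
    stat, rank, p = pk.smooth_test(f, "f0")
    assert stat == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_smooth_test_rejects_parametric(fitted_model1):
    with pytest.raises(ValueError):
        pk.smooth_test(fitted_model1, "x")


def test_frailty_recovery():
    """sigma = 0.5 world: sigma-hat lands in [0.3, 0.7] at n = 1000."""
    scn = pk.dchs_like_scenario(n_subjects=1000, seed=77)
    hists, _ = pk.simulate_cohort(scn)
    ped = pk.split_to_ped(hists, pk.CutpointGrid(np.linspace(0, 728, 31)), pk.StudyWindow())
    f = pk.fit(ped, ModelSpec(covariate=None, frailty=True))
    assert 0.3 <= f.sigma_frailty <= 0.7


def test_degenerate_ped_rejected():
    ped = pd.DataFrame(
        {"id": ["a"], "j": [1], "tstart": [0.0], "tend": [10.0], "t_j": [10.0],
         "exposure": [10.0], "offset": [np.log(10.0)], "event": [0]}
    )
    with pytest.raises(ValueError, match="degenerate"):
        pk.fit(ped, ModelSpec(covariate=None, frailty=False))


def test_separation_warning(small_ped):
    ped = small_ped.copy()
    ped["allzero"] = (ped["id"] == ped["id"].iloc[0]).astype(float)
    ped.loc[ped["allzero"] == 1.0, "event"] = 0
    with pytest.warns(RuntimeWarning, match="zero events"):
        try:
            pk.fit(ped, ModelSpec(covariate="allzero", baseline=False, frailty=False))
        except RuntimeError:
            pass  # separation may legitimately stall convergence


def test_summary_is_json_exportable(fitted_model1):
    import json

    s = fitted_model1.summary()
    json.dumps(s)
    assert s["terms"]["x"]["hr"] > 0
    assert "edf" in s["terms"]["f0"]
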