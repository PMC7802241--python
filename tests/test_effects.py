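"""Hazard / HR / cumulative-incidence curves, model selection, season grids."""

import numpy as np
import pandas as pd
import pytest

import pammkit as pk
from pammkit.effects import YEAR_DAYS, season_label
from pammkit.model import ModelSpec, TensorSpec


def test_incidence_is_hazard_times_365_25(fitted_model1):
    h = pk.hazard_curve(fitted_model1, {"x": 0.0}, "hazard_per_day")
    inc = pk.hazard_curve(fitted_model1, {"x": 0.0}, "incidence_per_child_year")
    assert np.allclose(inc.estimate, h.estimate * 365.25)
    assert np.allclose(inc.lower, h.lower * 365.25)
    # a constant daily hazard of 0.001 corresponds to 0.36525 episodes/child-year
    assert 0.001 * YEAR_DAYS == pytest.approx(0.36525)


def test_ci_is_monotone_transform_of_linear_predictor(fitted_model1):
    h = pk.hazard_curve(fitted_model1, {"x": 1.0})
    assert np.all(h.lower <= h.estimate) and np.all(h.estimate <= h.upper)
    # log-scale symmetric: log upper - log est == log est - log lower
    assert np.allclose(np.log(h.upper) - np.log(h.estimate), np.log(h.estimate) - np.log(h.lower), atol=1e-10)


def test_hr_curve_flat_for_model1(fitted_model1):
    hr = pk.hazard_ratio_curve(fitted_model1, "x")
    est, _, _ = fitted_model1.parametric_estimate("x")
    assert np.allclose(hr.estimate, np.exp(est), rtol=1e-12)


def test_hr_curve_model2_reduces_to_model1_when_f1_zero(small_ped):
    m2 = pk.fit(small_ped, ModelSpec(covariate="x", baseline_k=6, frailty=False), )
    # force f1 coefficients to zero on a copy of a time-varying fit
    m2v = pk.fit(small_ped, ModelSpec(covariate="x", time_varying=True, baseline_k=6, frailty=False),
                 lambdas={"f0": 1.0, "f1": 1.0})
    m2v.beta[m2v.design.terms["f1"].sl] = 0.0
    hr = pk.hazard_ratio_curve(m2v, "x")
    i1 = m2v.design.terms["x"].sl.start
    assert np.allclose(hr.estimate, np.exp(m2v.beta[i1]), rtol=1e-12)


def test_unknown_covariate_rejected(fitted_model1):
    with pytest.raises(ValueError):
        pk.hazard_ratio_curve(fitted_model1, "nope")
    with pytest.raises(ValueError):
        pk.hazard_curve(fitted_model1, {}, scale="bananas")


class TestCumulativeIncidence:
    def test_closed_form_single_interval(self):
        """Constant hazard h on one interval of length L: 1 - exp(-hL)."""
        h = pk.SubjectHistory("a", 0.0, 728.0, [500.0])
        h2 = pk.SubjectHistory("b", 0.0, 728.0, [])
        ped = pk.split_to_ped([h, h2], pk.CutpointGrid([0.0, 728.0]))
        f = pk.fit(ped, ModelSpec(covariate=None, baseline=False, frailty=False))
        rate = ped["event"].sum() / ped["exposure"].sum()
        cif = pk.cumulative_incidence(f)
        assert cif.estimate[-1] == pytest.approx(1 - np.exp(-rate * 728.0), abs=1e-7)

    def test_orderings(self, fitted_model1):
        c1 = pk.cumulative_incidence(fitted_model1, {"x": 0.0}, which=1)
        c2 = pk.cumulative_incidence(fitted_model1, {"x": 0.0}, which=2)
        assert np.all(np.diff(c1.estimate) >= -1e-12)
        assert np.all(np.diff(c2.estimate) >= -1e-12)
        assert np.all(c1.estimate >= c2.estimate - 1e-12)
        assert np.all((c1.estimate >= 0) & (c1.estimate <= 1))
        assert np.all(c1.lower <= c1.estimate) and np.all(c1.estimate <= c1.upper)

    def test_k_validation(self, fitted_model1):
        with pytest.raises(ValueError):
            pk.cumulative_incidence(fitted_model1, {"x": 0.0}, which=0)


class TestSelection:
    def _fits(self, small_ped):
        m1 = pk.fit(small_ped, ModelSpec(covariate="x", baseline_k=6, frailty=False))
        m2 = pk.fit(small_ped, ModelSpec(covariate="x", time_varying=True, baseline_k=6, frailty=False))
        return m1, m2

    def test_rule_and_boundary(self, small_ped):
        m1, m2 = self._fits(small_ped)
        p = m2.smooth_tests["f1"][2]
        rep = pk.select_final_model(m1, m2, alpha=0.05)
        assert rep["chosen"] == ("model2" if p < 0.05 else "model1")
        # p exactly at alpha -> model 1 (strict inequality)
        rep_b = pk.select_final_model(m1, m2, alpha=p)
        assert rep_b["chosen"] == "model1"
        # report carries Table-2-style numbers
        assert rep["model1"]["ir_group0"]["ir"] > 0
        assert len(rep["model1"]["ci"]) == 2

    def test_mismatched_covariate_rejected(self, small_ped):
        m1, m2 = self._fits(small_ped)
        ped2 = small_ped.rename(columns={"x": "y"})
        m1b = pk.fit(ped2, ModelSpec(covariate="y", baseline_k=6, frailty=False))
        with pytest.raises(ValueError, match="covariate"):
            pk.select_final_model(m1b, m2)


@pytest.fixture(scope="module")
def model3():
    scn = pk.dchs_like_scenario(n_subjects=250, seed=5, frailty_sd=0.5)
    scn.season_effect = lambda t, doy: 0.35 * np.cos(2 * np.pi * (doy - 180) / 365.0)
    hists, _ = pk.simulate_cohort(scn)
    ped = pk.split_to_ped(hists, pk.CutpointGrid(np.linspace(0, 728, 21)), pk.StudyWindow())
    ped = pk.attach_current_season(ped, hists)
    return pk.fit(ped, ModelSpec(tensor=TensorSpec(season_col="current_doy", S=6, M=6), frailty=True))


class TestSeason:
    def test_season_labels(self):
        # southern-hemisphere calendar: winter is 1 June - 31 August
        assert season_label(152) == "Winter" and season_label(243) == "Winter"
        assert season_label(151) == "Autumn" and season_label(244) == "Spring"
        assert season_label(1) == "Summer" and season_label(335) == "Summer"
        with pytest.raises(ValueError):
            season_label(0)

    def test_grids(self, model3):
        inc, hr = pk.season_grids(model3, "current_season", age_step=14.0, doy_step=7.0)
        # HR at day 1 is exactly 1 at every age (self-reference)
        assert np.allclose(hr.values[:, 0], 1.0, atol=1e-12)
        # periodic wrap: day 365 column adjacent-continuous with day 1
        step = np.abs(np.diff(hr.values, axis=1)).max()
        wrap = np.abs(hr.values[:, -1] - hr.values[:, 0]).max()
        assert wrap <= max(2 * step, 0.05)
        assert np.all(inc.values > 0)

    def test_variant_validation(self, model3, fitted_model1):
        with pytest.raises(ValueError):
            pk.season_grids(model3, "nope")
        with pytest.raises(ValueError, match="tensor"):
            pk.season_grids(fitted_model1, "current_season")
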