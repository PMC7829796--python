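"""Stepwise response models, efficacy ratios, correlations."""

import numpy as np
import pandas as pd
import pytest

from canopyflux import stats, synth
from canopyflux.reference import load_reference_coefficients, reference_efficacy
from canopyflux.stats import (
    LinearModelFit,
    correlate,
    efficacy_ratio,
    fit_response_model,
    per_unit_slope,
)


@pytest.fixture(scope="module")
def grid():
    field = synth.make_light_field(synth.STUDY2_PERPENDICULAR, seed=0)
    return field.rename(columns={})


def _table(field, y):
    out = field.copy()
    out["y"] = y
    return out


class TestStepwise:
    def test_zero_noise_two_slope_model_identified(self, grid):
        fr = grid["fr_umol_m2_s"]
        ppfd = grid["ppfd_umol_m2_s"]
        y = -0.50 + 0.00815 * fr + 0.00520 * ppfd
        fit = fit_response_model(_table(grid, y), "y")
        assert set(fit.terms) == {"fr", "ppfd"}
        assert fit.coef["intercept"] == pytest.approx(-0.50, rel=1e-8)
        assert fit.coef["fr"] == pytest.approx(0.00815, rel=1e-8)
        assert fit.coef["ppfd"] == pytest.approx(0.00520, rel=1e-8)

    def test_single_predictor_submodel_recovered(self, grid):
        y = 2.0 * grid["fr_umol_m2_s"]
        fit = fit_response_model(_table(grid, y), "y")
        assert fit.terms == ("fr",)
        assert fit.coef["fr"] == pytest.approx(2.0, rel=1e-10)

    def test_zero_noise_submodel_recovery_is_exact(self, grid):
        # elimination on data from any sub-model returns exactly that sub-model
        cases = {
            (): lambda fr, ppfd: np.full_like(fr, 3.0),
            ("fr",): lambda fr, ppfd: 1 + 0.1 * fr,
            ("ppfd",): lambda fr, ppfd: 1 - 0.01 * ppfd,
            ("fr", "ppfd"): lambda fr, ppfd: 1 + 0.1 * fr + 0.01 * ppfd,
        }
        for terms, f in cases.items():
            y = f(grid["fr_umol_m2_s"].to_numpy(), grid["ppfd_umol_m2_s"].to_numpy())
            fit = fit_response_model(_table(grid, y), "y")
            assert set(fit.terms) == set(terms), terms

    def test_interaction_survives_when_real(self, grid):
        fr = grid["fr_umol_m2_s"].to_numpy()
        ppfd = grid["ppfd_umol_m2_s"].to_numpy()
        rng = np.random.default_rng(1)
        y = 0.5 + 0.02 * fr + 0.004 * ppfd + 0.003 * (fr - fr.mean()) * (ppfd - ppfd.mean())
        y = y + rng.normal(0, 0.05, y.size)
        fit = fit_response_model(_table(grid, y), "y")
        assert "fr:ppfd" in fit.terms

    def test_type_one_error_rate_near_alpha(self, grid):
        # pure-noise responses: FR survives only by chance
        rng = np.random.default_rng(99)
        kept_fr = 0
        n_rep = 300
        for _ in range(n_rep):
            y = rng.normal(0, 1, len(grid))
            fit = fit_response_model(_table(grid, y), "y")
            kept_fr += "fr" in fit.terms
        # retention combines the interaction path and the main-effect test;
        # simulation-calibrated band around the nominal 5% level
        assert 0.01 <= kept_fr / n_rep <= 0.18

    def test_rank_deficient_design_rejected(self, grid):
        bad = grid.copy()
        bad["ppfd_umol_m2_s"] = 200.0
        bad["y"] = 1.0
        with pytest.raises(ValueError, match="constant predictor"):
            fit_response_model(bad, "y")


class TestEfficacy:
    def test_reference_early_incident_light(self):
        eff = reference_efficacy("incident_light", "early")
        assert eff.percent_more_effective == pytest.approx(56.73, abs=0.01)
        assert eff.percent_rounded == 57

    def test_reference_late_incident_light(self):
        eff = reference_efficacy("incident_light", "late")
        assert eff.percent_more_effective == pytest.approx(183.08, abs=0.01)
        assert eff.percent_rounded == 183

    def test_equal_slopes_give_zero(self):
        fit = LinearModelFit(
            response="y",
            terms=("fr", "ppfd"),
            coef={"intercept": 0.0, "fr": 0.5, "ppfd": 0.5},
            se={},
            p_values={},
            conf_int={},
            r_squared=1.0,
            n=10,
            alpha=0.05,
        )
        assert efficacy_ratio(fit).percent_more_effective == 0.0

    def test_requires_both_slopes(self, grid):
        y = 2.0 * grid["fr_umol_m2_s"]
        fit = fit_response_model(_table(grid, y), "y")
        with pytest.raises(ValueError, match="retained"):
            efficacy_ratio(fit)

    def test_invariant_under_response_rescaling(self, grid):
        rng = np.random.default_rng(5)
        y = 1 + 0.1 * grid["fr_umol_m2_s"] + 0.02 * grid["ppfd_umol_m2_s"]
        y = y + rng.normal(0, 0.1, len(y))
        e1 = efficacy_ratio(fit_response_model(_table(grid, y), "y"))
        e2 = efficacy_ratio(fit_response_model(_table(grid, 10 * y), "y"))
        assert e1.percent_more_effective == pytest.approx(e2.percent_more_effective, rel=1e-9)

    def test_reference_table_shape(self):
        table = load_reference_coefficients()
        assert len(table) == 8
        assert set(table["harvest"]) == {"early", "late"}


class TestCorrelate:
    def test_exact_line(self):
        x = np.linspace(0, 10, 20)
        c = correlate(x, 3 * x + 1)
        assert c.pearson_r == pytest.approx(1.0)
        assert c.slope == pytest.approx(3.0)
        assert c.intercept == pytest.approx(1.0)

    def test_independent_samples_weakly_correlated(self):
        rng = np.random.default_rng(2)
        c = correlate(rng.normal(size=1000), rng.normal(size=1000))
        assert abs(c.pearson_r) < 0.1

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_synthetic_width_area_correlation(self, noisy_experiment):
        exp = noisy_experiment
        m = exp.harvest[exp.harvest["harvest"] == "early"]
        c = correlate(m["leaf_width_cm"], m["leaf_area_cm2"])
        assert c.pearson_r > 0
        assert c.p_value < 0.05


class TestPerUnitSlope:
    def test_exact_slope(self, grid):
        y = 0.099 * grid["fr_umol_m2_s"] + 1.0
        slope, p = per_unit_slope(_table(grid, y), "y", "fr_umol_m2_s")
        assert slope == pytest.approx(0.099, rel=1e-10)
        assert p < 1e-10

    def test_constant_response(self, grid):
        slope, p = per_unit_slope(_table(grid, 5.0), "y", "fr_umol_m2_s")
        assert slope == 0.0
        assert p == pytest.approx(1.0)

    def test_study1_zero_noise_round_trip(self):
        # single-gradient study: FR slope of leaf length recovered exactly
        morph = dict(synth.DEFAULT_MORPHOLOGY)
        morph[("length", "early")] = (10.0, 0.099, 0.0)
        params = synth.TruePlantParams(morphology=morph).without_noise()
        exp = synth.simulate_experiment(
            gradient=synth.STUDY1_FR_GRADIENT, params=params, seed=4
        )
        m = exp.harvest.merge(exp.light_field, on="plant_id")
        early = m[m["harvest"] == "early"]
        slope, p = per_unit_slope(early, "leaf_length_cm", "fr_umol_m2_s")
        assert slope == pytest.approx(0.099, rel=1e-9)
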