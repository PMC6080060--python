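import numpy as np
import pytest

from spiroref import ModelSpec, Sex, build_design, fit_ols, refit_paper_models
from spiroref.errors import SingularDesignError
from spiroref.fitting import fit_model, two_branch_form
from spiroref.local import continuous_basis_coefficients


def _spec(terms, outcome="fev1", sex=Sex.MALE):
    return ModelSpec(outcome=outcome, terms=tuple(terms), sex=sex)


def _frame(ages, heights=None, weights=None, fev1=None, fvc=None):
    import pandas as pd

    n = len(ages)
    return pd.DataFrame(
        {
            "age_years": ages,
            "height_cm": heights if heights is not None else np.full(n, 170.0),
            "weight_kg": weights if weights is not None else np.full(n, 75.0),
            "fev1_l": fev1 if fev1 is not None else np.full(n, 3.0),
            "fvc_l": fvc if fvc is not None else np.full(n, 4.0),
        }
    )


class TestBuildDesign:
    @pytest.mark.parametrize(
        "age, expected", [(25.0, (25.0, 0.0)), (40.0, (25.0, 15.0)), (18.0, (18.0, 0.0))]
    )
    def test_piecewise_age_basis(self, age, expected):
        design, _ = build_design(_frame([age]), _spec(["age_young", "age_old"]))
        assert design[0, 0] == 1.0  # leading intercept column
        assert tuple(design[0, 1:]) == expected

    def test_missing_covariate_errors(self):
        frame = _frame([40.0]).drop(columns=["weight_kg"])
        with pytest.raises(ValueError, match="weight_kg"):
            build_design(frame, _spec(["W"]))

    def test_ln_fvc_response_is_logged(self):
        _, y = build_design(_frame([40.0], fvc=[4.0]), _spec(["H"], outcome="ln_fvc"))
        assert y[0] == pytest.approx(np.log(4.0))


class TestFitOls:
    def test_exact_recovery_of_noiseless_linear_model(self, rng):
        design = np.column_stack([np.ones(50), rng.normal(size=(50, 3))])
        beta = np.array([1.5, -2.0, 0.3, 4.0])
        response = design @ beta
        fm = fit_ols(design, response, _spec(["age_young", "age_old", "H"]))
        assert np.allclose(list(fm.coefficients.values()), beta, atol=1e-8)
        assert fm.residual_sd == pytest.approx(0.0, abs=1e-8)

    def test_constant_response_degenerate(self, rng):
        design = np.column_stack([np.ones(30), rng.normal(size=(30, 2))])
        fm = fit_ols(design, np.full(30, 2.5), _spec(["H", "W"]))
        assert fm.coefficients["H"] == pytest.approx(0.0, abs=1e-10)
        assert fm.coefficients["W"] == pytest.approx(0.0, abs=1e-10)
        assert fm.r_squared == pytest.approx(0.0, abs=1e-12)

    def test_rank_deficiency_names_collinear_columns(self, rng):
        x = rng.normal(size=40)
        design = np.column_stack([np.ones(40), x, 2 * x])
        with pytest.raises(SingularDesignError) as exc:
            fit_ols(design, rng.normal(size=40), _spec(["H", "H2"]))
        assert {"H", "H2"} & set(exc.value.columns)

    def test_agrees_with_normal_equations_oracle(self, rng):
        # brute-force oracle: solve (X'X) b = X'y directly
        for _ in range(10):
            design = np.column_stack([np.ones(20), rng.normal(size=(20, 3))])
            response = rng.normal(size=20)
            fm = fit_ols(design, response, _spec(["age_young", "age_old", "H"]))
            oracle = np.linalg.solve(design.T @ design, design.T @ response)
            assert np.allclose(list(fm.coefficients.values()), oracle, atol=1e-8)
            rss = ((response - design @ oracle) ** 2).sum()
            assert fm.residual_sd == pytest.approx(np.sqrt(rss / 16), rel=1e-8)

    def test_r_squared_invariant_under_covariate_rescaling(self, rng):
        ages = rng.uniform(18, 89, 100)
        y = 2.0 + 0.05 * ages + rng.normal(0, 0.5, 100)
        d1 = np.column_stack([np.ones(100), ages])
        d2 = np.column_stack([np.ones(100), 3.7 * ages + 11.0])
        spec = _spec(["A"])
        assert fit_ols(d1, y, spec).r_squared == pytest.approx(
            fit_ols(d2, y, spec).r_squared, abs=1e-12
        )


class TestRefit:
    def test_noiseless_recovery_of_generating_coefficients(self, noiseless_cohort):
        """Volume models refitted on a zero-noise cohort recover the
        generating (continuous-basis) coefficients essentially exactly."""
        fits = refit_paper_models(noiseless_cohort)
        for (sex, outcome), fm in fits.items():
            if outcome == "ratio":
                continue
            truth = continuous_basis_coefficients(sex, outcome)
            for term, value in fm.coefficients.items():
                expected = truth["intercept"] if term == "intercept" else truth[term]
                assert value == pytest.approx(expected, abs=1e-6), (sex, outcome, term)

    def test_prediction_continuous_at_knot(self, healthy_cohort):
        fm = refit_paper_models(healthy_cohort)[(Sex.MALE, "fev1")]
        below = fm.predict(_frame([25 - 1e-9], heights=[175.0]))
        at = fm.predict(_frame([25.0], heights=[175.0]))
        assert below[0] == pytest.approx(at[0], abs=1e-6)

    def test_residual_sd_recovered_within_10pct(self, healthy_cohort):
        from spiroref.local import residual_sd

        fits = refit_paper_models(healthy_cohort)
        for (sex, outcome), fm in fits.items():
            if outcome == "ratio":
                continue
            truth = residual_sd(sex, outcome)
            assert abs(fm.residual_sd / truth - 1) < 0.10, (sex, outcome)

    def test_missing_stratum_named(self, healthy_cohort):
        males_only = healthy_cohort.subset(Sex.MALE)
        with pytest.raises(ValueError, match="female"):
            refit_paper_models(males_only)

    def test_two_branch_display_form(self, healthy_cohort):
        fm = refit_paper_models(healthy_cohort)[(Sex.FEMALE, "fev1")]
        branches = two_branch_form(fm)
        c = fm.coefficients
        assert branches["intercept_old"] == pytest.approx(
            c["intercept"] + 25 * c["age_young"]
        )
        # the two display branches agree at the knot by construction
        young_at_knot = branches["intercept_young"] + 25 * branches["age_slope_young"]
        assert young_at_knot == pytest.approx(branches["intercept_old"], abs=1e-10)

    def test_exploratory_mode_returns_six_models(self, healthy_cohort):
        fits = refit_paper_models(healthy_cohort, exploratory=True)
        assert len(fits) == 6
        # the piecewise age structure is protected in exploration
        assert "age_young" in fits[(Sex.MALE, "fev1")].spec.terms
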