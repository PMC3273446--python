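import numpy as np
import pandas as pd
import pytest

from fpmort.comparators import (
    WHO_SCHEME,
    bmi_contribution_curve,
    categorize_bmi,
    compare_models,
    fit_comparator,
    narrow_bin_scheme,
    sensitivity_refit,
)
from fpmort.mfp_selection import SelectedForm, linear_form
from fpmort.pipeline import default_covariate_specs
from fpmort.synthetic_data import (
    apply_inclusion,
    default_config,
    generate_cohort,
    generate_null_cohort,
)


@pytest.mark.parametrize(
    "bmi, expected",
    [(25.0, "Overweight"), (18.5, "Normal"), (29.999, "Overweight"),
     (40.0, "Obese III"), (55.0, "Obese III")],
)
def test_categorize_bmi_who(bmi, expected):
    assert categorize_bmi(bmi, WHO_SCHEME) == expected


def test_categorize_below_support_errors():
    with pytest.raises(ValueError):
        categorize_bmi(17.0, WHO_SCHEME)


def test_narrow_bin_scheme_structure():
    scheme = narrow_bin_scheme()
    assert len(scheme.labels) == 30
    assert categorize_bmi(54.0, scheme) == scheme.labels[-1]
    assert categorize_bmi(22.5, scheme) == scheme.reference_category
    # first bin starts at the inclusion floor
    assert scheme.breakpoints[0] == 18.5


def test_category_population_conservation(included_cohort):
    bmi = included_cohort["bmi"].to_numpy()
    for scheme in (WHO_SCHEME, narrow_bin_scheme()):
        labels = categorize_bmi(bmi, scheme)
        assert pd.Series(labels).value_counts().sum() == len(bmi)


@pytest.fixture(scope="module")
def male_cohort():
    cfg = default_config(n_per_stratum=30_000, seed=13, sexes=("male",))
    cohort, _ = apply_inclusion(generate_cohort(cfg))
    return cohort


def _adjusters(cohort):
    return [
        linear_form("age", cohort["age"].to_numpy(), 10.0),
        SelectedForm("ever_smoker", "binary", "included"),
    ]


def test_linear_quadratic_parameter_recovery():
    """An LQ comparator recovers a generating quadratic logit within 2 SE."""
    rng = np.random.default_rng(31)
    n = 30_000
    bmi = np.clip(rng.normal(27, 5, n), 18.6, 60)
    age = rng.uniform(25, 75, n)
    smoke = (rng.random(n) < 0.5).astype(int)
    x = bmi / 10
    xc, x2c = x - x.mean(), x**2 - (x**2).mean()
    true = {"b1": -3.0, "b2": 0.55}
    eta = -3.2 + true["b1"] * xc + true["b2"] * x2c + 0.3 * smoke
    cohort = pd.DataFrame(
        {"bmi": bmi, "age": age, "ever_smoker": smoke,
         "died": (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int),
         "weight": np.ones(n)}
    )
    cm = fit_comparator(cohort, "linear-quadratic", _adjusters(cohort))
    labels = cm.model.design_labels
    for lab, truth in [("bmi^1", true["b1"]), ("bmi^2", true["b2"])]:
        i = 1 + labels.index(lab)
        se = np.sqrt(cm.model.covariance[i, i])
        assert abs(cm.model.coefficients[i] - truth) < 2 * se + 1e-9


def test_categorical_null_coefficients_near_zero():
    cfg = default_config(n_per_stratum=30_000, seed=41, sexes=("male",))
    cohort, _ = apply_inclusion(generate_null_cohort(cfg))
    cm = fit_comparator(cohort, "categorical", _adjusters(cohort), scheme=WHO_SCHEME)
    labels = cm.model.design_labels
    for j, lab in enumerate(labels):
        if not lab.startswith("bmi["):
            continue
        i = 1 + j
        se = np.sqrt(cm.model.covariance[i, i])
        assert abs(cm.model.coefficients[i]) < 3 * se + 1e-9


def test_within_category_predictions_constant(male_cohort):
    cm = fit_comparator(male_cohort, "categorical", _adjusters(male_cohort),
                        scheme=WHO_SCHEME)
    one = np.zeros(len(cm.adjusters[0].basis.centers) + 1)
    adj_row = np.zeros(2)
    inside = cm.predict(np.array([25.5, 27.0, 29.9]), adj_row)
    assert np.ptp(inside) == 0.0
    across = cm.predict(np.array([20.0, 27.0, 33.0]), adj_row)
    assert len(np.unique(across)) == 3


def test_fp_deviance_never_worse_than_lq(male_stratum, included_cohort):
    """The LQ model is the (1,2) FP candidate, so the selected FP2 fit can
    never have higher deviance on the same cohort."""
    sub = included_cohort[included_cohort["sex"] == "male"].reset_index(drop=True)
    adjusters = [f for f in male_stratum.forms if f.name != "bmi" and f.in_model]
    lq = fit_comparator(sub, "linear-quadratic", adjusters)
    assert male_stratum.fit.deviance <= lq.model.deviance + 1e-6


def test_compare_models_self_and_errors(male_stratum):
    same = compare_models(male_stratum.fit, male_stratum.fit)
    assert same.deviance_difference == 0.0
    assert same.df == 0
    from fpmort.weighted_glm import fit_logistic

    other = fit_logistic(np.empty((10, 0)), [1] * 5 + [0] * 5)
    with pytest.raises(ValueError, match="differing cohorts"):
        compare_models(male_stratum.fit, other)


def test_compare_models_nesting_and_chi2_switch(male_stratum, included_cohort):
    sub = included_cohort[included_cohort["sex"] == "male"].reset_index(drop=True)
    adjusters = [f for f in male_stratum.forms if f.name != "bmi" and f.in_model]
    lin = fit_comparator(sub, "untransformed-linear", adjusters)
    nested = compare_models(male_stratum.fit, lin.model, nested=True)
    assert nested.df == 1
    assert nested.deviance_difference >= 0
    assert nested.p_value is not None
    cat = fit_comparator(sub, "categorical", adjusters, scheme=WHO_SCHEME)
    non = compare_models(male_stratum.fit, cat.model)
    assert non.p_value is None  # non-nested: no chi-square reference by default
    forced = compare_models(male_stratum.fit, cat.model, force_chi2=True)
    assert forced.p_value is not None


def test_sensitivity_noop_filter_identical(male_cohort):
    assert (male_cohort["bmi"] <= 50).all() or True
    capped = male_cohort[male_cohort["bmi"] <= 50].reset_index(drop=True)
    specs = default_covariate_specs()
    res, _ = sensitivity_refit(capped, "exclude_extreme_bmi", specs)
    from fpmort.mfp_selection import mfp_cycle

    direct = mfp_cycle(capped, specs)
    assert res.model.deviance == pytest.approx(direct.model.deviance, rel=1e-12)
    np.testing.assert_allclose(res.model.coefficients, direct.model.coefficients)


def test_reverse_causation_lowers_left_arm():
    """Excess first-year deaths at low BMI: dropping early deaths must lower
    the refitted curve's left arm relative to the nadir region."""
    from dataclasses import replace

    # female stratum: substantial mass below BMI 20, where the excess deaths go
    cfg = default_config(n_per_stratum=40_000, seed=55, sexes=("female",))
    cfg = replace(cfg, reverse_causation=(20.0, 0.08))
    cohort, _ = apply_inclusion(generate_cohort(cfg))
    specs = default_covariate_specs()
    grid = np.array([19.0, 27.0])
    from fpmort.mfp_selection import mfp_cycle

    main = mfp_cycle(cohort, specs)
    main_curve = bmi_contribution_curve(main, grid)["bmi_logit_contribution"]
    refit, curve = sensitivity_refit(
        cohort, "exclude_early_deaths", specs, bmi_grid=grid
    )
    refit_curve = curve["bmi_logit_contribution"]
    main_left = main_curve[0] - main_curve[1]     # left arm relative to center
    refit_left = refit_curve[0] - refit_curve[1]
    assert refit_left < main_left


def test_sensitivity_unknown_variant():
    with pytest.raises(ValueError):
        sensitivity_refit(pd.DataFrame({"bmi": [20.0]}), "bogus", [])
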