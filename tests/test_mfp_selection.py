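import numpy as np
import pandas as pd
import pytest

from fpmort.fp_core import PowerPair
from fpmort.mfp_selection import (
    CovariateSpec,
    SelectedForm,
    fsp_decide,
    linear_form,
    lowess_logit_check,
    mfp_cycle,
    mfpi_test,
    select_function,
)
from fpmort.synthetic_data import apply_inclusion, default_config, generate_cohort
from fpmort.weighted_glm import RankDeficientError


@pytest.mark.parametrize(
    "devs, expected",
    [
        # chi2 critical values: 9.488 (df4), 7.815 (df3), 5.991 (df2)
        ((100.0, 99.0, 98.0, 97.0), "omitted"),   # dD=3.0 < 9.488
        ((150.0, 120.0, 119.5, 119.0), "linear"),  # test2 dD=1.0 < 7.815
        ((300.0, 250.0, 240.0, 230.0), "fp2"),     # test3 dD=10 > 5.991
        ((300.0, 250.0, 231.0, 230.0), "fp1"),     # test3 dD=1 < 5.991
    ],
)
def test_fsp_decide_staged_outcomes(devs, expected):
    chosen, tests = fsp_decide(*devs, alpha=0.05)
    assert chosen == expected
    assert [t.df for t in tests] == [4, 3, 2][: len(tests)]


def test_fsp_decide_forced_in_skips_inclusion_test():
    chosen, tests = fsp_decide(100.0, 99.0, 98.0, 97.0, alpha=0.05, forced_in=True)
    assert chosen == "linear"  # would have been omitted without forcing
    assert tests[0].name == "fp2_vs_linear"


def test_fsp_decide_rejects_inconsistent_deviances():
    with pytest.raises(ValueError, match="inconsistent"):
        fsp_decide(100.0, 99.0, 98.0, 99.5, alpha=0.05)


@pytest.fixture(scope="module")
def male_cohort():
    cfg = default_config(n_per_stratum=40_000, seed=9, sexes=("male",))
    cohort, _ = apply_inclusion(generate_cohort(cfg))
    return cohort


def _adjusters(cohort):
    return [
        linear_form("age", cohort["age"].to_numpy(), 10.0),
        SelectedForm("ever_smoker", "binary", "included"),
    ]


def test_select_function_detects_fp2_truth(male_cohort):
    form, trace = select_function(
        male_cohort, CovariateSpec("bmi", "continuous"), _adjusters(male_cohort)
    )
    assert isinstance(form.form, PowerPair) and form.form.degree == 2
    assert trace.tests[0].name == "fp2_vs_null"
    assert trace.tests[0].p_value < 1e-3
    # deviance ordering of the trace
    assert trace.dev_fp2 <= trace.dev_fp1 + 1e-6
    assert trace.dev_fp1 <= trace.dev_linear + 1e-6
    assert trace.dev_linear <= trace.dev_null + 1e-6


def test_select_function_constant_covariate_errors(male_cohort):
    cohort = male_cohort.copy()
    cohort["bmi"] = 25.0
    with pytest.raises(RankDeficientError):
        select_function(
            cohort, CovariateSpec("bmi", "continuous"), _adjusters(cohort)
        )


def test_mfp_cycle_reduces_to_select_function(male_cohort):
    sub = male_cohort.iloc[:8000].reset_index(drop=True)
    solo = mfp_cycle(sub, [CovariateSpec("bmi", "continuous")])
    form, _ = select_function(sub, CovariateSpec("bmi", "continuous"), [])
    assert solo.forms["bmi"].describe() == form.describe()


def test_mfp_cycle_alpha_zero_keeps_forced_linear(male_cohort):
    sub = male_cohort.iloc[:5000].reset_index(drop=True)
    specs = [
        CovariateSpec("bmi", "continuous", forced_in=True),
        CovariateSpec("age", "continuous", max_degree=1, forced_in=True),
        CovariateSpec("ever_smoker", "binary", forced_in=True),
    ]
    res = mfp_cycle(sub, specs, alpha=0.0)
    assert res.forms["bmi"].form == "linear"
    assert res.forms["age"].form == "linear"
    assert res.forms["ever_smoker"].form == "included"
    assert res.converged


def test_mfp_cycle_recovers_truth_and_is_deterministic(male_cohort):
    specs = [
        CovariateSpec("bmi", "continuous", max_degree=2),
        CovariateSpec("age", "continuous", max_degree=1),
        CovariateSpec("ever_smoker", "binary", forced_in=True),
    ]
    res = mfp_cycle(male_cohort, specs)
    res2 = mfp_cycle(male_cohort, specs)
    assert res.converged and res.n_cycles <= 5
    assert [f.describe() for f in res.forms.values()] == [
        f.describe() for f in res2.forms.values()
    ]
    assert res.model.deviance == pytest.approx(res2.model.deviance, rel=1e-12)
    # generating truth: BMI FP2, age included nonlinearly or linearly
    assert isinstance(res.forms["bmi"].form, PowerPair)
    assert res.forms["age"].in_model


def test_mfpi_detects_generated_interactions():
    """MFPI forward selection finds both the age x BMI and age x smoking
    interactions generated by the published female truth at the study's
    stratum size, with the expected degrees of freedom (2 product columns for
    an FP2 BMI, 1 for the binary)."""
    cfg = default_config(n_per_stratum=65_000, seed=21, sexes=("female",))
    cohort, _ = apply_inclusion(generate_cohort(cfg))
    specs = [
        CovariateSpec("bmi", "continuous", max_degree=2),
        CovariateSpec("age", "continuous", max_degree=1),
        CovariateSpec("ever_smoker", "binary", forced_in=True),
    ]
    main = mfp_cycle(cohort, specs)
    res = mfpi_test(cohort, main, [("age", "bmi"), ("age", "ever_smoker")])
    assert ("age", "bmi") in res.included
    assert ("age", "ever_smoker") in res.included
    dfs = {t.candidate: t.df for t in res.trace if t.included}
    assert dfs[("age", "bmi")] == 2
    assert dfs[("age", "ever_smoker")] == 1


def test_mfpi_type_one_error_under_null():
    """Male truth has no interactions: with the main-effect forms frozen at
    the generating truth, spurious inclusion stays near the test level."""
    from fpmort.fp_core import centered_basis
    from fpmort.mfp_selection import MfpResult, _fit_forms

    spurious = 0
    reps = 40
    for seed in range(reps):
        cfg = default_config(n_per_stratum=20_000, seed=0, sexes=("male",))
        cohort, _ = apply_inclusion(generate_cohort(cfg, seed=3_000 + seed))
        bmi = cohort["bmi"].to_numpy()
        age = cohort["age"].to_numpy()
        forms = {
            "bmi": SelectedForm(
                "bmi", "continuous", PowerPair((-2.0, -2.0)),
                centered_basis(bmi, PowerPair((-2.0, -2.0)), 10.0),
            ),
            "age": SelectedForm(
                "age", "continuous", PowerPair((2.0,)),
                centered_basis(age, PowerPair((2.0,)), 10.0),
            ),
            "ever_smoker": SelectedForm("ever_smoker", "binary", "included"),
        }
        main = MfpResult(
            forms=forms, order=list(forms),
            model=_fit_forms(cohort, list(forms.values())), trace=[],
        )
        res = mfpi_test(cohort, main, [("age", "bmi"), ("age", "ever_smoker")])
        spurious += bool(res.included)
    # two tests at alpha=0.05 => expect ~90% clean; allow Monte-Carlo slack
    assert spurious / reps <= 0.3


def test_mfpi_duplicate_candidate_skipped_collinear():
    """A candidate identical to an already-included one adds collinear
    columns and must be skipped with a warning."""
    from fpmort.fp_core import centered_basis
    from fpmort.mfp_selection import MfpResult, _fit_forms

    rng = np.random.default_rng(17)
    n = 20_000
    age = rng.uniform(20, 80, n)
    bmi = rng.uniform(19, 45, n)
    smoke = (rng.random(n) < 0.5).astype(int)
    eta = -3.5 + 0.03 * (age - 50) + 0.002 * (age - 50) * (bmi - 27)
    cohort = pd.DataFrame(
        {
            "age": age,
            "bmi": bmi,
            "ever_smoker": smoke,
            "died": (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int),
            "weight": np.ones(n),
        }
    )
    forms = {
        "bmi": linear_form("bmi", bmi, 10.0),
        "age": linear_form("age", age, 10.0),
        "ever_smoker": SelectedForm("ever_smoker", "binary", "included"),
    }
    main = MfpResult(
        forms=forms, order=list(forms), model=_fit_forms(cohort, list(forms.values())),
        trace=[],
    )
    with pytest.warns(UserWarning, match="collinear"):
        res = mfpi_test(cohort, main, [("age", "bmi"), ("age", "bmi")])
    assert res.included == [("age", "bmi")]
    assert any(t.skipped_collinear for t in res.trace)


def _parallel_logit_cohort(slope_gap: float, n=40_000, seed=5):
    rng = np.random.default_rng(seed)
    age = rng.uniform(20, 80, n)
    stratum = (rng.random(n) < 0.5).astype(int)
    eta = -5.0 + 0.04 * age + stratum * (0.3 + slope_gap * age)
    died = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    return pd.DataFrame({"age": age, "died": died, "group": stratum})


def _smoothed_slope(curve):
    return np.polyfit(curve["x"], curve["logit"], 1)[0]


def test_lowess_parallel_slopes_agree():
    out = lowess_logit_check(_parallel_logit_cohort(0.0), "age", "group", bins=25)
    s0, s1 = _smoothed_slope(out[0]), _smoothed_slope(out[1])
    assert abs(s0 - s1) < 0.05


def test_lowess_detects_slope_difference_with_sign():
    out = lowess_logit_check(_parallel_logit_cohort(0.05), "age", "group", bins=25)
    assert _smoothed_slope(out[1]) - _smoothed_slope(out[0]) > 0.02


def test_lowess_constant_zero_stratum_is_flat_floor():
    df = _parallel_logit_cohort(0.0, n=4000)
    df.loc[df["group"] == 1, "died"] = 0
    out = lowess_logit_check(df, "age", "group", bins=8)
    logits = out[1]["logit"]
    assert np.ptp(logits) < 0.5
    assert np.all(logits < np.log(0.01))  # near the continuity-corrected floor


def test_lowess_requires_two_strata():
    df = _parallel_logit_cohort(0.0, n=2000)
    df["group"] = 0
    with pytest.raises(ValueError):
        lowess_logit_check(df, "age", "group")
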