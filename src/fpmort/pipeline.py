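"""End-to-end study orchestration.

Filter -> stratify by sex -> MFP function selection -> MFPI interaction
testing -> nadir estimation -> comparator fits -> reports.  Everything is
driven by a :class:`StudyConfig` and fully reproducible from its seed; the
outputs are plain CSV/JSON files (descriptives, coefficient tables, nadir
tables, curve data, the full selection trace, and a run log).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import comparators as comp
from .fp_core import PowerPair, fp_transform
from .mfp_selection import (
    CovariateSpec,
    MfpResult,
    MfpiResult,
    SelectedForm,
    build_design,
    lowess_logit_check,
    mfp_cycle,
    mfpi_test,
)
from .nadir import NadirCoefficientMap, NadirEstimate, nadir_delta_ci
from .synthetic_data import (
    GeneratorConfig,
    apply_inclusion,
    default_config,
    generate_cohort,
    read_cohort_csv,
)
from .weighted_glm import FittedModel, predict_mortality

DEFAULT_PROFILE_AGES = (18, 40, 50, 65, 85)
DEFAULT_CURVE_AGES = (40, 50, 65)
DEFAULT_BMI_GRID = tuple(np.arange(18.5, 60.01, 0.5))


@dataclass
class StudyConfig:
    """Configuration for one full study run."""

    generator: GeneratorConfig | None = None
    input_csv: str | None = None
    horizon: float = 5.0
    alpha: float = 0.05
    sexes: tuple[str, ...] = ("male", "female")
    comparator_kinds: tuple[str, ...] = (
        "untransformed-linear", "linear-quadratic", "categorical",
    )
    sensitivity_variants: tuple[str, ...] = ()
    out_dir: str | None = None
    seed: int = 0
    chi2_for_nonnested: bool = False  # emit chi-square p even when non-nested
    bmi_scale: float = 10.0
    age_scale: float = 10.0

    def __post_init__(self) -> None:
        if self.horizon not in (3.0, 5.0):
            import warnings

            warnings.warn(
                f"outcome horizon {self.horizon} is non-standard "
                "(3- and 5-year horizons are the validated choices)"
            )


@dataclass
class StratumModel:
    """The final fitted model for one sex stratum, with everything needed to
    predict mortality at a (bmi, age, smoker) profile."""

    sex: str
    fit: FittedModel
    forms: list[SelectedForm]
    interactions: list[tuple[str, str]]
    mfp: MfpResult
    mfpi: MfpiResult | None

    def _frame(self, bmi, age, smoker) -> pd.DataFrame:
        bmi, age, smoker = np.broadcast_arrays(
            np.atleast_1d(bmi), np.atleast_1d(age), np.atleast_1d(smoker)
        )
        return pd.DataFrame(
            {"bmi": bmi.astype(float), "age": age.astype(float),
             "ever_smoker": smoker.astype(float)}
        )

    def design(self, bmi, age, smoker) -> np.ndarray:
        X, labels = build_design(
            self._frame(bmi, age, smoker), self.forms, self.interactions
        )
        if labels != self.fit.design_labels:
            raise RuntimeError("design labels drifted from the fitted model")
        return X

    def predict(self, bmi, age, smoker) -> np.ndarray:
        return np.atleast_1d(predict_mortality(self.fit, self.design(bmi, age, smoker)))

    def predict_with_ci(self, bmi, age, smoker, confidence: float = 0.95):
        X = self.design(bmi, age, smoker)
        A = np.column_stack([np.ones(len(X)), X])
        eta = A @ self.fit.coefficients
        se = np.sqrt(np.einsum("ij,jk,ik->i", A, self.fit.covariance, A))
        z = stats.norm.ppf(0.5 + confidence / 2.0)
        from scipy.special import expit

        return expit(eta), expit(eta - z * se), expit(eta + z * se)

    @property
    def bmi_form(self) -> SelectedForm:
        return next(f for f in self.forms if f.name == "bmi")

    @property
    def age_form(self) -> SelectedForm:
        return next(f for f in self.forms if f.name == "age")

    def nadir_at(self, age: float, smoker: int = 0) -> NadirEstimate:
        """Delta-method nadir estimate at the given profile."""
        form = self.bmi_form
        if not isinstance(form.form, PowerPair) or form.form.degree != 2:
            raise ValueError(
                "nadir estimation requires a degree-2 FP for BMI; "
                f"selected form is {form.describe()}"
            )
        labels = self.fit.design_labels
        bmi_labels = form.basis.column_labels("bmi")
        b1_i = 1 + labels.index(bmi_labels[0])
        b2_i = 1 + labels.index(bmi_labels[1])
        c1_i = c2_i = None
        g = 0.0
        if ("age", "bmi") in self.interactions:
            age_lab = self.age_form.basis.column_labels("age")[0]
            c1_i = 1 + labels.index(f"{age_lab}:{bmi_labels[0]}")
            c2_i = 1 + labels.index(f"{age_lab}:{bmi_labels[1]}")
            g = float(fp_transform(age, self.age_form.basis)[0])
        est = nadir_delta_ci(
            self.fit, form.form,
            NadirCoefficientMap(b1_i, b2_i, c1_i, c2_i, g),
            scale=form.basis.scale,
            profile={"age": age, "ever_smoker": smoker},
        )
        if np.isfinite(est.bmi_at_minimum):
            est.mortality_at_minimum = float(
                self.predict(est.bmi_at_minimum, age, smoker)[0]
            )
        return est


def outcome_for_horizon(cohort: pd.DataFrame, horizon: float) -> pd.DataFrame:
    """Recode the death indicator for a shorter horizon using death timing."""
    df = cohort.copy()
    if "time_to_death" in df.columns:
        died = (df["died"] == 1) & (df["time_to_death"] <= horizon)
        df["died"] = died.astype(int)
    return df


def default_covariate_specs(
    bmi_scale: float = 10.0, age_scale: float = 10.0
) -> list[CovariateSpec]:
    """BMI as a degree-2 FP candidate, age degree-1 (collinearity guard),
    smoking forced in as a binary adjuster."""
    return [
        CovariateSpec("bmi", "continuous", max_degree=2, scale=bmi_scale),
        CovariateSpec("age", "continuous", max_degree=1, scale=age_scale),
        CovariateSpec("ever_smoker", "binary", forced_in=True),
    ]


def analyze_stratum(
    cohort: pd.DataFrame,
    sex: str,
    alpha: float = 0.05,
    bmi_scale: float = 10.0,
    age_scale: float = 10.0,
    test_interactions: bool = True,
) -> StratumModel:
    """MFP selection plus MFPI interaction testing for one sex stratum."""
    specs = default_covariate_specs(bmi_scale, age_scale)
    mfp = mfp_cycle(cohort, specs, alpha)
    interactions: list[tuple[str, str]] = []
    mfpi = None
    if test_interactions and mfp.forms["bmi"].in_model and mfp.forms["age"].in_model:
        candidates = [("age", "bmi"), ("age", "ever_smoker")]
        mfpi = mfpi_test(cohort, mfp, candidates, alpha)
        interactions = mfpi.included
        fit = mfpi.model
    else:
        fit = mfp.model
    forms = [mfp.forms[s.name] for s in specs]
    return StratumModel(
        sex=sex, fit=fit, forms=forms, interactions=interactions,
        mfp=mfp, mfpi=mfpi,
    )


def report_descriptives(cohort: pd.DataFrame) -> pd.DataFrame:
    """Cohort summary per sex x survey year (plus a pooled Total row):
    sample size, deaths, deaths/1000, mean age, WHO-category prevalence and
    ever-smoker percentage."""
    rows = []
    for sex, sex_df in cohort.groupby("sex"):
        groups = [(str(y), g) for y, g in sex_df.groupby("survey_year")]
        groups.append(("Total", sex_df))
        for label, g in groups:
            cats = comp.categorize_bmi(g["bmi"].to_numpy(), comp.WHO_SCHEME)
            prev = pd.Series(cats).value_counts(normalize=True) * 100
            n = len(g)
            deaths = int((g["died"] == 1).sum())
            rows.append(
                {
                    "sex": sex,
                    "survey_year": label,
                    "n": n,
                    "deaths": deaths,
                    "deaths_per_1000": 1000.0 * deaths / n if n else float("nan"),
                    "mean_age": g["age"].mean(),
                    **{
                        f"pct_{lab}": float(prev.get(lab, 0.0))
                        for lab in comp.WHO_SCHEME.labels
                    },
                    "pct_ever_smoker": 100.0 * g["ever_smoker"].mean(),
                }
            )
    return pd.DataFrame(rows)


def coefficient_report(stratum: StratumModel) -> pd.DataFrame:
    """Coefficient table with stratum-specific age slopes when an
    age x smoking interaction is present."""
    rows = [
        {"term": lab, "coefficient": b, "se": s}
        for lab, b, s in stratum.fit.coef_table()
    ]
    if ("age", "ever_smoker") in stratum.interactions:
        labels = stratum.fit.design_labels
        age_lab = stratum.age_form.basis.column_labels("age")[0]
        i_main = 1 + labels.index(age_lab)
        i_int = 1 + labels.index(f"{age_lab}:ever_smoker")
        beta = stratum.fit.coefficients
        cov = stratum.fit.covariance
        for smoke, extra in ((0, 0.0), (1, 1.0)):
            coefv = beta[i_main] + extra * beta[i_int]
            var = (
                cov[i_main, i_main]
                + extra**2 * cov[i_int, i_int]
                + 2 * extra * cov[i_main, i_int]
            )
            rows.append(
                {
                    "term": f"{age_lab} | ever_smoker = {smoke}",
                    "coefficient": coefv,
                    "se": float(np.sqrt(max(var, 0.0))),
                }
            )
    rows.append(
        {"term": "log_likelihood", "coefficient": stratum.fit.loglik, "se": float("nan")}
    )
    return pd.DataFrame(rows)


def nadir_report(
    stratum: StratumModel,
    ages=DEFAULT_PROFILE_AGES,
    smokers=(0, 1),
) -> pd.DataFrame:
    rows = []
    for smoker in smokers:
        for age in ages:
            try:
                est = stratum.nadir_at(age, smoker)
            except ValueError as err:
                rows.append({"sex": stratum.sex, "age": age, "ever_smoker": smoker,
                             "error": str(err)})
                continue
            rows.append(
                {
                    "sex": stratum.sex,
                    "age": age,
                    "ever_smoker": smoker,
                    "optimal_bmi": est.bmi_at_minimum,
                    "se": est.se,
                    "ci_low": est.ci95[0],
                    "ci_high": est.ci95[1],
                    "mortality_at_optimum": est.mortality_at_minimum,
                    "boundary": est.boundary,
                }
            )
    return pd.DataFrame(rows)


def curve_report(
    stratum: StratumModel,
    ages=DEFAULT_CURVE_AGES,
    smokers=(0, 1),
    bmi_grid=DEFAULT_BMI_GRID,
) -> pd.DataFrame:
    grid = np.asarray(bmi_grid, dtype=float)
    frames = []
    for smoker in smokers:
        for age in ages:
            p, lo, hi = stratum.predict_with_ci(grid, age, smoker)
            frames.append(
                pd.DataFrame(
                    {
                        "sex": stratum.sex,
                        "model": "fp",
                        "age": age,
                        "smoker": smoker,
                        "bmi_grid": grid,
                        "predicted_mortality": p,
                        "ci_low": lo,
                        "ci_high": hi,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def _comparator_curves(
    stratum: StratumModel,
    cmodel: comp.ComparatorModel,
    age: float,
    smoker: int,
    bmi_grid,
) -> np.ndarray:
    one = pd.DataFrame({"bmi": [25.0], "age": [age], "ever_smoker": [float(smoker)]})
    adj_row, _ = build_design(one, cmodel.adjusters)
    return np.atleast_1d(cmodel.predict(np.asarray(bmi_grid), adj_row[0]))


def run_study(config: StudyConfig) -> dict:
    """Run the whole pipeline; returns the report bundle as a dict and, when
    ``config.out_dir`` is set, writes it out as CSV/JSON files."""
    if config.generator is None and config.input_csv is None:
        config = StudyConfig(**{**asdict_shallow(config), "generator": default_config(seed=config.seed)})
    if config.input_csv is not None:
        raw = read_cohort_csv(config.input_csv)
    else:
        raw = generate_cohort(config.generator, seed=config.seed)
    if len(raw) == 0:
        raise ValueError("empty input cohort")
    cohort, tally = apply_inclusion(raw)
    cohort = outcome_for_horizon(cohort, config.horizon)

    bundle: dict = {
        "config": {
            "horizon": config.horizon,
            "alpha": config.alpha,
            "seed": config.seed,
            "sexes": list(config.sexes),
            "source": config.input_csv or "synthetic-generator",
        },
        "exclusions": tally,
        "descriptives": report_descriptives(cohort),
        "strata": {},
    }
    for sex in config.sexes:
        sub = cohort[cohort["sex"] == sex].reset_index(drop=True)
        if len(sub) == 0 or (sub["died"] == 1).sum() == 0:
            bundle["strata"][sex] = {
                "error": f"stratum {sex!r} has no subjects or no deaths; skipped"
            }
            continue
        stratum = analyze_stratum(
            sub, sex, config.alpha, config.bmi_scale, config.age_scale
        )
        entry: dict = {
            "model": stratum,
            "coefficients": coefficient_report(stratum),
            "nadir": nadir_report(stratum),
            "curves": curve_report(stratum),
            "selection_trace": [t.to_dict() for t in stratum.mfp.trace],
            "interaction_trace": [
                {
                    "candidate": f"{t.candidate[0]}x{t.candidate[1]}",
                    "statistic": t.statistic,
                    "df": t.df,
                    "p": t.p_value,
                    "included": t.included,
                    "skipped_collinear": t.skipped_collinear,
                }
                for t in (stratum.mfpi.trace if stratum.mfpi else [])
            ],
        }
        adjusters = [f for f in stratum.forms if f.name != "bmi" and f.in_model]
        comparisons = []
        grid = np.asarray(DEFAULT_BMI_GRID)
        main_curve = stratum.predict(grid, 50.0, 0)
        for kind in config.comparator_kinds:
            cmodel = comp.fit_comparator(
                sub, kind, adjusters,
                scheme=comp.WHO_SCHEME if kind == "categorical" else None,
                bmi_scale=config.bmi_scale,
            )
            nested = kind == "untransformed-linear"
            comparison = comp.compare_models(
                stratum.fit, cmodel.model,
                main_curve, _comparator_curves(stratum, cmodel, 50.0, 0, grid),
                nested=nested, force_chi2=config.chi2_for_nonnested,
            )
            comparisons.append(
                {
                    "comparator": kind,
                    "deviance_difference": comparison.deviance_difference,
                    "df": comparison.df,
                    "p_value": comparison.p_value,
                    "nested": comparison.nested,
                    "max_abs_curve_diff": comparison.max_abs_curve_diff,
                    "mean_abs_curve_diff": comparison.mean_abs_curve_diff,
                }
            )
        entry["comparisons"] = pd.DataFrame(comparisons)
        sens = {}
        for variant in config.sensitivity_variants:
            res, curve = comp.sensitivity_refit(
                sub, variant, default_covariate_specs(config.bmi_scale, config.age_scale),
                config.alpha,
            )
            sens[variant] = {
                "bmi_form": res.forms["bmi"].describe(),
                "curve": curve,
            }
        entry["sensitivity"] = sens
        try:
            entry["lowess"] = lowess_logit_check(sub, "age", "ever_smoker")
        except ValueError:
            entry["lowess"] = None
        bundle["strata"][sex] = entry

    if config.out_dir is not None:
        _write_bundle(bundle, Path(config.out_dir))
    return bundle


def asdict_shallow(cfg: StudyConfig) -> dict:
    return {k: getattr(cfg, k) for k in cfg.__dataclass_fields__}


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    return str(o)


def _write_bundle(bundle: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle["descriptives"].to_csv(out_dir / "descriptives.csv", index=False)
    trace = {"exclusions": bundle["exclusions"]}
    for sex, entry in bundle["strata"].items():
        if "error" in entry:
            trace[sex] = {"error": entry["error"]}
            continue
        entry["coefficients"].to_csv(out_dir / f"coefficients_{sex}.csv", index=False)
        entry["nadir"].to_csv(out_dir / f"nadir_{sex}.csv", index=False)
        entry["curves"].to_csv(out_dir / f"curves_{sex}.csv", index=False)
        entry["comparisons"].to_csv(out_dir / f"comparisons_{sex}.csv", index=False)
        trace[sex] = {
            "selection": entry["selection_trace"],
            "interactions": entry["interaction_trace"],
            "forms": [f.describe() for f in entry["model"].forms],
        }
    (out_dir / "selection_trace.json").write_text(
        json.dumps(trace, indent=2, default=_json_default)
    )
    cfg_txt = json.dumps(bundle["config"], sort_keys=True, default=_json_default)
    log = {
        "config": bundle["config"],
        "config_sha256": hashlib.sha256(cfg_txt.encode()).hexdigest(),
    }
    (out_dir / "run_log.json").write_text(json.dumps(log, indent=2))
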