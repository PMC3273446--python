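"""Model selection for fractional polynomials.

Three layers:

* the closed test (function-selection procedure): staged deviance-difference
  tests with 4, 3 and 2 degrees of freedom deciding among omitting a
  covariate, keeping it linear, or using its best FP1 / FP2 transform, with
  family-wise error control by construction;
* the MFP cycle: covariates are visited in order of descending linear-model
  significance, each re-selected given the others' current forms, until a
  full cycle changes nothing (backward elimination included: a covariate that
  fails its inclusion test is dropped unless forced in);
* the MFPI interaction step: with main-effect forms frozen, products of the
  transformed columns are tested by deviance difference and added by forward
  selection, then double-checked graphically via lowess-smoothed empirical
  logits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .fp_core import FPBasis, PowerPair, centered_basis, fp_transform
from .weighted_glm import (
    FittedModel,
    RankDeficientError,
    deviance_difference_test,
    fit_logistic,
)

_DEV_TOL = 1e-6
MAX_CYCLES = 5


@dataclass(frozen=True)
class CovariateSpec:
    """Declaration of one model covariate for MFP selection."""

    name: str
    kind: str  # "continuous" | "binary"
    max_degree: int = 2
    scale: float = 10.0
    forced_in: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary"):
            raise ValueError(f"unknown covariate kind {self.kind!r}")
        if self.kind == "continuous" and self.max_degree not in (1, 2):
            raise ValueError("continuous covariates support max_degree 1 or 2")


@dataclass(frozen=True)
class SelectedForm:
    """A covariate's current functional form within the model."""

    name: str
    kind: str
    form: str | PowerPair  # "omitted" | "linear" | "included" | PowerPair
    basis: FPBasis | None = None

    @property
    def in_model(self) -> bool:
        return self.form != "omitted"

    def describe(self) -> str:
        if isinstance(self.form, PowerPair):
            return f"{self.name}~FP{self.form.degree}{self.form}"
        return f"{self.name}~{self.form}"


@dataclass
class TestRecord:
    name: str
    statistic: float
    df: int
    p_value: float
    significant: bool


@dataclass
class FunctionSelection:
    """Trace of one covariate's closed-test decision."""

    covariate: str
    dev_null: float
    dev_linear: float
    dev_fp1: float
    fp1_powers: PowerPair | None
    dev_fp2: float | None
    fp2_powers: PowerPair | None
    tests: list[TestRecord]
    chosen: str | PowerPair
    cycle: int = 0

    def to_dict(self) -> dict:
        return {
            "covariate": self.covariate,
            "cycle": self.cycle,
            "deviances": {
                "null": self.dev_null,
                "linear": self.dev_linear,
                "fp1_best": self.dev_fp1,
                "fp2_best": self.dev_fp2,
            },
            "fp1_powers": str(self.fp1_powers) if self.fp1_powers else None,
            "fp2_powers": str(self.fp2_powers) if self.fp2_powers else None,
            "tests": [
                {
                    "name": t.name,
                    "statistic": t.statistic,
                    "df": t.df,
                    "p": t.p_value,
                    "significant": t.significant,
                }
                for t in self.tests
            ],
            "chosen": str(self.chosen),
        }


def fsp_decide(
    dev_null: float,
    dev_linear: float,
    dev_fp1_best: float,
    dev_fp2_best: float,
    alpha: float = 0.05,
    forced_in: bool = False,
) -> tuple[str, list[TestRecord]]:
    """The closed test on pre-computed deviances.

    Test 1 (df 4): best FP2 vs null -- not significant => "omitted".
    Test 2 (df 3): best FP2 vs linear -- not significant => "linear".
    Test 3 (df 2): best FP2 vs best FP1 -- significant => "fp2", else "fp1".
    A forced-in covariate skips test 1 (it is never dropped).

    Raises when the best FP2 deviance exceeds a sub-model's beyond tolerance
    (the fits cannot then come from nested minimizations on the same data).
    """
    tol = _DEV_TOL * (abs(dev_fp2_best) + 1.0)
    for label, dev in [
        ("null", dev_null), ("linear", dev_linear), ("fp1", dev_fp1_best)
    ]:
        if dev_fp2_best > dev + tol:
            raise ValueError(
                f"inconsistent deviances: best FP2 ({dev_fp2_best}) worse than "
                f"{label} model ({dev})"
            )
    tests: list[TestRecord] = []

    def run(name: str, dev_reduced: float, df: int) -> bool:
        stat, p = deviance_difference_test(dev_reduced, dev_fp2_best, df, tol=_DEV_TOL)
        sig = p < alpha
        tests.append(TestRecord(name, stat, df, p, sig))
        return sig

    if not forced_in:
        if not run("fp2_vs_null", dev_null, 4):
            return "omitted", tests
    if not run("fp2_vs_linear", dev_linear, 3):
        return "linear", tests
    if run("fp2_vs_fp1", dev_fp1_best, 2):
        return "fp2", tests
    return "fp1", tests


def _columns_for(form: SelectedForm, df: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    if not form.in_model:
        return np.empty((len(df), 0)), []
    if form.kind == "binary":
        return df[form.name].to_numpy(float).reshape(-1, 1), [form.name]
    cols = fp_transform(df[form.name].to_numpy(float), form.basis)
    return cols, form.basis.column_labels(form.name)


def build_design(
    df: pd.DataFrame,
    forms: list[SelectedForm],
    interactions: list[tuple[str, str]] = (),
) -> tuple[np.ndarray, list[str]]:
    """Assemble the centered design matrix for the given functional forms.

    ``interactions`` lists (continuous, partner) pairs; each contributes the
    products of every transformed column of the continuous variable with every
    column of the partner.
    """
    blocks: list[np.ndarray] = []
    labels: list[str] = []
    by_name: dict[str, tuple[np.ndarray, list[str]]] = {}
    for form in forms:
        cols, labs = _columns_for(form, df)
        by_name[form.name] = (cols, labs)
        if cols.shape[1]:
            blocks.append(cols)
            labels.extend(labs)
    for cont, partner in interactions:
        ccols, clabs = by_name[cont]
        pcols, plabs = by_name[partner]
        if not ccols.shape[1] or not pcols.shape[1]:
            raise ValueError(
                f"interaction {cont}x{partner} references an omitted covariate"
            )
        for j in range(ccols.shape[1]):
            for k in range(pcols.shape[1]):
                blocks.append((ccols[:, j] * pcols[:, k]).reshape(-1, 1))
                labels.append(f"{clabs[j]}:{plabs[k]}")
    X = np.hstack(blocks) if blocks else np.empty((len(df), 0))
    return X, labels


def linear_form(name: str, values, scale: float) -> SelectedForm:
    return SelectedForm(
        name, "continuous", "linear",
        centered_basis(values, PowerPair((1.0,)), scale),
    )


def _fit_forms(
    df: pd.DataFrame,
    forms: list[SelectedForm],
    interactions: list[tuple[str, str]] = (),
) -> FittedModel:
    X, labels = build_design(df, forms, interactions)
    return fit_logistic(
        X, df["died"].to_numpy(float), df["weight"].to_numpy(float), labels
    )


def select_function(
    cohort: pd.DataFrame,
    target: CovariateSpec,
    adjusters: list[SelectedForm],
    alpha: float = 0.05,
    cycle: int = 0,
) -> tuple[SelectedForm, FunctionSelection]:
    """Closed-test function selection for one continuous covariate.

    Fits every FP candidate of the target (adjusters held at their current
    forms), finds the best FP1 and FP2 by minimum deviance (ties broken by
    enumeration order), and delegates the staged decision to
    :func:`fsp_decide`.  Non-converged candidate fits are skipped with a
    warning; if every candidate fails, an error is raised.
    """
    from .fp_core import enumerate_candidates

    values = cohort[target.name].to_numpy(float)

    def fit_with(pp: PowerPair | None, lin: bool = False):
        if pp is None and not lin:
            form = SelectedForm(target.name, "continuous", "omitted")
        elif lin:
            form = linear_form(target.name, values, target.scale)
        else:
            form = SelectedForm(
                target.name, "continuous", pp,
                centered_basis(values, pp, target.scale),
            )
        return form, _fit_forms(cohort, [form] + adjusters)

    _, null_fit = fit_with(None)
    lin_form, lin_fit = fit_with(None, lin=True)

    def best_of(degree: int):
        best = None
        for pp in enumerate_candidates(degree):
            form, fit = fit_with(pp)
            if not fit.converged:
                warnings.warn(
                    f"candidate {target.name}~FP{pp} did not converge; skipped"
                )
                continue
            if best is None or fit.deviance < best[1].deviance - 1e-8:
                best = (form, fit)
        if best is None:
            raise RuntimeError(
                f"no FP{degree} candidate for {target.name!r} converged"
            )
        return best

    fp1_form, fp1_fit = best_of(1)
    if target.max_degree == 2:
        fp2_form, fp2_fit = best_of(2)
    else:
        fp2_form, fp2_fit = fp1_form, fp1_fit

    if target.max_degree == 2:
        chosen_kind, tests = fsp_decide(
            null_fit.deviance, lin_fit.deviance, fp1_fit.deviance,
            fp2_fit.deviance, alpha, forced_in=target.forced_in,
        )
    else:
        # degree-1 closed test: FP1 vs null (df 2), FP1 vs linear (df 1)
        tests = []
        chosen_kind = "fp1"
        if not target.forced_in:
            stat, p = deviance_difference_test(null_fit.deviance, fp1_fit.deviance, 2)
            tests.append(TestRecord("fp1_vs_null", stat, 2, p, p < alpha))
            if p >= alpha:
                chosen_kind = "omitted"
        if chosen_kind != "omitted":
            stat, p = deviance_difference_test(lin_fit.deviance, fp1_fit.deviance, 1)
            tests.append(TestRecord("fp1_vs_linear", stat, 1, p, p < alpha))
            if p >= alpha:
                chosen_kind = "linear"

    chosen_form = {
        "omitted": SelectedForm(target.name, "continuous", "omitted"),
        "linear": lin_form,
        "fp1": fp1_form,
        "fp2": fp2_form,
    }[chosen_kind]
    trace = FunctionSelection(
        covariate=target.name,
        dev_null=null_fit.deviance,
        dev_linear=lin_fit.deviance,
        dev_fp1=fp1_fit.deviance,
        fp1_powers=fp1_form.form if isinstance(fp1_form.form, PowerPair) else None,
        dev_fp2=fp2_fit.deviance if target.max_degree == 2 else None,
        fp2_powers=fp2_form.form if isinstance(fp2_form.form, PowerPair) else None,
        tests=tests,
        chosen=chosen_form.form,
        cycle=cycle,
    )
    return chosen_form, trace


@dataclass
class MfpResult:
    forms: dict[str, SelectedForm]
    order: list[str]
    model: FittedModel
    trace: list[FunctionSelection]
    binary_tests: list[TestRecord] = field(default_factory=list)
    converged: bool = True
    n_cycles: int = 0

    def form_of(self, name: str) -> SelectedForm:
        return self.forms[name]


def _visit_order(
    cohort: pd.DataFrame, specs: list[CovariateSpec]
) -> list[str]:
    """Descending Wald significance of each covariate in a preliminary
    all-linear model; ties broken by declared order."""
    forms = []
    for s in specs:
        if s.kind == "binary":
            forms.append(SelectedForm(s.name, "binary", "included"))
        else:
            forms.append(linear_form(s.name, cohort[s.name].to_numpy(float), s.scale))
    fit = _fit_forms(cohort, forms)
    z = np.abs(fit.coefficients[1:]) / np.sqrt(np.diag(fit.covariance)[1:])
    order = sorted(
        range(len(specs)), key=lambda i: (-z[i], i)
    )
    return [specs[i].name for i in order]


def mfp_cycle(
    cohort: pd.DataFrame,
    covariate_specs: list[CovariateSpec],
    alpha: float = 0.05,
) -> MfpResult:
    """Multivariable FP selection with backward elimination.

    Covariates are re-selected one at a time (continuous via the closed test,
    non-forced binary via a df-1 inclusion test) given the others' current
    forms, cycling until a full pass changes nothing (cap 5 cycles, after
    which the current model is returned flagged non-converged).
    """
    if not covariate_specs:
        raise ValueError("at least one covariate is required")
    specs = {s.name: s for s in covariate_specs}
    order = _visit_order(cohort, covariate_specs)
    state: dict[str, SelectedForm] = {}
    for s in covariate_specs:
        if s.kind == "binary":
            state[s.name] = SelectedForm(s.name, "binary", "included")
        else:
            state[s.name] = linear_form(s.name, cohort[s.name].to_numpy(float), s.scale)
    trace: list[FunctionSelection] = []
    binary_tests: list[TestRecord] = []
    converged = False
    n_cycles = 0
    for cycle in range(1, MAX_CYCLES + 1):
        n_cycles = cycle
        changed = False
        for name in order:
            spec = specs[name]
            others = [state[o] for o in state if o != name]
            if spec.kind == "continuous":
                new_form, t = select_function(
                    cohort, spec, others, alpha, cycle=cycle
                )
                trace.append(t)
            else:
                if spec.forced_in:
                    continue
                with_form = SelectedForm(name, "binary", "included")
                without = SelectedForm(name, "binary", "omitted")
                dev_with = _fit_forms(cohort, [with_form] + others).deviance
                dev_without = _fit_forms(cohort, [without] + others).deviance
                stat, p = deviance_difference_test(dev_without, dev_with, 1)
                binary_tests.append(
                    TestRecord(f"{name}_inclusion_cycle{cycle}", stat, 1, p, p < alpha)
                )
                new_form = with_form if p < alpha else without
            if new_form.describe() != state[name].describe():
                changed = True
            state[name] = new_form
        if not changed:
            converged = True
            break
    final_forms = [state[s.name] for s in covariate_specs]
    model = _fit_forms(cohort, final_forms)
    return MfpResult(
        forms={f.name: f for f in final_forms},
        order=order,
        model=model,
        trace=trace,
        binary_tests=binary_tests,
        converged=converged,
        n_cycles=n_cycles,
    )


@dataclass
class InteractionTest:
    candidate: tuple[str, str]
    statistic: float
    df: int
    p_value: float
    included: bool
    skipped_collinear: bool = False


@dataclass
class MfpiResult:
    included: list[tuple[str, str]]
    trace: list[InteractionTest]
    model: FittedModel


def mfpi_test(
    cohort: pd.DataFrame,
    main_result: MfpResult,
    candidates: list[tuple[str, str]],
    alpha: float = 0.05,
) -> MfpiResult:
    """Interaction testing with frozen main-effect forms (MFPI).

    Each candidate (continuous, partner) adds the products of the continuous
    variable's frozen FP columns with the partner's column(s); the deviance
    difference against the current model is chi-square with df = number of
    added columns.  Forward selection: the most significant candidate below
    ``alpha`` is added, the rest re-tested, until none qualifies.  Candidates
    whose product columns are collinear with the existing design are skipped
    with a warning.
    """
    forms = [main_result.forms[n] for n in main_result.forms]
    in_model = {f.name for f in forms if f.in_model}
    included: list[tuple[str, str]] = []
    trace: list[InteractionTest] = []
    base_fit = _fit_forms(cohort, forms, interactions=included)
    remaining = []
    for cand in candidates:
        if cand[0] not in in_model or cand[1] not in in_model:
            warnings.warn(
                f"interaction {cand[0]}x{cand[1]} skipped: a member is not in "
                "the main-effects model"
            )
            continue
        remaining.append(cand)
    while remaining:
        results = []
        for cand in remaining:
            try:
                fit = _fit_forms(cohort, forms, interactions=included + [cand])
            except RankDeficientError as err:
                warnings.warn(
                    f"interaction {cand[0]}x{cand[1]} skipped (collinear): {err}"
                )
                trace.append(InteractionTest(cand, float("nan"), 0, float("nan"),
                                             False, skipped_collinear=True))
                continue
            df_added = fit.n_params - base_fit.n_params
            stat, p = deviance_difference_test(
                base_fit.deviance, fit.deviance, df_added
            )
            results.append((p, cand, stat, df_added, fit))
        remaining = [c for c in remaining
                     if c in [r[1] for r in results]]
        if not results:
            break
        results.sort(key=lambda r: r[0])
        p, cand, stat, df_added, fit = results[0]
        if p < alpha:
            included.append(cand)
            base_fit = fit
            trace.append(InteractionTest(cand, stat, df_added, p, True))
            remaining.remove(cand)
        else:
            for p_, cand_, stat_, df_, _ in results:
                trace.append(InteractionTest(cand_, stat_, df_, p_, False))
            break
    return MfpiResult(included=included, trace=trace, model=base_fit)


def lowess_logit_check(
    cohort: pd.DataFrame,
    x_variable: str,
    stratifier: str,
    bins: int = 20,
    frac: float = 0.6,
    it: int = 1,
) -> dict:
    """Per-stratum lowess-smoothed empirical logits of the outcome vs x.

    Within each stratum the outcome is binned on x (equal-count bins), the
    death rate continuity-corrected as (d + 0.5) / (n + 1), logit-transformed
    and smoothed (tricube lowess, span ``frac``, ``it`` robustness
    iterations).  Used to verify interactions graphically: diverging smoothed
    slopes across strata corroborate a detected interaction.
    """
    if bins < 5:
        raise ValueError("need at least 5 bins")
    strata = cohort[stratifier].dropna().unique()
    if len(strata) < 2:
        raise ValueError("need at least 2 strata")
    out = {}
    for s in sorted(strata):
        sub = cohort[cohort[stratifier] == s]
        if len(sub) == 0:
            warnings.warn(f"stratum {s!r} empty; omitted")
            continue
        x = sub[x_variable].to_numpy(float)
        y = sub["died"].to_numpy(float)
        edges = np.unique(np.quantile(x, np.linspace(0, 1, bins + 1)))
        idx = np.clip(np.digitize(x, edges[1:-1]), 0, len(edges) - 2)
        xs, logits = [], []
        for b in range(len(edges) - 1):
            m = idx == b
            if m.sum() == 0:
                continue
            phat = (y[m].sum() + 0.5) / (m.sum() + 1.0)
            xs.append(x[m].mean())
            logits.append(np.log(phat / (1 - phat)))
        sm = _sm_lowess(np.array(logits), np.array(xs), frac=frac, it=it,
                        return_sorted=True)
        out[s] = {"x": sm[:, 0], "logit": sm[:, 1],
                  "raw_x": np.array(xs), "raw_logit": np.array(logits)}
    return out
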