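"""Comparison models for the FP mortality curve.

Three conventional alternatives to the FP model -- untransformed linear BMI,
linear-quadratic BMI, and categorical (WHO classes or narrow bins) -- plus
the sensitivity refits (dropping early deaths, dropping extreme BMI) used to
check that the fitted curve is not driven by reverse causation or outliers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fp_core import PowerPair, centered_basis, fp_transform
from .mfp_selection import (
    CovariateSpec,
    MfpResult,
    SelectedForm,
    build_design,
    linear_form,
    mfp_cycle,
)
from .weighted_glm import FittedModel, deviance_difference_test, fit_logistic


@dataclass(frozen=True)
class BMICategoryScheme:
    """Contiguous left-closed right-open BMI intervals covering [lower, inf)."""

    name: str
    breakpoints: tuple[float, ...]  # ascending; last interval is open-ended
    labels: tuple[str, ...]
    reference_category: str

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.breakpoints):
            raise ValueError("need one label per interval")
        if list(self.breakpoints) != sorted(self.breakpoints):
            raise ValueError("breakpoints must be ascending")
        if self.reference_category not in self.labels:
            raise ValueError("reference category not among labels")


WHO_SCHEME = BMICategoryScheme(
    name="who",
    breakpoints=(18.5, 25.0, 30.0, 35.0, 40.0),
    labels=("Normal", "Overweight", "Obese I", "Obese II", "Obese III"),
    reference_category="Normal",
)


def narrow_bin_scheme() -> BMICategoryScheme:
    """30 narrow bins: 1-unit bins on [18.5, 40), 2-unit bins on [40, 54),
    one open bin [54, inf).  Reference: the bin containing BMI 22."""
    cuts = [18.5] + list(np.arange(19.0, 40.0, 1.0)) + list(
        np.arange(40.0, 54.0, 2.0)
    ) + [54.0]
    labels = tuple(
        f"[{lo:g},{hi:g})" for lo, hi in zip(cuts[:-1], cuts[1:])
    ) + (f"[{cuts[-1]:g},inf)",)
    ref = [lab for lo, lab in zip(cuts, labels) if lo <= 22.0][-1]
    return BMICategoryScheme("narrow", tuple(cuts), labels, ref)


def categorize_bmi(bmi, scheme: BMICategoryScheme):
    """Category label(s) for BMI value(s); boundaries open to the right
    (25.0 is Overweight under the WHO scheme)."""
    arr = np.atleast_1d(np.asarray(bmi, dtype=float))
    if np.any(arr < scheme.breakpoints[0]):
        bad = arr[arr < scheme.breakpoints[0]][0]
        raise ValueError(
            f"BMI {bad} below the {scheme.name!r} scheme support "
            f"(starts at {scheme.breakpoints[0]})"
        )
    idx = np.searchsorted(scheme.breakpoints, arr, side="right") - 1
    labels = np.asarray(scheme.labels, dtype=object)[idx]
    return labels[0] if np.isscalar(bmi) or np.ndim(bmi) == 0 else labels


@dataclass
class ComparatorModel:
    """A fitted comparison model plus what is needed to predict from it."""

    kind: str
    model: FittedModel
    bmi_basis: object | None  # FPBasis for continuous kinds
    scheme: BMICategoryScheme | None
    merged_categories: dict[str, str]
    adjusters: list[SelectedForm]

    def bmi_design(self, bmi) -> np.ndarray:
        arr = np.atleast_1d(np.asarray(bmi, dtype=float))
        if self.kind in ("untransformed-linear", "linear-quadratic"):
            return fp_transform(arr, self.bmi_basis)
        labels = categorize_bmi(arr, self.scheme)
        labels = np.array(
            [self.merged_categories.get(lab, lab) for lab in labels], dtype=object
        )
        cats = [lab for lab in self.scheme.labels
                if lab != self.scheme.reference_category
                and lab not in self.merged_categories]
        return np.column_stack([(labels == c).astype(float) for c in cats])

    def predict(self, bmi, adjuster_row: np.ndarray) -> np.ndarray:
        from .weighted_glm import predict_mortality

        bd = self.bmi_design(bmi)
        rows = np.column_stack([bd, np.tile(adjuster_row, (bd.shape[0], 1))])
        return predict_mortality(self.model, rows)


def fit_comparator(
    cohort: pd.DataFrame,
    model_kind: str,
    adjusters: list[SelectedForm],
    scheme: BMICategoryScheme | None = None,
    bmi_scale: float = 10.0,
) -> ComparatorModel:
    """Fit one comparison model with BMI entered per ``model_kind``.

    ``model_kind`` is one of ``untransformed-linear``, ``linear-quadratic``
    or ``categorical`` (the latter requiring a scheme; empty categories are
    merged into their left neighbour with a warning).  Adjusters (age in its
    selected FP form, smoking) are passed as frozen SelectedForms.
    """
    bmi = cohort["bmi"].to_numpy(float)
    y = cohort["died"].to_numpy(float)
    w = cohort["weight"].to_numpy(float)
    adj_X, adj_labels = build_design(cohort, adjusters)
    merged: dict[str, str] = {}
    if model_kind == "untransformed-linear":
        basis = centered_basis(bmi, PowerPair((1.0,)), bmi_scale)
        X = fp_transform(bmi, basis)
        labels = basis.column_labels("bmi")
    elif model_kind == "linear-quadratic":
        basis = centered_basis(bmi, PowerPair((1.0, 2.0)), bmi_scale)
        X = fp_transform(bmi, basis)
        labels = basis.column_labels("bmi")
    elif model_kind == "categorical":
        if scheme is None:
            raise ValueError("categorical model requires a scheme")
        basis = None
        lab_arr = categorize_bmi(bmi, scheme)
        counts = pd.Series(lab_arr).value_counts()
        for i, lab in enumerate(scheme.labels):
            if counts.get(lab, 0) == 0:
                neighbour = scheme.labels[max(i - 1, 0)]
                if neighbour == lab and len(scheme.labels) > 1:
                    neighbour = scheme.labels[1]
                merged[lab] = neighbour
                warnings.warn(
                    f"category {lab!r} empty; merged into {neighbour!r}"
                )
        lab_arr = np.array([merged.get(lab, lab) for lab in lab_arr], dtype=object)
        cats = [lab for lab in scheme.labels
                if lab != scheme.reference_category and lab not in merged]
        X = np.column_stack([(lab_arr == c).astype(float) for c in cats])
        labels = [f"bmi[{c}]" for c in cats]
    else:
        raise ValueError(f"unknown model kind {model_kind!r}")
    fit = fit_logistic(
        np.column_stack([X, adj_X]), y, w, labels + adj_labels
    )
    return ComparatorModel(
        kind=model_kind, model=fit, bmi_basis=basis, scheme=scheme,
        merged_categories=merged, adjusters=list(adjusters),
    )


def sensitivity_refit(
    cohort: pd.DataFrame,
    variant: str,
    covariate_specs: list[CovariateSpec],
    alpha: float = 0.05,
    bmi_grid: np.ndarray | None = None,
) -> tuple[MfpResult, pd.DataFrame]:
    """Re-run the full MFP selection on a filtered cohort.

    ``variant``: ``exclude_early_deaths`` drops subjects dying within one
    year of baseline; ``exclude_extreme_bmi`` drops BMI > 50.  Emits a
    warning if the filter removes more than half the deaths.  Returns the
    refitted result and curve points (linear predictor of the BMI block) on a
    common grid for overlay comparison.
    """
    if variant == "exclude_early_deaths":
        if "time_to_death" not in cohort.columns:
            raise ValueError("early-death exclusion needs a time_to_death column")
        keep = ~((cohort["died"] == 1) & (cohort["time_to_death"] < 1.0))
    elif variant == "exclude_extreme_bmi":
        keep = cohort["bmi"] <= 50.0
    else:
        raise ValueError(f"unknown sensitivity variant {variant!r}")
    filtered = cohort[keep].reset_index(drop=True)
    deaths_before = int((cohort["died"] == 1).sum())
    deaths_after = int((filtered["died"] == 1).sum())
    if deaths_before and deaths_after < 0.5 * deaths_before:
        warnings.warn(
            f"{variant} removed {deaths_before - deaths_after}/{deaths_before} "
            "deaths (more than half)"
        )
    result = mfp_cycle(filtered, covariate_specs, alpha)
    if bmi_grid is None:
        bmi_grid = np.arange(18.5, 60.5, 0.5)
    return result, bmi_contribution_curve(result, bmi_grid)


def bmi_contribution_curve(result: MfpResult, bmi_grid) -> pd.DataFrame:
    """The BMI block of the fitted logit on a grid (centering-dependent up to
    an additive constant, so overlay comparisons should anchor curves at a
    common reference BMI)."""
    bmi_grid = np.asarray(bmi_grid, dtype=float)
    form = result.forms.get("bmi")
    contrib = np.zeros(len(bmi_grid))
    if form is not None and form.in_model:
        cols = fp_transform(bmi_grid, form.basis)
        labels = result.model.design_labels
        beta = result.model.coefficients
        for j, lab in enumerate(form.basis.column_labels("bmi")):
            contrib += beta[1 + labels.index(lab)] * cols[:, j]
    return pd.DataFrame({"bmi": bmi_grid, "bmi_logit_contribution": contrib})


@dataclass
class ModelComparison:
    deviance_difference: float
    df: int
    p_value: float | None
    nested: bool
    max_abs_curve_diff: float | None
    mean_abs_curve_diff: float | None


def compare_models(
    main: FittedModel,
    comparator: FittedModel,
    main_curve: np.ndarray | None = None,
    comparator_curve: np.ndarray | None = None,
    nested: bool | None = None,
    force_chi2: bool = False,
) -> ModelComparison:
    """Deviance-difference comparison of two fits on the identical cohort.

    ``deviance_difference`` is comparator minus main (positive favours the
    main model).  df is the parameter-count difference; a chi-square p-value
    is emitted only for nested comparisons (or under ``force_chi2``, which
    mimics reporting conventions that apply the chi-square reference
    regardless of nesting).  Curve divergence summaries are computed when
    predicted-mortality curves on a common grid are supplied.
    """
    if main.n_obs != comparator.n_obs:
        raise ValueError(
            f"models fitted on differing cohorts (n={main.n_obs} vs "
            f"{comparator.n_obs}); comparison is meaningless"
        )
    dd = comparator.deviance - main.deviance
    df = abs(main.n_params - comparator.n_params)
    if nested is None:
        nested = False
    p = None
    if df >= 1 and (nested or force_chi2):
        _, p = deviance_difference_test(
            max(comparator.deviance, main.deviance),
            min(comparator.deviance, main.deviance),
            df,
        )
    max_d = mean_d = None
    if main_curve is not None and comparator_curve is not None:
        diff = np.abs(np.asarray(main_curve) - np.asarray(comparator_curve))
        max_d = float(diff.max())
        mean_d = float(diff.mean())
    return ModelComparison(dd, df, p, nested, max_d, mean_d)
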