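"""Survey-weighted logistic regression via iteratively reweighted least squares.

Weights are treated as pseudo-likelihood frequency weights: the fit maximises
the weighted Bernoulli log-likelihood

    l(beta) = sum_i w_i [ y_i ln pi_i + (1 - y_i) ln(1 - pi_i) ],

and the default covariance is the inverse of the weighted Fisher information
(model-based).  A design-based sandwich covariance is available as an optional
extra for users who want robustness to the weighting, but deviance-difference
chi-square tests between nested fits use the weighted likelihood directly.
Deviance is defined as -2 * l(beta) (the saturated model contributes zero for
a binary outcome).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats
from scipy.special import expit

_PROB_CLIP = 1e-12
_DEV_RTOL = 1e-10
_MAX_ITER = 100


class RankDeficientError(ValueError):
    """Design matrix is rank deficient; message names the collinear columns."""


@dataclass
class FittedModel:
    """One weighted logistic fit.

    ``coefficients`` holds the intercept first, then the design columns in
    declared order; ``design_labels`` names the non-intercept columns.
    ``deviance`` is -2 * ``loglik`` by construction.
    """

    coefficients: np.ndarray
    covariance: np.ndarray
    deviance: float
    loglik: float
    n_obs: int
    converged: bool
    design_labels: list[str]
    message: str = ""
    sandwich_covariance: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_params(self) -> int:
        return len(self.coefficients)

    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance))

    def coef_table(self) -> list[tuple[str, float, float]]:
        labels = ["(Intercept)"] + list(self.design_labels)
        return list(zip(labels, self.coefficients.tolist(), self.se().tolist()))


def _check_rank(A: np.ndarray, labels: list[str]) -> None:
    # QR with column pivoting flags which columns are linearly dependent
    _, R, piv = linalg.qr(A, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = max(A.shape) * np.finfo(float).eps * (diag[0] if diag.size else 0.0)
    rank = int(np.sum(diag > tol))
    if rank < A.shape[1]:
        all_labels = ["(Intercept)"] + labels
        bad = [all_labels[j] for j in piv[rank:]]
        raise RankDeficientError(
            f"design matrix is rank deficient (rank {rank} < {A.shape[1]}); "
            f"collinear columns: {bad}"
        )


def fit_logistic(
    design,
    outcome,
    weights=None,
    design_labels: list[str] | None = None,
    compute_sandwich: bool = False,
    normalize_weights: bool = True,
    max_iter: int = _MAX_ITER,
) -> FittedModel:
    """Fit a weighted logistic regression (intercept added automatically).

    Parameters
    ----------
    design : array-like of shape (n, k)
        Covariate columns, already transformed/centered by the caller.  May
        be empty (k = 0) for an intercept-only fit.
    outcome : array-like of 0/1
    weights : positive array-like, optional (default all ones)
    design_labels : names for the k columns; defaults to x1..xk.
    compute_sandwich : also compute the design-based sandwich covariance.
    normalize_weights : rescale weights to mean 1 (sum = n) before fitting.
        Coefficient estimates are invariant to weight scale, but the
        log-likelihood, deviance and model-based covariance are not: survey
        weights carry an arbitrary population scale (and pooled-year weights
        a 1/n_years factor), and chi-square deviance tests and Wald
        covariances are calibrated only when the total weight equals the
        sample size.  Disable to fit on the raw weight scale.

    Returns a :class:`FittedModel`; hitting the iteration cap (e.g. under
    perfect separation) sets ``converged=False`` with a diagnostic message
    rather than raising.
    """
    X = np.asarray(design, dtype=float)
    if X.ndim == 1:
        X = X.reshape(-1, 1) if X.size else X.reshape(0, 0)
    y = np.asarray(outcome, dtype=float).ravel()
    n = y.size
    if X.size == 0:
        X = np.empty((n, 0))
    if X.shape[0] != n:
        raise ValueError(f"design has {X.shape[0]} rows but outcome has {n}")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float).ravel()
    if w.shape[0] != n:
        raise ValueError("weights length mismatch")
    if not np.all(np.isfinite(X)):
        raise ValueError("design contains non-finite values")
    if not np.all((y == 0) | (y == 1)):
        raise ValueError("outcome must be coded 0/1")
    if not np.all(w > 0):
        raise ValueError("weights must be strictly positive")
    if normalize_weights:
        w = w * (n / w.sum())

    labels = design_labels if design_labels is not None else [
        f"x{j + 1}" for j in range(X.shape[1])
    ]
    if len(labels) != X.shape[1]:
        raise ValueError("design_labels length mismatch")

    A = np.column_stack([np.ones(n), X])
    _check_rank(A, labels)

    # start from the intercept-only MLE
    beta = np.zeros(A.shape[1])
    ybar = np.clip(np.average(y, weights=w), _PROB_CLIP, 1 - _PROB_CLIP)
    beta[0] = np.log(ybar / (1 - ybar))

    def weighted_dev(b: np.ndarray) -> float:
        p = np.clip(expit(A @ b), _PROB_CLIP, 1 - _PROB_CLIP)
        return -2.0 * float(np.sum(w * (y * np.log(p) + (1 - y) * np.log1p(-p))))

    dev = weighted_dev(beta)
    converged = False
    message = ""
    info = None
    for _ in range(max_iter):
        p = np.clip(expit(A @ beta), _PROB_CLIP, 1 - _PROB_CLIP)
        irls_w = w * p * (1 - p)
        score = A.T @ (w * (y - p))
        info = A.T @ (A * irls_w[:, None])
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            message = "singular information matrix during IRLS"
            break
        # step-halving keeps the deviance non-increasing
        new_dev = weighted_dev(beta + step)
        halvings = 0
        while new_dev > dev + 1e-12 and halvings < 30:
            step *= 0.5
            halvings += 1
            new_dev = weighted_dev(beta + step)
        beta = beta + step
        if abs(dev - new_dev) <= _DEV_RTOL * (abs(dev) + 0.1):
            dev = new_dev
            converged = True
            break
        dev = new_dev
    else:
        message = f"IRLS iteration cap ({max_iter}) reached"

    p = np.clip(expit(A @ beta), _PROB_CLIP, 1 - _PROB_CLIP)
    if not converged and not message:
        message = "IRLS did not converge"
    if converged and dev < 1e-6 and A.shape[1] > 1:
        # every observation fitted perfectly: coefficients are diverging
        converged = False
        message = (
            "perfect separation suspected: deviance collapsed to "
            f"{dev:.3g}; coefficients are not identified"
        )
    if not converged and (p.min() < 1e-8 or p.max() > 1 - 1e-8):
        message += "; fitted probabilities at the clip boundary suggest separation"

    info = A.T @ (A * (w * p * (1 - p))[:, None])
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.full((A.shape[1], A.shape[1]), np.nan)
        converged = False
        message += "; information matrix singular at the solution"
    loglik = -dev / 2.0

    sandwich = None
    if compute_sandwich:
        score_rows = A * (w * (y - p))[:, None]
        meat = score_rows.T @ score_rows
        sandwich = cov @ meat @ cov

    return FittedModel(
        coefficients=beta,
        covariance=cov,
        deviance=dev,
        loglik=loglik,
        n_obs=n,
        converged=converged,
        design_labels=list(labels),
        message=message,
        sandwich_covariance=sandwich,
    )


def predict_mortality(model: FittedModel, design_row) -> float | np.ndarray:
    """Inverse-logit of the linear predictor for one or more design rows.

    The caller must apply the same FP scaling/centering used at fit time.
    """
    row = np.asarray(design_row, dtype=float)
    k = model.n_params - 1
    if row.ndim == 1:
        if row.size != k:
            raise ValueError(f"expected {k} design values, got {row.size}")
        eta = model.coefficients[0] + row @ model.coefficients[1:]
    else:
        if row.shape[1] != k:
            raise ValueError(f"expected {k} design columns, got {row.shape[1]}")
        eta = model.coefficients[0] + row @ model.coefficients[1:]
    return expit(eta)


def deviance_difference_test(
    dev_reduced: float, dev_full: float, df: int, tol: float = 1e-6
) -> tuple[float, float]:
    """Chi-square test on the deviance difference between nested fits.

    Returns ``(statistic, p_value)`` with the statistic clamped at zero;
    a deviance difference below ``-tol`` indicates non-nested models or a
    failed fit and raises.
    """
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    stat = dev_reduced - dev_full
    if stat < -tol * (abs(dev_full) + 1.0):
        raise ValueError(
            f"reduced-model deviance {dev_reduced} is below full-model deviance "
            f"{dev_full} beyond tolerance; models are not nested or a fit failed"
        )
    stat = max(stat, 0.0)
    return stat, float(stats.chi2.sf(stat, df))
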