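"""Fractional-polynomial (FP) transformation engine.

An FP basis for a positive covariate x is built from powers drawn from the
canonical set S = {-2, -1, -0.5, 0, 0.5, 1, 2, 3}, where power 0 denotes the
natural-log transform.  A degree-2 FP with distinct powers (p1, p2) spans
{x^p1, x^p2}; a repeated power (p, p) spans {x^p, x^p * ln x} (for p = 0:
{ln x, (ln x)^2}).  Covariates are pre-divided by a positive scale (BMI by 10
here) and each transformed column is centered by subtracting a constant, which
stabilises the fit numerically and gives the intercept an interpretable
reference point without changing slopes or deviance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations_with_replacement

import numpy as np

#: Canonical FP power set; 0 encodes the natural-log transform.
POWER_SET: tuple[float, ...] = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)


class FPDomainError(ValueError):
    """Raised when a value falls outside the positive domain of an FP transform."""


@dataclass(frozen=True)
class PowerPair:
    """An FP power choice: one power (degree 1) or two (degree 2).

    Degree-2 powers are stored sorted ascending; a repeated pair (p, p) is
    legal and denotes the {x^p, x^p ln x} basis.
    """

    powers: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.powers) not in (1, 2):
            raise ValueError(f"degree must be 1 or 2, got {len(self.powers)} powers")
        for p in self.powers:
            if p not in POWER_SET:
                raise ValueError(f"power {p} not in the canonical set {POWER_SET}")
        if len(self.powers) == 2 and self.powers[0] > self.powers[1]:
            object.__setattr__(self, "powers", tuple(sorted(self.powers)))

    @property
    def degree(self) -> int:
        return len(self.powers)

    @property
    def is_repeated(self) -> bool:
        return self.degree == 2 and self.powers[0] == self.powers[1]

    def __str__(self) -> str:
        return "(" + ",".join(_fmt_power(p) for p in self.powers) + ")"


def _fmt_power(p: float) -> str:
    return str(int(p)) if float(p).is_integer() else str(p)


@dataclass(frozen=True)
class FPBasis:
    """A concrete FP transformation: powers plus scale and per-column centers.

    ``scale`` is the pre-division constant (10 for BMI and age here); every
    scaled value must be strictly positive because logs and negative powers
    are involved.  ``centers`` has one entry per basis column and is
    subtracted after transformation.
    """

    power_pair: PowerPair
    scale: float = 1.0
    centers: tuple[float, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError(f"scale must be positive, got {self.scale}")
        if self.centers is None:
            object.__setattr__(self, "centers", (0.0,) * self.power_pair.degree)
        if len(self.centers) != self.power_pair.degree:
            raise ValueError(
                f"need {self.power_pair.degree} centers, got {len(self.centers)}"
            )

    @property
    def degree(self) -> int:
        return self.power_pair.degree

    def column_labels(self, name: str) -> list[str]:
        pp = self.power_pair
        if pp.is_repeated:
            p = _fmt_power(pp.powers[0])
            if pp.powers[0] == 0.0:
                return [f"ln({name})", f"ln({name})^2"]
            return [f"{name}^{p}", f"{name}^{p}*ln({name})"]
        return [
            f"ln({name})" if p == 0.0 else f"{name}^{_fmt_power(p)}"
            for p in pp.powers
        ]


def _power_term(xs: np.ndarray, p: float) -> np.ndarray:
    return np.log(xs) if p == 0.0 else xs**p


def raw_fp_columns(xs: np.ndarray, power_pair: PowerPair) -> np.ndarray:
    """Uncentered FP columns of the already-scaled covariate, shape (n, degree)."""
    xs = np.asarray(xs, dtype=float)
    p = power_pair.powers
    if power_pair.degree == 1:
        cols = [_power_term(xs, p[0])]
    elif power_pair.is_repeated:
        first = _power_term(xs, p[0])
        cols = [first, first * np.log(xs)]
    else:
        cols = [_power_term(xs, p[0]), _power_term(xs, p[1])]
    return np.column_stack(cols)


def fp_transform(x, basis: FPBasis) -> np.ndarray:
    """Transform covariate values through an FP basis.

    Returns the centered design columns in power order: shape ``(degree,)``
    for scalar input, ``(n, degree)`` for array input.

    Raises
    ------
    FPDomainError
        If any scaled value is non-positive.
    """
    scalar = np.isscalar(x) or np.ndim(x) == 0
    xs = np.atleast_1d(np.asarray(x, dtype=float)) / basis.scale
    if not np.all(xs > 0):
        bad = np.asarray(x, dtype=float).ravel()[np.flatnonzero(~(xs > 0))[0]]
        raise FPDomainError(
            f"value {bad!r} is non-positive after scaling by {basis.scale}; "
            "FP transforms require strictly positive inputs"
        )
    cols = raw_fp_columns(xs, basis.power_pair) - np.asarray(basis.centers)
    return cols[0] if scalar else cols


def enumerate_candidates(max_degree: int) -> list[PowerPair]:
    """All FP candidates of the given degree, in ascending lexicographic order.

    Degree 1 yields the 8 singleton powers; degree 2 yields the 36 unordered
    pairs with repetition (28 distinct + 8 repeated).  The ordering is stable
    and used for deterministic tie-breaking during selection.
    """
    if max_degree == 1:
        return [PowerPair((p,)) for p in POWER_SET]
    if max_degree == 2:
        return [
            PowerPair(pair) for pair in combinations_with_replacement(POWER_SET, 2)
        ]
    raise ValueError(f"unsupported degree {max_degree}; must be 1 or 2")


def default_centering(values, power_pair: PowerPair, scale: float) -> tuple[float, ...]:
    """Centering constants: the FP transform evaluated at the sample mean.

    center_j = g_j(mean(x) / scale), one per basis column.  Centering at the
    transform of the (unweighted) mean, rather than at the mean of the
    transformed column, is the convention used throughout this package; it
    makes the intercept the linear predictor of a subject at the covariate
    mean.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot center on an empty sample")
    mean_scaled = values.mean() / scale
    if mean_scaled <= 0:
        raise FPDomainError(f"sample mean {values.mean()} non-positive after scaling")
    return tuple(raw_fp_columns(np.array([mean_scaled]), power_pair)[0])


def centered_basis(values, power_pair: PowerPair, scale: float) -> FPBasis:
    """Convenience: an FPBasis with default (transform-of-mean) centering."""
    return FPBasis(power_pair, scale, default_centering(values, power_pair, scale))
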