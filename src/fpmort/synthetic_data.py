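"""Synthetic NHIS-like cohort generator.

Emulates the statistical structure of the pooled 1997-2000 adult interview
cohort: two sex strata with their published mean ages and smoking
prevalences, a right-skewed (shifted-lognormal) BMI distribution calibrated to
the published WHO-category prevalences, pooled survey weights (gamma around 1,
divided by the number of pooled years), and a Bernoulli 5-year death outcome
drawn from a true fractional-polynomial logit whose slope coefficients are the
published estimates.  Everything is reproducible from a single integer seed.

Deliberate simplifications: weights are i.i.d. scalars (no cluster/stratum
design), covariates are drawn independently within sex, and death timing is
uniform over the horizon unless a reverse-causation hook is switched on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from . import reference as ref
from .fp_core import PowerPair, raw_fp_columns

COHORT_COLUMNS = [
    "id", "sex", "age", "bmi", "ever_smoker", "survey_year", "weight",
    "died", "time_to_death",
]


@dataclass(frozen=True)
class TrueModel:
    """The generating logit for one sex stratum.

    BMI enters as an FP2 of bmi/bmi_scale centered at the transform of
    ``bmi_center``; age as (age/age_scale)^age_power centered at the transform
    of ``age_center``.  ``age_slope_by_smoke`` allows an age x smoking
    interaction; ``age_bmi`` the two age x BMI product coefficients.
    """

    bmi_powers: PowerPair
    bmi1: float
    bmi2: float
    age_power: float
    age_slope_by_smoke: tuple[float, float]
    age_bmi: tuple[float, float]
    smoke: float
    intercept: float
    bmi_scale: float = 10.0
    age_scale: float = 10.0
    bmi_center: float = 27.0
    age_center: float = 46.0

    def linear_predictor(self, bmi, age, smoker) -> np.ndarray:
        bmi = np.asarray(bmi, float)
        age = np.asarray(age, float)
        smoker = np.asarray(smoker, float)
        bcols = raw_fp_columns(bmi / self.bmi_scale, self.bmi_powers)
        bcent = raw_fp_columns(
            np.array([self.bmi_center / self.bmi_scale]), self.bmi_powers
        )[0]
        bcols = bcols - bcent
        apow = PowerPair((self.age_power,))
        acol = raw_fp_columns(age / self.age_scale, apow)[:, 0]
        acent = raw_fp_columns(np.array([self.age_center / self.age_scale]), apow)[0, 0]
        acol = acol - acent
        b1 = self.bmi1 + self.age_bmi[0] * acol
        b2 = self.bmi2 + self.age_bmi[1] * acol
        a0, a1 = self.age_slope_by_smoke
        age_slope = np.where(smoker > 0.5, a1, a0)
        return (
            self.intercept
            + b1 * bcols[:, 0]
            + b2 * bcols[:, 1]
            + age_slope * acol
            + self.smoke * smoker
        )

    def death_probability(self, bmi, age, smoker) -> np.ndarray:
        return expit(self.linear_predictor(bmi, age, smoker))


def _reference_true_model(sex: str) -> TrueModel:
    m = ref.REFERENCE_MODELS[sex]
    return TrueModel(
        bmi_powers=m.bmi_powers,
        bmi1=m.bmi1,
        bmi2=m.bmi2,
        age_power=m.age_power,
        age_slope_by_smoke=m.age_slope_by_smoke,
        age_bmi=m.age_bmi,
        smoke=m.smoke,
        intercept=ref.GENERATOR_INTERCEPT[sex],
        bmi_center=ref.BMI_MEAN[sex],
        age_center=ref.MEAN_AGE[sex],
    )


@dataclass(frozen=True)
class SexStratumConfig:
    n: int
    age_loc: float
    age_sd: float
    smoking_prevalence: float
    bmi_shift: float
    bmi_mu: float
    bmi_sigma: float
    true_model: TrueModel

    def validate(self) -> None:
        if self.n <= 0:
            raise ValueError("stratum size must be positive")
        if not 0.0 < self.smoking_prevalence < 1.0:
            raise ValueError(
                f"smoking prevalence {self.smoking_prevalence} outside (0, 1)"
            )
        if self.bmi_sigma <= 0 or self.age_sd <= 0:
            raise ValueError("dispersion parameters must be positive")


@dataclass(frozen=True)
class GeneratorConfig:
    """Full generator configuration; defaults reproduce the published cohort
    structure (sample sizes scaled by ``n`` per stratum)."""

    strata: dict[str, SexStratumConfig]
    seed: int = 0
    horizon: float = 5.0
    years: tuple[int, ...] = (1997, 1998, 1999, 2000)
    #: gamma shape for raw weights (mean 1); shape 25 gives CV 0.2.  Mild
    #: dispersion keeps the naive weighted-likelihood chi-square tests and
    #: model-based covariances calibrated (design effect 1 + CV^2 ~ 1.04);
    #: real survey weights are more dispersed and would need design-effect
    #: corrections the analysis deliberately does not apply.
    weight_gamma_shape: float = 25.0
    age_range: tuple[float, float] = (18.0, 99.0)
    #: optional (bmi_threshold, extra_first_year_death_prob): injects excess
    #: early deaths among low-BMI subjects to emulate reverse causation.
    reverse_causation: tuple[float, float] | None = None

    @property
    def n_pooled_years(self) -> int:
        return len(self.years)

    def validate(self) -> None:
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")
        for cfg in self.strata.values():
            cfg.validate()


def default_config(
    n_per_stratum: int = 50_000, seed: int = 0, sexes: tuple[str, ...] = ("male", "female")
) -> GeneratorConfig:
    """The calibrated default configuration (published-truth coefficients)."""
    strata = {
        sex: SexStratumConfig(
            n=n_per_stratum,
            age_loc=ref.AGE_TRUNCNORM_LOC[sex],
            age_sd=ref.AGE_SD,
            smoking_prevalence=ref.SMOKING_PREVALENCE[sex],
            bmi_shift=ref.BMI_LOGNORMAL[sex][0],
            bmi_mu=ref.BMI_LOGNORMAL[sex][1],
            bmi_sigma=ref.BMI_LOGNORMAL[sex][2],
            true_model=_reference_true_model(sex),
        )
        for sex in sexes
    }
    return GeneratorConfig(strata=strata, seed=seed)


def null_config(config: GeneratorConfig) -> GeneratorConfig:
    """Same marginals, but the outcome is independent of BMI (all BMI and
    interaction coefficients zeroed)."""
    strata = {
        sex: replace(
            cfg,
            true_model=replace(cfg.true_model, bmi1=0.0, bmi2=0.0, age_bmi=(0.0, 0.0)),
        )
        for sex, cfg in config.strata.items()
    }
    return replace(config, strata=strata)


def generate_cohort(config: GeneratorConfig, seed: int | None = None) -> pd.DataFrame:
    """Draw a raw cohort (before inclusion filtering) from the configuration.

    Byte-identical output for identical (config, seed).  BMI values above the
    recording ceiling 99.99 are retained here and removed by
    :func:`apply_inclusion`, mirroring how out-of-range records reach a real
    extract.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    frames = []
    offset = 0
    for sex in sorted(config.strata):
        cfg = config.strata[sex]
        n = cfg.n
        lo, hi = config.age_range
        a = (lo - cfg.age_loc) / cfg.age_sd
        b = (hi - cfg.age_loc) / cfg.age_sd
        age = stats.truncnorm.rvs(
            a, b, loc=cfg.age_loc, scale=cfg.age_sd, size=n, random_state=rng
        )
        bmi = cfg.bmi_shift + rng.lognormal(cfg.bmi_mu, cfg.bmi_sigma, n)
        smoker = (rng.random(n) < cfg.smoking_prevalence).astype(int)
        year = rng.choice(config.years, size=n)
        shape = config.weight_gamma_shape
        weight = rng.gamma(shape, 1.0 / shape, n) / config.n_pooled_years
        # the death model is only defined on positive scaled BMI; out-of-range
        # records get a placeholder outcome and are dropped at inclusion
        ok = bmi / cfg.true_model.bmi_scale > 0
        prob = np.zeros(n)
        prob[ok] = cfg.true_model.death_probability(bmi[ok], age[ok], smoker[ok])
        died = (rng.random(n) < prob).astype(int)
        ttd = np.where(died == 1, rng.uniform(0.0, config.horizon, n), np.nan)
        ttd = np.where(died == 1, np.maximum(ttd, 1e-9), np.nan)
        if config.reverse_causation is not None:
            thr, extra = config.reverse_causation
            low = (bmi < thr) & (died == 0)
            hit = low & (rng.random(n) < extra)
            died[hit] = 1
            ttd[hit] = rng.uniform(0.0, 1.0, n)[hit]
        frames.append(
            pd.DataFrame(
                {
                    "id": np.arange(offset, offset + n),
                    "sex": sex,
                    "age": age,
                    "bmi": bmi,
                    "ever_smoker": smoker,
                    "survey_year": year,
                    "weight": weight,
                    "died": died,
                    "time_to_death": ttd,
                }
            )
        )
        offset += n
    return pd.concat(frames, ignore_index=True)


def generate_null_cohort(config: GeneratorConfig, seed: int | None = None) -> pd.DataFrame:
    """As :func:`generate_cohort` with the outcome made independent of BMI."""
    return generate_cohort(null_config(config), seed=seed)


def apply_inclusion(records: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the study inclusion criteria and tally exclusions by reason.

    Drops: age < 18; BMI < 18.5; BMI missing or > 99.99; unknown smoking
    status.  A record excludable for several reasons is counted once, in the
    order above.  Idempotent.
    """
    df = records.copy()
    tally = {"age": 0, "bmi_low": 0, "bmi_range": 0, "smoking_missing": 0}
    age_bad = df["age"].isna() | (df["age"] < 18.0)
    tally["age"] = int(age_bad.sum())
    df = df[~age_bad]
    bmi_missing_or_high = df["bmi"].isna() | (df["bmi"] > 99.99)
    tally["bmi_range"] = int(bmi_missing_or_high.sum())
    df = df[~bmi_missing_or_high]
    bmi_low = df["bmi"] < 18.5
    tally["bmi_low"] = int(bmi_low.sum())
    df = df[~bmi_low]
    smoke_bad = df["ever_smoker"].isna()
    tally["smoking_missing"] = int(smoke_bad.sum())
    df = df[~smoke_bad]
    return df.reset_index(drop=True), tally


def write_cohort_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=COHORT_COLUMNS)


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns and c != "time_to_death"]
    if missing:
        raise ValueError(f"cohort CSV is missing required columns: {missing}")
    return df
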