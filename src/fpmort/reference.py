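"""Published reference values for the NHIS 1997-2000 BMI-mortality analysis.

These constants come from the published sex-stratified 5-year mortality study
of US adults (National Health Interview Survey 1997-2000 linked to the
National Death Index): descriptive calibration targets, the final
fractional-polynomial logistic coefficient estimates, and the reported
optimal-BMI (nadir) figures.  They serve two purposes here: as the default
"truth" of the synthetic cohort generator, and as inputs to the desk-level
worked examples (closed-form nadirs computed directly from the published
coefficients).

The published BMI-column centering constants are functions of unpublished
sample means, so absolute predicted probabilities from these coefficients are
not reproducible; slopes, curve shapes and nadirs are.
"""

from __future__ import annotations

from dataclasses import dataclass

from .fp_core import PowerPair

# --- Descriptive targets (final analytic cohort, pooled 1997-2000) -----------

MEAN_AGE = {"male": 45.49, "female": 47.13}
SMOKING_PREVALENCE = {"male": 0.5493, "female": 0.4047}
FIVE_YEAR_DEATH_RATE = {"male": 0.0637, "female": 0.0555}
SAMPLE_SIZE = {"male": 52549, "female": 65412}

#: WHO-category prevalence (%) among subjects with BMI >= 18.5:
#: Normal [18.5,25), Overweight [25,30), Obese I [30,35), Obese II [35,40),
#: Obese III 40+.
WHO_PREVALENCE_PCT = {
    "male": (35.66, 43.87, 14.97, 3.92, 1.58),
    "female": (48.06, 29.30, 14.14, 5.19, 3.31),
}


# --- Final FP logistic models (coefficient point estimates) ------------------


@dataclass(frozen=True)
class ReferenceModel:
    """Published coefficient set for one sex stratum.

    BMI enters as an FP2 of BMI/10 and age as (age/10)^2, both centered at the
    transform of the stratum mean (ages are published; BMI means are not).
    ``age_slope_by_smoke`` gives the age coefficient within each smoking
    stratum (equal entries mean no age-smoking interaction); ``age_bmi``
    holds the two age x BMI product coefficients (zeros mean none).
    """

    sex: str
    bmi_powers: PowerPair
    bmi1: float
    bmi2: float
    age_power: float
    age_slope_by_smoke: tuple[float, float]  # (never, ever)
    age_bmi: tuple[float, float]
    smoke: float
    intercept: float
    loglik: float
    bmi_scale: float = 10.0
    age_scale: float = 10.0

    @property
    def has_bmi_age_interaction(self) -> bool:
        return any(c != 0.0 for c in self.age_bmi)

    @property
    def has_age_smoke_interaction(self) -> bool:
        return self.age_slope_by_smoke[0] != self.age_slope_by_smoke[1]


MALE_MODEL = ReferenceModel(
    sex="male",
    bmi_powers=PowerPair((-2.0, -2.0)),
    bmi1=24.260,
    bmi2=-49.284,
    age_power=2.0,
    age_slope_by_smoke=(0.077, 0.077),
    age_bmi=(0.0, 0.0),
    smoke=0.581,
    intercept=-4.366,
    loglik=-9503.563,
)

FEMALE_MODEL = ReferenceModel(
    sex="female",
    bmi_powers=PowerPair((-2.0, -1.0)),
    bmi1=20.328,
    bmi2=-18.490,
    age_power=2.0,
    age_slope_by_smoke=(0.082, 0.075),
    age_bmi=(0.244, -0.115),
    smoke=0.832,
    intercept=-4.712,
    loglik=-10179.990,
)

REFERENCE_MODELS = {"male": MALE_MODEL, "female": FEMALE_MODEL}


# --- Published nadir (optimal BMI) results -----------------------------------

#: Male nadir is age- and smoking-constant (no BMI interactions).
MALE_NADIR = 26.97
MALE_NADIR_CI = (26.41, 27.54)
#: Female nadir increases with age (BMI x age interaction present).
FEMALE_NADIR_BY_AGE = {18: 19.25, 50: 22.34, 85: 26.86}
FEMALE_NADIR_CI_AGE50 = (20.10, 24.57)
LQ_NADIR = {"male": 31.84, "female": 23.04}

#: Published 5-year mortality estimates for 50-year-old never smokers under
#: the FP model (point estimates): at the optimal BMI and at BMI = 50.
MORTALITY_AT_OPTIMUM_NEVER_SMOKER = {"male": 0.0176, "female": 0.0100}
MORTALITY_AT_BMI50_NEVER_SMOKER = {"male": 0.0548, "female": 0.0355}


# --- Synthetic-generator calibration constants -------------------------------
# Shifted-lognormal BMI parameters fitted (least squares, at package build
# time) to the WHO-category prevalence targets above; age truncated-normal
# locations solved so the truncated mean matches the published mean age; the
# generator intercept calibrated so the overall simulated 5-year death rate
# matches the published rate (the published intercept refers to unpublished
# centering constants and is not directly transferable).

BMI_LOGNORMAL = {  # (shift, mu, sigma): bmi = shift + LogNormal(mu, sigma)
    "male": (17.9802, 2.11448, 0.45094),
    "female": (9.1933, 2.74036, 0.36288),
}
#: Mean BMI of the calibrated distribution conditional on BMI >= 18.5; used
#: as the generator's BMI centering point.
BMI_MEAN = {"male": 27.1522, "female": 26.4870}
AGE_TRUNCNORM_LOC = {"male": 42.7420, "female": 44.9079}
AGE_SD = 17.5
GENERATOR_INTERCEPT = {"male": -3.993, "female": -4.300}
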