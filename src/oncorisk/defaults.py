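"""Default study conditions for the synthetic matched cohort.

These constants define the data-generating world the package simulates: the
20 common cancer sites (with haematological vs solid classification and
sex-restricted sites), plausible UK primary-care marginals for the score's
predictors, sex-specific "true" scoring models used as the generating
hazard, site-level true log-hazard increments for cancer survivorship, and
predictor missingness rates of the order seen in routinely collected
primary-care data.  They are fixed study conditions, not tuning knobs.
"""

from __future__ import annotations

import math

from .scoring import CoefficientSet, FPTransformSpec, Term

#: The 20 cancer sites, haematological subset, and sex restrictions.
CANCER_SITES = (
    "oral_cavity",
    "oesophagus",
    "stomach",
    "colorectal",
    "liver",
    "pancreas",
    "lung",
    "melanoma",
    "breast",
    "cervix",
    "uterus",
    "ovary",
    "prostate",
    "kidney",
    "bladder",
    "brain_cns",
    "thyroid",
    "non_hodgkin_lymphoma",
    "multiple_myeloma",
    "leukaemia",
)

HAEMATOLOGICAL_SITES = frozenset(
    {"non_hodgkin_lymphoma", "multiple_myeloma", "leukaemia"}
)
FEMALE_ONLY_SITES = frozenset({"breast", "cervix", "uterus", "ovary"})
MALE_ONLY_SITES = frozenset({"prostate"})

#: Approximate relative frequencies of the 20 sites (normalised at use).
DEFAULT_SITE_FREQUENCIES = {
    "breast": 0.225,
    "prostate": 0.17,
    "colorectal": 0.12,
    "lung": 0.09,
    "melanoma": 0.05,
    "non_hodgkin_lymphoma": 0.045,
    "bladder": 0.04,
    "kidney": 0.03,
    "uterus": 0.03,
    "leukaemia": 0.03,
    "ovary": 0.025,
    "oesophagus": 0.02,
    "stomach": 0.02,
    "multiple_myeloma": 0.02,
    "oral_cavity": 0.02,
    "pancreas": 0.015,
    "cervix": 0.015,
    "brain_cns": 0.015,
    "thyroid": 0.01,
    "liver": 0.01,
}

#: True log-hazard increments for cancer survivorship by site: modest for
#: most solid tumours, larger for haematological, lung and bladder cancers,
#: echoing the excess-risk pattern reported for cancer survivors.
DEFAULT_CANCER_EFFECTS = {site: math.log(1.12) for site in CANCER_SITES}
DEFAULT_CANCER_EFFECTS.update(
    {
        "lung": math.log(1.45),
        "bladder": math.log(1.35),
        "brain_cns": math.log(1.25),
        "non_hodgkin_lymphoma": math.log(1.40),
        "multiple_myeloma": math.log(1.30),
        "leukaemia": math.log(1.45),
    }
)

SMOKING_LEVELS = ["non", "ex", "light", "moderate", "heavy"]
ETHNICITY_LEVELS = ["white", "south_asian", "black", "chinese_other", "mixed"]

#: Missingness fractions for the six substitutable predictors, of the order
#: seen for these variables in primary-care records (blood-test derived
#: variables missing far more often than smoking status).
DEFAULT_MISSINGNESS_RATES = {
    "smoking": 0.15,
    "bmi": 0.20,
    "ethnicity": 0.30,
    "sbp": 0.10,
    "sbp_sd": 0.40,
    "chol_hdl_ratio": 0.40,
}


def _common_terms(sex: str, compact: bool) -> list[Term]:
    smoking_coef = [0.19, 0.45, 0.56, 0.79]
    terms = [
        Term(
            name="age",
            transform=FPTransformSpec(powers=(-1.0, 3.0), pre_scale=10.0),
            coefficients=[-8.0, 0.0016] if sex == "male" else [-7.0, 0.0014],
        ),
        Term(
            name="sbp",
            transform=FPTransformSpec(powers=(1.0,)),
            coefficients=[0.012],
            age_interaction=[0.06],
        ),
        Term(
            name="chol_hdl_ratio",
            transform=FPTransformSpec(powers=(1.0,)),
            coefficients=[0.15],
        ),
        Term(
            name="smoking",
            levels=SMOKING_LEVELS,
            coefficients=smoking_coef,
            age_interaction=[2.0, 2.0, 2.5, 2.5],
        ),
        Term(name="diabetes", levels=["0", "1"], coefficients=[0.55]),
    ]
    if compact:
        return terms
    terms += [
        Term(
            name="bmi",
            transform=FPTransformSpec(powers=(-2.0, -2.0), pre_scale=10.0),
            coefficients=[-0.5, 1.8],
        ),
        Term(
            name="sbp_sd",
            transform=FPTransformSpec(powers=(1.0,)),
            coefficients=[0.011],
        ),
        Term(
            name="ethnicity",
            levels=ETHNICITY_LEVELS,
            coefficients=[0.35, -0.10, -0.20, 0.05],
        ),
        # deprivation twentile enters as an ordinal score 1..20
        Term(
            name="deprivation",
            transform=FPTransformSpec(powers=(1.0,)),
            coefficients=[0.022],
        ),
        Term(
            name="treated_hypertension",
            levels=["0", "1"],
            coefficients=[0.50],
            age_interaction=[2.5],
        ),
    ]
    return terms


def _centering_means(terms: list[Term]) -> dict[str, float]:
    # Means on the transformed scale for a cohort centred near age 63,
    # SBP 130 mmHg, BMI 26.5, cholesterol ratio 4.0.  Categorical
    # indicator columns are centred at plausible prevalences.
    means = {
        "age_1": 0.1635,
        "age_2": 273.0,
        "sbp": 130.0,
        "chol_hdl_ratio": 4.0,
        "smoking_ex": 0.25,
        "smoking_light": 0.09,
        "smoking_moderate": 0.09,
        "smoking_heavy": 0.09,
        "diabetes_1": 0.05,
        "bmi_1": 0.1465,
        "bmi_2": 0.1415,
        "sbp_sd": 9.8,
        "ethnicity_south_asian": 0.04,
        "ethnicity_black": 0.03,
        "ethnicity_chinese_other": 0.02,
        "ethnicity_mixed": 0.01,
        "deprivation": 10.5,
        "treated_hypertension_1": 0.12,
    }
    cols = {c for t in terms for c in t.columns()}
    return {k: v for k, v in means.items() if k in cols}


def _substitution_values(compact: bool) -> dict[str, object]:
    vals = {
        "smoking": "non",
        "sbp": 130.0,
        "chol_hdl_ratio": 4.0,
    }
    if not compact:
        vals.update({"bmi": 26.5, "ethnicity": "white", "sbp_sd": 9.8})
    return vals


def default_coefficient_set(sex: str, compact: bool = False) -> CoefficientSet:
    """Sex-specific true scoring model used as the generating hazard.

    ``compact=True`` returns a reduced model (fewer terms) intended for
    replicate-heavy simulation studies where fit time dominates.
    """
    if sex not in ("male", "female"):
        raise ValueError("sex must be 'male' or 'female'")
    terms = _common_terms(sex, compact)
    return CoefficientSet(
        sex=sex,
        # 10-year baseline survival at the centring means; men at higher risk
        baseline_survival_10y=0.86 if sex == "male" else 0.92,
        terms=terms,
        centering_means=_centering_means(terms),
        substitution_values=_substitution_values(compact),
        age_term="age",
    )
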