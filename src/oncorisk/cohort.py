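"""Synthetic matched cancer-survivor / cancer-free cohort generator.

Emulates the structure of a UK primary-care matched cohort: 1-year cancer
survivors each matched to up to five cancer-free individuals on sex and age
(within 3 years), with follow-up from an index date one year after
diagnosis.  Cardiovascular event times are drawn from a proportional-hazards
model with an exponential baseline whose linear predictor comes from a
"true" scoring model (so parameter recovery can be tested against known
ground truth), with cancer survivorship adding site-specific log-hazard
increments.  Non-cardiovascular death and loss to follow-up are independent
exponential competing processes; follow-up is administratively truncated at
the 10-year horizon.

Eligibility fields (prior cardiovascular disease, recent statin scripts,
pre-index registration time) are generated directly so the study's
exclusion filters can be applied and accounted for.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import defaults
from .defaults import (
    CANCER_SITES,
    FEMALE_ONLY_SITES,
    HAEMATOLOGICAL_SITES,
    MALE_ONLY_SITES,
    ETHNICITY_LEVELS,
    SMOKING_LEVELS,
)
from .scoring import SUBSTITUTABLE_PREDICTORS, CoefficientSet

__all__ = [
    "SimulationConfig",
    "ExclusionReport",
    "generate_cohort",
    "apply_exclusions",
    "inject_missingness",
    "write_ground_truth",
    "COHORT_COLUMNS",
]

#: Fixed column order of the cohort table.
COHORT_COLUMNS = [
    "participant_id",
    "matched_set_id",
    "group",
    "cancer_site",
    "cancer_type",
    "sex",
    "age_at_index",
    "smoking",
    "bmi",
    "ethnicity",
    "sbp",
    "sbp_sd",
    "chol_hdl_ratio",
    "deprivation",
    "diabetes",
    "treated_hypertension",
    "prior_cvd",
    "statin_scripts_prior_year",
    "pre_index_followup",
    "followup_time",
    "event_cvd",
    "event_death",
]


class CohortError(ValueError):
    """Invalid simulation configuration or empty generation request."""


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort draw."""

    n_matched_sets: int
    matching_ratio: int = 5
    age_range: tuple[float, float] = (25.0, 84.0)
    true_model: dict[str, CoefficientSet] | None = None  # sex -> generating model
    cancer_effects: dict[str, float] = field(
        default_factory=lambda: dict(defaults.DEFAULT_CANCER_EFFECTS)
    )
    site_frequencies: dict[str, float] = field(
        default_factory=lambda: dict(defaults.DEFAULT_SITE_FREQUENCIES)
    )
    missingness_rates: dict[str, float] = field(
        default_factory=lambda: dict(defaults.DEFAULT_MISSINGNESS_RATES)
    )
    competing_death_rate: float = 0.02  # events per person-year
    survivor_death_multiplier: float = 1.8  # excess non-CVD mortality post cancer
    censoring_rate: float = 0.07  # loss to follow-up, events per person-year
    admin_horizon: float = 10.0
    female_fraction: float = 0.58
    seed: int = 0
    compact_model: bool = False

    def __post_init__(self) -> None:
        if self.n_matched_sets < 1:
            raise CohortError("n_matched_sets must be >= 1")
        if self.matching_ratio < 1:
            raise CohortError("matching_ratio must be >= 1")
        lo, hi = self.age_range
        if not (25.0 <= lo < hi <= 84.0):
            raise CohortError("age_range must lie within [25, 84]")
        for name in ("competing_death_rate", "censoring_rate", "admin_horizon"):
            if getattr(self, name) < 0:
                raise CohortError(f"{name} must be >= 0")
        total = sum(self.site_frequencies.values())
        if not math.isclose(total, 1.0, abs_tol=1e-6):
            raise CohortError(f"site_frequencies sum to {total}, expected 1")
        unknown = set(self.site_frequencies) - set(CANCER_SITES)
        if unknown:
            raise CohortError(f"unknown cancer sites {sorted(unknown)}")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise CohortError("female_fraction must be in [0, 1]")
        if self.true_model is None:
            self.true_model = {
                s: defaults.default_coefficient_set(s, compact=self.compact_model)
                for s in ("male", "female")
            }

    def with_uniform_cancer_effect(self, log_hr: float) -> "SimulationConfig":
        """Copy of this config with the same log-HR for every cancer site."""
        return dataclasses.replace(
            self, cancer_effects={s: float(log_hr) for s in CANCER_SITES}
        )

    def ground_truth(self) -> dict:
        """Generating parameters, suitable for the sidecar file."""
        return {
            "seed": self.seed,
            "n_matched_sets": self.n_matched_sets,
            "matching_ratio": self.matching_ratio,
            "age_range": list(self.age_range),
            "cancer_effects": {k: float(v) for k, v in self.cancer_effects.items()},
            "site_frequencies": {
                k: float(v) for k, v in self.site_frequencies.items()
            },
            "missingness_rates": {
                k: float(v) for k, v in self.missingness_rates.items()
            },
            "competing_death_rate": self.competing_death_rate,
            "survivor_death_multiplier": self.survivor_death_multiplier,
            "censoring_rate": self.censoring_rate,
            "admin_horizon": self.admin_horizon,
            "female_fraction": self.female_fraction,
            "true_model": {s: m.to_dict() for s, m in self.true_model.items()},
        }


@dataclass
class ExclusionReport:
    """Per-criterion removal counts; overlapping criteria are double counted."""

    n_input: int
    removed_age: int
    removed_prior_cvd: int
    removed_statin: int
    removed_short_preindex: int
    n_removed: int
    retained_survivor: int
    retained_cancer_free: int
    double_counted: bool = True

    @property
    def n_retained(self) -> int:
        return self.retained_survivor + self.retained_cancer_free

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "quantity": [
                    "input",
                    "removed_age_out_of_range",
                    "removed_prior_cvd",
                    "removed_current_statin",
                    "removed_short_preindex_followup",
                    "removed_total",
                    "retained_survivor",
                    "retained_cancer_free",
                ],
                "count": [
                    self.n_input,
                    self.removed_age,
                    self.removed_prior_cvd,
                    self.removed_statin,
                    self.removed_short_preindex,
                    self.n_removed,
                    self.retained_survivor,
                    self.retained_cancer_free,
                ],
            }
        )


def _draw_sites(rng: np.random.Generator, sexes: np.ndarray, cfg) -> np.ndarray:
    """Site draw conditional on sex (sex-specific sites restricted)."""
    sites = np.array(list(cfg.site_frequencies.keys()))
    freqs = np.array([cfg.site_frequencies[s] for s in sites], dtype=float)
    out = np.empty(len(sexes), dtype=object)
    for sex, banned in (("male", FEMALE_ONLY_SITES), ("female", MALE_ONLY_SITES)):
        mask = sexes == sex
        if not mask.any():
            continue
        ok = ~np.isin(sites, list(banned))
        p = freqs * ok
        if p.sum() <= 0:
            raise CohortError(f"no cancer sites available for sex {sex}")
        out[mask] = rng.choice(sites[ok], size=mask.sum(), p=p[ok] / p[ok].sum())
    return out


def _draw_predictors(rng: np.random.Generator, n: int) -> dict[str, np.ndarray]:
    """Independent marginal draws for the score's predictors."""
    return {
        "smoking": rng.choice(
            SMOKING_LEVELS, size=n, p=[0.48, 0.25, 0.09, 0.09, 0.09]
        ),
        "bmi": np.clip(rng.lognormal(math.log(26.2), 0.16, n), 15.0, 55.0),
        "ethnicity": rng.choice(
            ETHNICITY_LEVELS, size=n, p=[0.90, 0.04, 0.03, 0.02, 0.01]
        ),
        "sbp": np.clip(rng.normal(130.0, 16.0, n), 85.0, 220.0),
        "sbp_sd": np.clip(rng.lognormal(math.log(9.0), 0.40, n), 0.5, 40.0),
        "chol_hdl_ratio": np.clip(rng.lognormal(math.log(3.9), 0.25, n), 1.0, 12.0),
        "deprivation": rng.integers(1, 21, n).astype(float),
        "diabetes": (rng.random(n) < 0.05).astype(int).astype(str),
        "treated_hypertension": (rng.random(n) < 0.12).astype(int).astype(str),
    }


def generate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Draw a matched cohort with known generating hazard.

    Each matched set holds one 1-year cancer survivor and 1..matching_ratio
    cancer-free controls of the same sex within 3 years of age.  The
    returned frame carries ``config.ground_truth()`` in ``attrs`` for
    recovery testing.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n_sets = config.n_matched_sets
    lo, hi = config.age_range

    surv_sex = np.where(rng.random(n_sets) < config.female_fraction, "female", "male")
    surv_age = np.clip(rng.normal(62.7, 12.5, n_sets), lo, hi)
    surv_site = _draw_sites(rng, surv_sex, config)

    if config.matching_ratio == 1:
        n_controls = np.ones(n_sets, dtype=int)
    else:
        fallback = rng.integers(1, config.matching_ratio, n_sets)
        n_controls = np.where(
            rng.random(n_sets) < 0.75, config.matching_ratio, fallback
        )

    set_ids = np.concatenate(
        [np.arange(1, n_sets + 1), np.repeat(np.arange(1, n_sets + 1), n_controls)]
    )
    is_survivor = np.concatenate(
        [np.ones(n_sets, bool), np.zeros(int(n_controls.sum()), bool)]
    )
    sex = np.concatenate([surv_sex, np.repeat(surv_sex, n_controls)])
    ctrl_age = np.clip(
        np.repeat(surv_age, n_controls)
        + rng.uniform(-3.0, 3.0, int(n_controls.sum())),
        lo,
        hi,
    )
    age = np.concatenate([surv_age, ctrl_age])
    site = np.concatenate(
        [surv_site, np.full(int(n_controls.sum()), "none", dtype=object)]
    )
    n = len(age)

    preds = _draw_predictors(rng, n)
    df = pd.DataFrame(
        {
            "participant_id": np.arange(1, n + 1),
            "matched_set_id": set_ids,
            "group": np.where(is_survivor, "survivor", "cancer_free"),
            "cancer_site": site,
            "cancer_type": [
                "none"
                if s == "none"
                else ("haematological" if s in HAEMATOLOGICAL_SITES else "solid")
                for s in site
            ],
            "sex": sex,
            "age_at_index": age,
            **preds,
        }
    )

    # eligibility fields (exclusions applied downstream, not here)
    df["prior_cvd"] = (rng.random(n) < 0.08).astype(int)
    df["statin_scripts_prior_year"] = rng.choice(
        [0, 1, 2, 4], size=n, p=[0.88, 0.04, 0.05, 0.03]
    )
    df["pre_index_followup"] = rng.lognormal(math.log(5.0), 0.6, n)

    # event-time generation: exponential baseline x exp(linear predictor)
    lp = np.zeros(n)
    h0 = np.zeros(n)
    for s, model in config.true_model.items():
        mask = (df["sex"] == s).to_numpy()
        if mask.any():
            lp[mask] = model.linear_predictor(df.loc[mask]).to_numpy()
            h0[mask] = -math.log(model.baseline_survival_10y) / 10.0
    cancer_inc = np.array(
        [config.cancer_effects.get(s, 0.0) if s != "none" else 0.0 for s in site]
    )
    hazard = h0 * np.exp(lp + cancer_inc)

    t_cvd = rng.exponential(1.0 / hazard)
    death_rate = np.where(
        is_survivor,
        config.competing_death_rate * config.survivor_death_multiplier,
        config.competing_death_rate,
    )
    e_death = rng.exponential(1.0, n)
    t_death = np.where(death_rate > 0, e_death / np.maximum(death_rate, 1e-300), np.inf)
    t_cens = (
        rng.exponential(1.0, n) / config.censoring_rate
        if config.censoring_rate > 0
        else np.full(n, np.inf)
    )
    followup = np.minimum.reduce([t_cvd, t_death, t_cens, np.full(n, config.admin_horizon)])
    df["followup_time"] = followup
    df["event_cvd"] = (t_cvd == followup).astype(int)
    df["event_death"] = ((t_death == followup) & (df["event_cvd"] == 0)).astype(int)
    df["true_linear_predictor"] = lp + cancer_inc

    df = df[COHORT_COLUMNS + ["true_linear_predictor"]]
    df.attrs["ground_truth"] = config.ground_truth()
    return df


def apply_exclusions(records: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionReport]:
    """Apply the study eligibility filters.

    Removes: age outside 25..84 (inclusive), prior cardiovascular disease,
    two or more statin prescriptions in the year before index, and (for
    cancer-free controls only) less than 2 years of pre-index registration.
    Individuals failing several criteria are counted under each.
    """
    age_bad = (records["age_at_index"] < 25) | (records["age_at_index"] > 84)
    cvd_bad = records["prior_cvd"].astype(int) == 1
    statin_bad = records["statin_scripts_prior_year"].astype(int) >= 2
    preindex_bad = (records["group"] == "cancer_free") & (
        records["pre_index_followup"] < 2.0
    )
    excluded = age_bad | cvd_bad | statin_bad | preindex_bad
    kept = records.loc[~excluded].copy()
    if kept.empty:
        warnings.warn("all records excluded", stacklevel=2)
    report = ExclusionReport(
        n_input=len(records),
        removed_age=int(age_bad.sum()),
        removed_prior_cvd=int(cvd_bad.sum()),
        removed_statin=int(statin_bad.sum()),
        removed_short_preindex=int(preindex_bad.sum()),
        n_removed=int(excluded.sum()),
        retained_survivor=int((kept["group"] == "survivor").sum()),
        retained_cancer_free=int((kept["group"] == "cancer_free").sum()),
    )
    return kept, report


def inject_missingness(
    records: pd.DataFrame, rates: dict[str, float], seed: int | None = None
) -> pd.DataFrame:
    """Set each substitutable predictor missing independently at its rate (MCAR)."""
    unknown = set(rates) - set(SUBSTITUTABLE_PREDICTORS)
    if unknown:
        raise CohortError(
            f"missingness rates allowed only for {SUBSTITUTABLE_PREDICTORS}; "
            f"got {sorted(unknown)}"
        )
    for k, r in rates.items():
        if not 0.0 <= r <= 1.0:
            raise CohortError(f"rate for {k!r} outside [0, 1]: {r}")
    rng = np.random.default_rng(seed)
    out = records.copy()
    for k, r in rates.items():
        if r == 0:
            continue
        mask = rng.random(len(out)) < r
        col = out[k]
        if col.dtype.kind in "if":
            out.loc[mask, k] = np.nan
        else:
            out[k] = col.astype(object)
            out.loc[mask, k] = np.nan
    return out


def inject_missingness_mar(
    records: pd.DataFrame,
    rates: dict[str, float],
    seed: int | None = None,
    driver: str = "age_at_index",
) -> pd.DataFrame:
    """Covariate-dependent missingness (probability increasing in ``driver``).

    The per-predictor rate is preserved on average but tilted along the
    driver's quartiles, for imputation stress-testing.
    """
    unknown = set(rates) - set(SUBSTITUTABLE_PREDICTORS)
    if unknown:
        raise CohortError(f"unknown predictors {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    out = records.copy()
    q = pd.qcut(out[driver], 4, labels=False, duplicates="drop").to_numpy()
    tilt = np.array([0.4, 0.8, 1.2, 1.6])[q]
    for k, r in rates.items():
        p = np.clip(r * tilt, 0.0, 1.0)
        mask = rng.random(len(out)) < p
        if out[k].dtype.kind not in "if":
            out[k] = out[k].astype(object)
        out.loc[mask, k] = np.nan
    return out


def write_ground_truth(config: SimulationConfig, path) -> None:
    """Write the generating parameters and seed as a YAML sidecar."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.ground_truth(), fh, sort_keys=False)
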