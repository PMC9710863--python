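"""Coefficient-set-driven 10-year cardiovascular risk scoring.

The scoring model follows the QRISK family convention: a sex-specific Cox
model summarised by a linear predictor over fractional-polynomial (FP)
transformed, mean-centred predictors plus age-interaction products, and a
10-year baseline survival ``S0``.  The 10-year risk of a participant with
linear predictor ``lp`` is ``1 - S0 ** exp(lp)``.

Coefficient values are never hard-coded: a :class:`CoefficientSet` is read
from (and written to) a YAML config, so any published or refitted model can
be supplied.  Missing values among the six substitutable predictors
(smoking, body-mass index, ethnicity, systolic blood pressure, its
standard deviation, and the total:HDL cholesterol ratio) are filled from
the set's configured substitution values before scoring, mirroring the
score's single-value substitution approach.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SUBSTITUTABLE_PREDICTORS",
    "FPTransformSpec",
    "Term",
    "CoefficientSet",
    "fp_transform",
    "substitute_missing",
    "linear_predictor",
    "predicted_risk",
    "score_cohort",
    "load_coefficient_set",
    "save_coefficient_set",
]

#: Predictors whose missing values may be filled by substitution (and the
#: only ones the synthetic cohort makes missing).
SUBSTITUTABLE_PREDICTORS = (
    "smoking",
    "bmi",
    "ethnicity",
    "sbp",
    "sbp_sd",
    "chol_hdl_ratio",
)

#: Model term name -> cohort-table column, where they differ.
PREDICTOR_ALIASES = {"age": "age_at_index"}


class ScoringError(ValueError):
    """Raised for invalid scoring inputs (missing predictors, bad transforms)."""


@dataclass(frozen=True)
class FPTransformSpec:
    """Fractional-polynomial transform: powers applied to u=(x+shift)/scale.

    Royston–Altman conventions: power p != 0 gives u**p, p == 0 gives ln(u);
    a repeated power (p, p) gives (u**p, u**p * ln u), so (0, 0) gives
    (ln u, (ln u)**2).
    """

    powers: tuple[float, ...] = (1.0,)
    pre_scale: float = 1.0
    pre_shift: float = 0.0

    def __post_init__(self) -> None:
        if not 1 <= len(self.powers) <= 2:
            raise ScoringError("FP transform takes one or two powers")
        if self.pre_scale == 0:
            raise ScoringError("pre_scale must be nonzero")


def _single_power(u: np.ndarray, p: float) -> np.ndarray:
    return np.log(u) if p == 0 else u**p


def fp_transform(x, spec: FPTransformSpec) -> tuple[np.ndarray, ...]:
    """Apply a fractional-polynomial transform, returning one term per power."""
    u = (np.asarray(x, dtype=float) + spec.pre_shift) / spec.pre_scale
    if np.any(u <= 0):
        raise ScoringError(
            f"FP transform requires positive argument; got min u = {np.min(u)}"
        )
    t1 = _single_power(u, spec.powers[0])
    if len(spec.powers) == 1:
        return (t1,)
    p1, p2 = spec.powers
    t2 = t1 * np.log(u) if p2 == p1 else _single_power(u, p2)
    return (t1, t2)


@dataclass
class Term:
    """One model term: a continuous FP-transformed predictor or a categorical.

    For continuous terms ``coefficients`` aligns with the FP powers (one or
    two components).  For categorical terms the first level is the reference
    and ``coefficients`` aligns with the remaining levels.
    ``age_interaction`` (optional, same length) holds coefficients for the
    product of the centred component with the centred first age component.
    """

    name: str
    coefficients: list[float]
    transform: FPTransformSpec | None = None
    levels: list[str] | None = None
    age_interaction: list[float] | None = None

    def __post_init__(self) -> None:
        if (self.transform is None) == (self.levels is None):
            raise ScoringError(
                f"term {self.name!r}: exactly one of transform/levels required"
            )
        n = len(self.columns())
        if len(self.coefficients) != n:
            raise ScoringError(f"term {self.name!r}: expected {n} coefficients")
        if self.age_interaction is not None and len(self.age_interaction) != n:
            raise ScoringError(
                f"term {self.name!r}: age_interaction length must match components"
            )

    @property
    def is_categorical(self) -> bool:
        return self.levels is not None

    def columns(self) -> list[str]:
        if self.is_categorical:
            return [f"{self.name}_{lvl}" for lvl in self.levels[1:]]
        if len(self.transform.powers) == 1:
            return [self.name]
        return [f"{self.name}_1", f"{self.name}_2"]

    def expand(self, df: pd.DataFrame) -> dict[str, np.ndarray]:
        """Raw (uncentred) component columns for this term."""
        col = self.name if self.name in df.columns else PREDICTOR_ALIASES.get(self.name)
        if col is None or col not in df.columns:
            raise ScoringError(f"predictor {self.name!r} absent from records")
        x = df[col]
        if x.isna().any():
            raise ScoringError(f"predictor {self.name!r} contains missing values")
        if self.is_categorical:
            sx = x.astype(str)
            unknown = set(sx.unique()) - set(map(str, self.levels))
            if unknown:
                raise ScoringError(
                    f"term {self.name!r}: unknown categories {sorted(unknown)}"
                )
            return {
                f"{self.name}_{lvl}": (sx == str(lvl)).to_numpy(float)
                for lvl in self.levels[1:]
            }
        comps = fp_transform(x.to_numpy(float), self.transform)
        return dict(zip(self.columns(), comps))


@dataclass
class CoefficientSet:
    """A sex-specific scoring model (terms, centring means, baseline survival)."""

    sex: str
    baseline_survival_10y: float
    terms: list[Term]
    centering_means: dict[str, float]
    substitution_values: dict[str, object] = field(default_factory=dict)
    age_term: str = "age"

    def __post_init__(self) -> None:
        if not 0 < self.baseline_survival_10y < 1:
            raise ScoringError("baseline_survival_10y must be in (0, 1)")
        names = [t.name for t in self.terms]
        if len(set(names)) != len(names):
            raise ScoringError("duplicate term names")
        if any(t.age_interaction is not None for t in self.terms):
            if self.age_term not in names:
                raise ScoringError(
                    f"age interactions reference absent term {self.age_term!r}"
                )
        missing = [
            c for t in self.terms for c in t.columns() if c not in self.centering_means
        ]
        if missing:
            raise ScoringError(f"centering means missing for columns {missing}")

    @property
    def age_column(self) -> str:
        """Expanded column used as 'the' age component in interactions."""
        for t in self.terms:
            if t.name == self.age_term:
                return t.columns()[0]
        raise ScoringError(f"no term named {self.age_term!r}")

    def expand(self, df: pd.DataFrame, center: bool = True) -> pd.DataFrame:
        """Expanded component columns (optionally centred), no products."""
        cols: dict[str, np.ndarray] = {}
        for t in self.terms:
            cols.update(t.expand(df))
        out = pd.DataFrame(cols, index=df.index)
        if center:
            out -= pd.Series(self.centering_means).reindex(out.columns)
        return out

    def linear_predictor(self, df: pd.DataFrame) -> pd.Series:
        xc = self.expand(df, center=True)
        lp = np.zeros(len(df))
        age_c = xc[self.age_column].to_numpy() if self._has_interactions() else None
        for t in self.terms:
            for col, beta, gamma in zip(
                t.columns(),
                t.coefficients,
                t.age_interaction or [None] * len(t.columns()),
            ):
                v = xc[col].to_numpy()
                lp += beta * v
                if gamma is not None:
                    lp += gamma * v * age_c
        return pd.Series(lp, index=df.index, name="linear_predictor")

    def _has_interactions(self) -> bool:
        return any(t.age_interaction is not None for t in self.terms)

    # -- serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        terms = []
        for t in self.terms:
            d: dict = {"name": t.name, "coefficient": list(map(float, t.coefficients))}
            if t.is_categorical:
                d["levels"] = list(t.levels)
            else:
                d["transform"] = {
                    "powers": list(map(float, t.transform.powers)),
                    "scale": float(t.transform.pre_scale),
                    "shift": float(t.transform.pre_shift),
                }
            if t.age_interaction is not None:
                d["age_interaction"] = list(map(float, t.age_interaction))
            terms.append(d)
        return {
            "sex": self.sex,
            "baseline_survival_10y": float(self.baseline_survival_10y),
            "age_term": self.age_term,
            "terms": terms,
            "centering_means": {k: float(v) for k, v in self.centering_means.items()},
            "substitution_values": dict(self.substitution_values),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CoefficientSet":
        terms = []
        for td in d["terms"]:
            tr = td.get("transform")
            terms.append(
                Term(
                    name=td["name"],
                    coefficients=list(td["coefficient"]),
                    transform=None
                    if tr is None
                    else FPTransformSpec(
                        powers=tuple(tr["powers"]),
                        pre_scale=tr.get("scale", 1.0),
                        pre_shift=tr.get("shift", 0.0),
                    ),
                    levels=td.get("levels"),
                    age_interaction=td.get("age_interaction"),
                )
            )
        return cls(
            sex=d["sex"],
            baseline_survival_10y=d["baseline_survival_10y"],
            terms=terms,
            centering_means=dict(d["centering_means"]),
            substitution_values=dict(d.get("substitution_values", {})),
            age_term=d.get("age_term", "age"),
        )


def load_coefficient_set(path) -> CoefficientSet:
    with open(path) as fh:
        return CoefficientSet.from_dict(yaml.safe_load(fh))


def save_coefficient_set(coeffs: CoefficientSet, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(coeffs.to_dict(), fh, sort_keys=False)


def substitute_missing(
    records: pd.DataFrame, coeffs: CoefficientSet
) -> tuple[pd.DataFrame, pd.Series]:
    """Fill missing substitutable predictors from the coefficient set.

    Returns the completed copy and, per record, the list of substituted
    field names.  A missing value in any non-substitutable predictor used
    by the model is a hard error.
    """
    out = records.copy()
    subbed = [[] for _ in range(len(out))]
    model_predictors = {t.name for t in coeffs.terms}
    for name in model_predictors:
        col = name if name in out.columns else PREDICTOR_ALIASES.get(name)
        if col is None or col not in out.columns:
            raise ScoringError(f"predictor {name!r} absent from records")
        mask = out[col].isna()
        if not mask.any():
            continue
        if name not in SUBSTITUTABLE_PREDICTORS:
            raise ScoringError(f"predictor {name!r} is missing and not substitutable")
        if name not in coeffs.substitution_values:
            raise ScoringError(f"no substitution value configured for {name!r}")
        out.loc[mask, col] = coeffs.substitution_values[name]
        for i in np.flatnonzero(mask.to_numpy()):
            subbed[i].append(name)
    return out, pd.Series(subbed, index=out.index, name="substituted_fields")


def linear_predictor(records: pd.DataFrame, coeffs: CoefficientSet) -> pd.Series:
    """Centred linear predictor; records must be complete for model terms."""
    return coeffs.linear_predictor(records)


def predicted_risk(lp, baseline_survival_10y: float):
    """10-year event risk 1 - S0 ** exp(lp); fraction in (0, 1)."""
    if not 0 < baseline_survival_10y < 1:
        raise ScoringError("baseline survival must be in (0, 1)")
    lp = np.asarray(lp, dtype=float)
    # exp on the log scale avoids overflow for extreme linear predictors
    risk = -np.expm1(np.exp(lp) * math.log(baseline_survival_10y))
    return risk if risk.ndim else float(risk)


def score_cohort(
    records: pd.DataFrame,
    coeffs_male: CoefficientSet,
    coeffs_female: CoefficientSet,
) -> pd.DataFrame:
    """Score a mixed-sex cohort with the matching sex-specific model.

    Returns one row per record: participant_id, sex, linear_predictor,
    risk_10y and the substituted field list.
    """
    by_sex = {"male": coeffs_male, "female": coeffs_female}
    unknown = set(records["sex"].unique()) - set(by_sex)
    if unknown:
        raise ScoringError(f"unknown sex categories {sorted(unknown)}")
    parts = []
    for sex, coeffs in by_sex.items():
        sub = records[records["sex"] == sex]
        if sub.empty:
            continue
        completed, subbed = substitute_missing(sub, coeffs)
        lp = coeffs.linear_predictor(completed)
        parts.append(
            pd.DataFrame(
                {
                    "participant_id": sub["participant_id"].to_numpy()
                    if "participant_id" in sub.columns
                    else sub.index,
                    "sex": sex,
                    "linear_predictor": lp.to_numpy(),
                    "risk_10y": predicted_risk(
                        lp.to_numpy(), coeffs.baseline_survival_10y
                    ),
                    "substituted_fields": subbed.to_numpy(dtype=object),
                },
                index=sub.index,
            )
        )
    if not parts:
        return pd.DataFrame(
            columns=[
                "participant_id",
                "sex",
                "linear_predictor",
                "risk_10y",
                "substituted_fields",
            ]
        )
    return pd.concat(parts).loc[records.index]
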