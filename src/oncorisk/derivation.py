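"""Replicated score derivation: multiple imputation, sex-specific Cox
models with age interactions, Rubin pooling, and the formal inclusion rule
for candidate cancer-survivorship variables.

Workflow per sex stratum:

1. build the analysis design matrix (fractional-polynomial components,
   centred at the stratum's observed means, with age-interaction product
   columns) plus candidate cancer-survivorship columns;
2. impute the incomplete predictors *m* times by chained equations whose
   models contain every analysis predictor, explicitly constructed
   age-interaction product columns, the Nelson–Aalen cumulative-hazard
   estimate at each subject's exit time, and the event indicator;
   continuous draws are Bayesian linear-regression draws (posterior draw
   of the coefficients before the residual draw, so between-imputation
   variance is non-degenerate), with skewed variables handled on the log
   scale; categorical draws come from a multinomial logistic model fitted
   on a bootstrap resample;
3. fit the Cox partial likelihood per completed dataset;
4. pool by Rubin's rules: T = W + (1 + 1/m) B, with Barnard–Rubin degrees
   of freedom for the Wald test;
5. because all columns are centred, the pooled main coefficient of a
   candidate variable is its log hazard ratio *at the mean age*; the
   inclusion rule asks for HR < 0.90 or > 1.10 with two-sided P < 0.01.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, NelsonAalenFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .defaults import CANCER_SITES, HAEMATOLOGICAL_SITES
from .scoring import SUBSTITUTABLE_PREDICTORS, CoefficientSet

__all__ = [
    "ImputationConfig",
    "ModelSpec",
    "PooledCoxResult",
    "InclusionDecision",
    "CoxFit",
    "nelson_aalen",
    "impute",
    "fit_cox",
    "pool_rubin",
    "hr_at_mean_age",
    "evaluate_inclusion",
    "run_extension_analysis",
    "build_design",
]

CATEGORICAL_PREDICTORS = ("smoking", "ethnicity")

#: Minimum support for a cancer level to be estimated in a sex stratum.
MIN_CARRIERS_PER_LEVEL = 10
MIN_EVENTS_PER_LEVEL = 5


class DerivationError(RuntimeError):
    """Imputation or model-fitting failure."""


@dataclass
class ImputationConfig:
    m: int = 5
    variables_to_impute: tuple[str, ...] = SUBSTITUTABLE_PREDICTORS
    log_transform: frozenset[str] = frozenset({"bmi", "chol_hdl_ratio", "sbp_sd"})
    n_cycles: int = 5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("at least two imputations are required")
        unknown = set(self.variables_to_impute) - set(SUBSTITUTABLE_PREDICTORS)
        if unknown:
            raise ValueError(f"cannot impute {sorted(unknown)}")


@dataclass
class ModelSpec:
    """Analysis model: base scoring-model structure plus a cancer encoding."""

    base: CoefficientSet  # structure source; its coefficient values are ignored
    cancer_encoding: str = "none"  # none | binary | three_level | site_specific
    cancer_age_interaction: bool = True

    def __post_init__(self) -> None:
        if self.cancer_encoding not in ("none", "binary", "three_level", "site_specific"):
            raise ValueError(f"unknown cancer encoding {self.cancer_encoding!r}")


@dataclass
class CoxFit:
    params: pd.Series
    cov: pd.DataFrame
    n: int
    n_events: int


@dataclass
class PooledCoxResult:
    """Rubin-pooled coefficients over m imputations."""

    terms: list[str]
    beta: pd.Series  # pooled point estimates
    W: pd.Series  # within-imputation variance
    B: pd.Series  # between-imputation variance
    T: pd.Series  # total variance W + (1 + 1/m) B
    df: pd.Series  # Barnard-Rubin degrees of freedom
    p: pd.Series  # two-sided Wald P
    m: int
    n_complete_df: float

    def summary(self) -> pd.DataFrame:
        se = np.sqrt(self.T)
        return pd.DataFrame(
            {
                "beta": self.beta,
                "se": se,
                "W": self.W,
                "B": self.B,
                "T": self.T,
                "df": self.df,
                "hr": np.exp(self.beta),
                "ci_low": np.exp(self.beta - 1.96 * se),
                "ci_high": np.exp(self.beta + 1.96 * se),
                "p": self.p,
            }
        )


@dataclass
class InclusionDecision:
    variable: str
    ihr: float
    p: float
    lower_threshold: float = 0.90
    upper_threshold: float = 1.10
    alpha: float = 0.01
    meets: bool = field(init=False)

    def __post_init__(self) -> None:
        self.meets = bool(
            (self.ihr < self.lower_threshold or self.ihr > self.upper_threshold)
            and self.p < self.alpha
        )


def nelson_aalen(times, events) -> np.ndarray:
    """Nelson–Aalen cumulative hazard evaluated at each subject's exit time."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if np.any(times <= 0):
        raise ValueError("times must be positive")
    naf = NelsonAalenFitter(nelson_aalen_smoothing=False)
    naf.fit(times, events)
    ch = naf.cumulative_hazard_.iloc[:, 0]
    grid = ch.index.to_numpy(dtype=float)
    vals = ch.to_numpy(dtype=float)
    idx = np.searchsorted(grid, times, side="right") - 1
    return np.where(idx >= 0, vals[np.maximum(idx, 0)], 0.0)


# ---------------------------------------------------------------------------
# design-matrix construction


def _cancer_columns(df: pd.DataFrame, encoding: str) -> dict[str, np.ndarray]:
    surv = (df["group"] == "survivor").to_numpy()
    if encoding == "none":
        return {}
    if encoding == "binary":
        return {"cancer": surv.astype(float)}
    if encoding == "three_level":
        ctype = df["cancer_type"].astype(str).to_numpy()
        return {
            "cancer_solid": (ctype == "solid").astype(float),
            "cancer_haematological": (ctype == "haematological").astype(float),
        }
    cols = {}
    site = df["cancer_site"].astype(str).to_numpy()
    for s in CANCER_SITES:
        ind = (site == s).astype(float)
        if ind.any():
            cols[f"cancer_{s}"] = ind
    return cols


def build_design(
    df: pd.DataFrame,
    spec: ModelSpec,
    means: dict[str, float] | None = None,
    center: bool = True,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Centred analysis design matrix with age-interaction products.

    Columns: every expanded base-model component, candidate cancer columns,
    and ``<col>:age`` products for components with an age interaction.
    ``means`` (column -> centring mean) defaults to the means of ``df``;
    passing the same mapping across imputed datasets keeps the pooled
    coefficients on a common centring.
    """
    raw: dict[str, np.ndarray] = {}
    interacts: list[str] = []
    for t in spec.base.terms:
        cols = t.expand(df)
        raw.update(cols)
        if t.age_interaction is not None:
            interacts += list(cols.keys())
    cancer = _cancer_columns(df, spec.cancer_encoding)
    raw.update(cancer)
    if spec.cancer_age_interaction:
        interacts += list(cancer.keys())

    X = pd.DataFrame(raw, index=df.index)
    if means is None:
        means = X.mean().to_dict()
    if center:
        X = X - pd.Series(means).reindex(X.columns)
    age_col = spec.base.age_column
    age_c = X[age_col].to_numpy()
    for c in interacts:
        if c == age_col:
            continue
        X[f"{c}:age"] = X[c].to_numpy() * age_c
    return X, means


# ---------------------------------------------------------------------------
# multiple imputation


def _bayesian_linear_draw(
    Xo: np.ndarray, yo: np.ndarray, Xm: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Posterior-predictive draw from a normal linear model (ridge-stabilised)."""
    n, p = Xo.shape
    ridge = 1e-8 * np.eye(p)
    xtx = Xo.T @ Xo + ridge
    beta_hat = np.linalg.solve(xtx, Xo.T @ yo)
    resid = yo - Xo @ beta_hat
    dof = max(n - p, 2)
    sigma2 = (resid @ resid) / rng.chisquare(dof)
    cov = sigma2 * np.linalg.inv(xtx)
    beta = rng.multivariate_normal(beta_hat, cov, method="cholesky")
    return Xm @ beta + rng.normal(0.0, np.sqrt(sigma2), len(Xm))


def _categorical_draw(
    Xo: np.ndarray, yo: np.ndarray, Xm: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Multinomial-logistic draw; bootstrap refit carries parameter uncertainty."""
    classes = np.unique(yo)
    if len(classes) == 1:
        return np.full(len(Xm), classes[0])
    boot = rng.integers(0, len(yo), len(yo))
    Xb, yb = Xo[boot], yo[boot]
    if len(np.unique(yb)) < 2:  # degenerate resample: fall back to original rows
        Xb, yb = Xo, yo
    model = LogisticRegression(max_iter=500, C=1e4)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(Xb, yb)
    prob = model.predict_proba(Xm)
    cum = prob.cumsum(axis=1)
    u = rng.random(len(Xm))[:, None]
    pick = (u > cum).sum(axis=1)
    return model.classes_[np.minimum(pick, len(model.classes_) - 1)]


def _imputation_predictors(
    df: pd.DataFrame,
    spec: ModelSpec,
    target: str,
    na_hazard: np.ndarray,
) -> np.ndarray:
    """Imputation-model design for one target variable.

    All analysis components and age products of the *other* predictors,
    the Nelson–Aalen cumulative hazard, and the event indicator.
    """
    X, _ = build_design(df, spec, center=True)
    target_cols: set[str] = set()
    for t in spec.base.terms:
        if t.name == target:
            target_cols = set(t.columns())
    drop = [
        c
        for c in X.columns
        if c in target_cols or (":" in c and c.split(":")[0] in target_cols)
    ]
    X = X.drop(columns=drop)
    mat = np.column_stack(
        [np.ones(len(df)), X.to_numpy(float), na_hazard, df["event_cvd"].to_numpy(float)]
    )
    return mat


def impute(
    records: pd.DataFrame,
    config: ImputationConfig,
    spec: ModelSpec,
    rng: np.random.Generator | None = None,
) -> list[pd.DataFrame]:
    """Draw m completed datasets by chained equations (see module docstring).

    With no missing data the result is m identical copies of the input.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    targets = [
        v
        for v in config.variables_to_impute
        if v in records.columns and records[v].isna().any()
    ]
    if not targets:
        return [records.copy() for _ in range(config.m)]

    na_hazard = nelson_aalen(
        records["followup_time"].to_numpy(), records["event_cvd"].to_numpy()
    )
    masks = {v: records[v].isna().to_numpy() for v in targets}
    observed_rows = {v: ~masks[v] for v in targets}

    datasets = []
    for sub_rng in rng.spawn(config.m):
        df = records.copy()
        # initial fill: random draws from the observed marginal
        for v in targets:
            obs = df.loc[observed_rows[v], v].to_numpy()
            if len(obs) == 0:
                raise DerivationError(f"variable {v!r} has no observed values")
            df.loc[masks[v], v] = sub_rng.choice(obs, masks[v].sum())
        for _ in range(config.n_cycles):
            for v in targets:
                try:
                    M = _imputation_predictors(df, spec, v, na_hazard)
                except Exception as err:  # pragma: no cover - defensive
                    raise DerivationError(f"imputation design failed for {v!r}: {err}")
                obs, mis = observed_rows[v], masks[v]
                if v in CATEGORICAL_PREDICTORS:
                    yo = df.loc[obs, v].astype(str).to_numpy()
                    df.loc[mis, v] = _categorical_draw(M[obs], yo, M[mis], sub_rng)
                else:
                    x = df.loc[obs, v].to_numpy(float)
                    logged = v in config.log_transform
                    yo = np.log(x) if logged else x
                    try:
                        draw = _bayesian_linear_draw(M[obs], yo, M[mis], sub_rng)
                    except np.linalg.LinAlgError as err:
                        raise DerivationError(
                            f"imputation model for {v!r} failed: {err}"
                        )
                    if logged:  # clip on the log scale to avoid overflow
                        draw = np.clip(draw, np.log(x.min()), np.log(x.max()))
                        vals = np.exp(draw)
                    else:
                        vals = draw
                    # clip to the observed support so downstream FP
                    # transforms stay defined
                    vals = np.clip(vals, x.min(), x.max())
                    df.loc[mis, v] = vals
        datasets.append(df)
    return datasets


# ---------------------------------------------------------------------------
# Cox fitting and pooling


def fit_cox(
    dataset: pd.DataFrame,
    spec: ModelSpec | None = None,
    design: pd.DataFrame | None = None,
    duration_col: str = "followup_time",
    event_col: str = "event_cvd",
    means: dict[str, float] | None = None,
    admin_horizon: float = 10.0,
) -> CoxFit:
    """Cox partial-likelihood fit on one completed dataset.

    Either a ``ModelSpec`` (design built from the records) or a prebuilt
    ``design`` matrix may be supplied.  Administrative censoring at the
    horizon is applied before fitting.  Efron's tie correction is used;
    simulated event times are continuous so ties are incidental.
    """
    if design is None:
        if spec is None:
            raise ValueError("either spec or design is required")
        design, _ = build_design(dataset, spec, means=means)
    t = dataset[duration_col].to_numpy(float)
    e = dataset[event_col].to_numpy(int)
    over = t > admin_horizon
    t = np.minimum(t, admin_horizon)
    e = np.where(over, 0, e)
    frame = design.copy()
    frame["__t"] = t
    frame["__e"] = e
    cph = CoxPHFitter(penalizer=0.0)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(frame, duration_col="__t", event_col="__e")
    except ConvergenceError as err:
        raise DerivationError(f"Cox model did not converge: {err}")
    return CoxFit(
        params=cph.params_.copy(),
        cov=cph.variance_matrix_.copy(),
        n=len(frame),
        n_events=int(e.sum()),
    )


def pool_rubin(fits: list[CoxFit]) -> PooledCoxResult:
    """Combine m Cox fits by Rubin's rules."""
    m = len(fits)
    if m < 2:
        raise ValueError("Rubin pooling requires at least two fits")
    terms = list(fits[0].params.index)
    for f in fits[1:]:
        if list(f.params.index) != terms:
            raise ValueError("mismatched term lists across imputations")
    est = np.vstack([f.params.to_numpy() for f in fits])
    var = np.vstack([np.diag(f.cov.to_numpy()) for f in fits])
    beta = est.mean(axis=0)
    W = var.mean(axis=0)
    B = est.var(axis=0, ddof=1)
    T = W + (1 + 1 / m) * B

    # Barnard-Rubin small-sample degrees of freedom
    n_com = fits[0].n - len(terms)
    with np.errstate(divide="ignore", invalid="ignore"):
        lam = np.where(T > 0, (1 + 1 / m) * B / T, 0.0)
        nu_old = np.where(lam > 0, (m - 1) / lam**2, np.inf)
        nu_obs = (n_com + 1) / (n_com + 3) * n_com * (1 - lam)
        df = np.where(
            np.isinf(nu_old), nu_obs, nu_old * nu_obs / (nu_old + nu_obs)
        )
        z = np.where(T > 0, np.abs(beta) / np.sqrt(T), np.inf)
    p = np.where(
        df > 1e7, 2 * stats.norm.sf(z), 2 * stats.t.sf(z, np.maximum(df, 1.0))
    )
    idx = pd.Index(terms)
    return PooledCoxResult(
        terms=terms,
        beta=pd.Series(beta, idx),
        W=pd.Series(W, idx),
        B=pd.Series(B, idx),
        T=pd.Series(T, idx),
        df=pd.Series(df, idx),
        p=pd.Series(p, idx),
        m=m,
        n_complete_df=float(n_com),
    )


def hr_at_mean_age(
    pooled: PooledCoxResult, term: str
) -> tuple[float, tuple[float, float], float]:
    """Hazard ratio for ``term`` at the cohort mean age.

    All design columns (including the age component feeding the
    interactions) are centred at cohort means, so interaction contributions
    vanish at the mean age and the main coefficient is directly the log HR
    there.
    """
    if term not in pooled.beta.index:
        raise KeyError(f"term {term!r} not in pooled result")
    b = float(pooled.beta[term])
    se = float(np.sqrt(pooled.T[term]))
    with np.errstate(over="ignore"):
        return (
            float(np.exp(b)),
            (float(np.exp(b - 1.96 * se)), float(np.exp(b + 1.96 * se))),
            float(pooled.p[term]),
        )


def evaluate_inclusion(
    variable: str,
    ihr: float,
    p: float,
    lower: float = 0.90,
    upper: float = 1.10,
    alpha: float = 0.01,
) -> InclusionDecision:
    """Apply the score's formal rule: HR < 0.90 or > 1.10 and P < 0.01 (strict)."""
    if ihr <= 0:
        raise ValueError("hazard ratio must be positive")
    if not 0 <= p <= 1:
        raise ValueError("P must be a probability")
    return InclusionDecision(
        variable=variable,
        ihr=ihr,
        p=p,
        lower_threshold=lower,
        upper_threshold=upper,
        alpha=alpha,
    )


def _encoding_levels(encoding: str) -> list[str] | None:
    if encoding == "binary":
        return ["cancer"]
    if encoding == "three_level":
        return ["cancer_solid", "cancer_haematological"]
    return None  # site-specific: depends on observed sites


def run_extension_analysis(
    records: pd.DataFrame,
    base_models: dict[str, CoefficientSet],
    encodings: tuple[str, ...] = ("binary", "three_level", "site_specific"),
    imputation: ImputationConfig | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Full derivation: impute -> fit per sex and encoding -> pool -> decide.

    Returns a tidy decision table with one row per sex x encoding x cancer
    level: iHR at the mean age, 95% CI, P, the inclusion flag, and an
    ``estimable`` flag (a level with no events among its carriers in a
    stratum is reported, not silently dropped).  Imputation is performed
    once per sex (with the binary survivorship indicator in the imputation
    model) and the completed datasets are reused across encodings.
    """
    imputation = imputation or ImputationConfig()
    rng = np.random.default_rng(
        seed if seed is not None else imputation.seed
    )
    if set(records["group"].unique()) != {"survivor", "cancer_free"}:
        raise ValueError("cohort must contain both survivors and cancer-free controls")
    rows = []
    for sex in ("male", "female"):
        sub = records[records["sex"] == sex].reset_index(drop=True)
        if sub.empty or sub["group"].nunique() < 2:
            continue
        base = base_models[sex]
        imp_spec = ModelSpec(base=base, cancer_encoding="binary")
        completed = impute(sub, imputation, imp_spec, rng=rng)
        # shared centring means from the first completed dataset
        _, means = build_design(completed[0], ModelSpec(base=base, cancer_encoding="none"))
        for encoding in encodings:
            spec = ModelSpec(base=base, cancer_encoding=encoding)
            cancer_cols = _cancer_columns(sub, encoding)
            estimable = {}
            for col, ind in cancer_cols.items():
                carriers = ind.astype(bool)
                # a level needs a handful of carriers and events to support
                # a coefficient plus its age interaction; sparser levels are
                # reported as inestimable rather than risking a degenerate
                # (monotone-likelihood) fit
                estimable[col] = bool(
                    carriers.sum() >= MIN_CARRIERS_PER_LEVEL
                    and sub.loc[carriers, "event_cvd"].sum() >= MIN_EVENTS_PER_LEVEL
                )
            drop_cols = [c for c, ok in estimable.items() if not ok]
            fits = []
            try:
                for ds in completed:
                    design_raw, _ = build_design(ds, spec, means=None, center=False)
                    design = _centred_with_products(ds, spec, design_raw, means)
                    if drop_cols:
                        drop = [c for c in design.columns
                                if c in drop_cols or c.split(":")[0] in drop_cols]
                        design = design.drop(columns=drop)
                    fits.append(
                        fit_cox(ds, design=design)
                    )
                pooled = pool_rubin(fits)
            except DerivationError as err:
                for col in cancer_cols:
                    rows.append(_decision_row(sex, encoding, col, err=str(err)))
                continue
            for col in cancer_cols:
                if not estimable[col]:
                    rows.append(
                        _decision_row(
                            sex, encoding, col,
                            err="insufficient carriers or events in level",
                        )
                    )
                    continue
                ihr, (lo, hi), p = hr_at_mean_age(pooled, col)
                dec = evaluate_inclusion(col, ihr, p)
                rows.append(
                    {
                        "sex": sex,
                        "encoding": encoding,
                        "level": col,
                        "ihr": ihr,
                        "ci_low": lo,
                        "ci_high": hi,
                        "p_value": p,
                        "meets": dec.meets,
                        "estimable": True,
                        "note": "",
                    }
                )
    return pd.DataFrame(rows)


def _centred_with_products(
    ds: pd.DataFrame, spec: ModelSpec, raw_design: pd.DataFrame, means: dict[str, float]
) -> pd.DataFrame:
    """Centre raw (uncentred, product-free) columns at shared means, rebuild products."""
    main_cols = [c for c in raw_design.columns if ":" not in c]
    X = raw_design[main_cols].copy()
    mean_ser = pd.Series(
        {c: means.get(c, float(X[c].mean())) for c in main_cols}
    )
    X = X - mean_ser
    age_col = spec.base.age_column
    age_c = X[age_col].to_numpy()
    interacts = []
    for t in spec.base.terms:
        if t.age_interaction is not None:
            interacts += t.columns()
    if spec.cancer_age_interaction:
        interacts += [c for c in main_cols if c.startswith("cancer")]
    for c in interacts:
        if c != age_col and c in X.columns:
            X[f"{c}:age"] = X[c].to_numpy() * age_c
    return X


def _decision_row(sex: str, encoding: str, level: str, err: str) -> dict:
    return {
        "sex": sex,
        "encoding": encoding,
        "level": level,
        "ihr": np.nan,
        "ci_low": np.nan,
        "ci_high": np.nan,
        "p_value": np.nan,
        "meets": False,
        "estimable": False,
        "note": err,
    }
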