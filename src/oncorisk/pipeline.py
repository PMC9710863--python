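"""End-to-end study pipeline: cohort -> exclusions -> scoring -> validation
-> derivation, with delimited-table artefacts and a JSON manifest.

Also owns cohort-table I/O: a comma-separated file with one header row and
empty fields for missing values (schema in :data:`oncorisk.cohort.COHORT_COLUMNS`).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, defaults
from .cohort import (
    COHORT_COLUMNS,
    ExclusionReport,
    SimulationConfig,
    apply_exclusions,
    generate_cohort,
    inject_missingness,
    write_ground_truth,
)
from .derivation import ImputationConfig, run_extension_analysis
from .scoring import CoefficientSet, load_coefficient_set, score_cohort
from .validation import (
    aalen_johansen_cif,
    calibration_by_decile,
    harrells_c,
    km_cumulative_incidence,
    split_risk_groups,
)

__all__ = [
    "RunConfig",
    "RunReport",
    "SchemaError",
    "DataError",
    "read_cohort",
    "write_cohort",
    "run_pipeline",
]

log = logging.getLogger("oncorisk")

_NUMERIC_COLS = {
    "participant_id": int,
    "matched_set_id": int,
    "age_at_index": float,
    "bmi": float,
    "sbp": float,
    "sbp_sd": float,
    "chol_hdl_ratio": float,
    "deprivation": float,
    "prior_cvd": int,
    "statin_scripts_prior_year": int,
    "pre_index_followup": float,
    "followup_time": float,
    "event_cvd": int,
    "event_death": int,
}
_NULLABLE_NUMERIC = {"bmi", "sbp", "sbp_sd", "chol_hdl_ratio"}


class SchemaError(ValueError):
    """Cohort file does not match the documented schema."""


class DataError(ValueError):
    """Cohort file matches the schema but holds unparseable values."""


def write_cohort(records: pd.DataFrame, path) -> None:
    """Write the cohort table (CSV, empty field = missing)."""
    cols = [c for c in COHORT_COLUMNS if c in records.columns]
    records[cols].to_csv(path, index=False, na_rep="")


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort table, reporting schema problems and bad rows by line."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort file missing required column(s): {missing}")
    for col, typ in _NUMERIC_COLS.items():
        raw = df[col]
        num = pd.to_numeric(raw, errors="coerce")
        bad = num.isna() & raw.notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header + 1-based
            raise DataError(
                f"unparseable value {raw[bad.idxmax()]!r} in column {col!r} "
                f"(line {line})"
            )
        if num.isna().any() and col not in _NULLABLE_NUMERIC:
            line = int(num.isna().idxmax()) + 2
            raise DataError(f"missing value in required column {col!r} (line {line})")
        df[col] = num if col in _NULLABLE_NUMERIC else num.astype(typ)
    return df[COHORT_COLUMNS]


@dataclass
class RunConfig:
    """One pipeline run: either simulate a cohort or read one from disk."""

    output_dir: str | Path
    simulation: SimulationConfig | None = None
    cohort_path: str | Path | None = None
    coefficients_male: CoefficientSet | str | None = None
    coefficients_female: CoefficientSet | str | None = None
    risk_threshold: float = 0.10
    horizon: float = 10.0
    c_sample_fraction: float = 0.1
    imputation: ImputationConfig = field(default_factory=ImputationConfig)
    encodings: tuple[str, ...] = ("binary", "three_level", "site_specific")
    run_derivation: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.cohort_path is None):
            raise ValueError("exactly one of simulation / cohort_path is required")

    def resolve_models(self) -> dict[str, CoefficientSet]:
        out = {}
        for sex, src in (
            ("male", self.coefficients_male),
            ("female", self.coefficients_female),
        ):
            if src is None:
                out[sex] = defaults.default_coefficient_set(sex)
            elif isinstance(src, CoefficientSet):
                out[sex] = src
            else:
                out[sex] = load_coefficient_set(src)
        return out


@dataclass
class RunReport:
    output_dir: Path
    exclusions: ExclusionReport
    group_sizes: dict[str, int]
    median_followup: dict[str, float]
    median_risk: dict[str, float]
    high_risk_fraction: dict[str, float]
    incidence: pd.DataFrame
    calibration: pd.DataFrame
    c_statistics: pd.DataFrame
    decisions: pd.DataFrame | None
    seed: int
    wall_clock_s: float
    files: dict[str, str] = field(default_factory=dict)


def _age_band(age: pd.Series) -> pd.Series:
    return pd.Series(
        np.where(age <= 59, "25-59", "60-84"), index=age.index, name="age_band"
    )


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute every enabled stage and persist its tables under output_dir."""
    t0 = time.time()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    sub_seeds = [int(s) for s in ss.generate_state(4)]
    sub_seeds = [s % (2**31) for s in sub_seeds]
    log.info("stage seeds: %s", sub_seeds)
    files: dict[str, str] = {}

    # --- cohort -----------------------------------------------------------
    if config.simulation is not None:
        cohort = generate_cohort(config.simulation)
        cohort = cohort.drop(columns=["true_linear_predictor"])
        write_ground_truth(config.simulation, out / "ground_truth.yaml")
        files["ground_truth"] = "ground_truth.yaml"
    else:
        cohort = read_cohort(config.cohort_path)

    kept, report = apply_exclusions(cohort)
    if config.simulation is not None:
        kept = inject_missingness(
            kept, config.simulation.missingness_rates, seed=sub_seeds[0]
        )
        write_cohort(kept, out / "cohort.csv")
        files["cohort"] = "cohort.csv"
    report.to_frame().to_csv(out / "exclusion_report.csv", index=False)
    files["exclusion_report"] = "exclusion_report.csv"
    kept = kept.reset_index(drop=True)

    # --- scoring ----------------------------------------------------------
    models = config.resolve_models()
    scores = score_cohort(kept, models["male"], models["female"])
    scored = kept.assign(
        risk_10y=scores["risk_10y"].to_numpy(),
        linear_predictor=scores["linear_predictor"].to_numpy(),
    )
    scores_out = scores.copy()
    scores_out["substituted_fields"] = scores_out["substituted_fields"].map(
        ";".join
    )
    scores_out.to_csv(out / "scores.csv", index=False)
    files["scores"] = "scores.csv"

    scored["risk_group"] = split_risk_groups(
        scored["risk_10y"], config.risk_threshold
    )
    group_sizes = scored["group"].value_counts().to_dict()
    median_followup = scored.groupby("group")["followup_time"].median().to_dict()
    median_risk = scored.groupby("group")["risk_10y"].median().to_dict()
    high_risk = (
        scored.assign(high=scored["risk_group"] == "high")
        .groupby("group")["high"]
        .mean()
        .to_dict()
    )

    # --- validation: cumulative incidence curves -------------------------
    curves = []
    for grp in ("survivor", "cancer_free"):
        for rg in ("low", "high"):
            m = (scored["group"] == grp) & (scored["risk_group"] == rg)
            if m.sum() < 2 or scored.loc[m, "event_cvd"].sum() == 0:
                continue
            label = f"{grp}/{rg}"
            t = scored.loc[m, "followup_time"]
            km = km_cumulative_incidence(t, scored.loc[m, "event_cvd"], group=label)
            codes = np.where(
                scored.loc[m, "event_cvd"] == 1,
                1,
                np.where(scored.loc[m, "event_death"] == 1, 2, 0),
            )
            aj = aalen_johansen_cif(t, codes, group=label, seed=sub_seeds[1])
            for curve in (km, aj):
                frame = curve.to_frame()
                frame["n_subjects"] = int(m.sum())
                curves.append(frame)
    incidence = pd.concat(curves, ignore_index=True)
    incidence.to_csv(out / "cumulative_incidence.csv", index=False)
    files["cumulative_incidence"] = "cumulative_incidence.csv"

    # --- validation: calibration and discrimination ----------------------
    cal_parts = []
    for (sex, grp), sub in scored.groupby(["sex", "group"]):
        cal = calibration_by_decile(
            sub["risk_10y"], sub["followup_time"], sub["event_cvd"], config.horizon
        )
        cal.insert(0, "group", grp)
        cal.insert(0, "sex", sex)
        cal_parts.append(cal)
    calibration = pd.concat(cal_parts, ignore_index=True)
    calibration.to_csv(out / "calibration.csv", index=False)
    files["calibration"] = "calibration.csv"

    c_rows = []
    bands = ("all", "25-59", "60-84")
    band = _age_band(scored["age_at_index"])
    for (sex, grp), sub in scored.groupby(["sex", "group"]):
        for b in bands:
            m = sub.index if b == "all" else sub.index[band[sub.index] == b]
            if len(m) < 20:
                continue
            try:
                res = harrells_c(
                    scored.loc[m, "risk_10y"],
                    scored.loc[m, "followup_time"],
                    scored.loc[m, "event_cvd"],
                    sample_fraction=config.c_sample_fraction,
                    seed=sub_seeds[2],
                )
            except ValueError:
                continue
            c_rows.append(
                {
                    "sex": sex,
                    "group": grp,
                    "age_band": b,
                    "c_statistic": res.c_statistic,
                    "comparable_pairs": res.comparable_pairs,
                    "n_used": res.n_used,
                }
            )
    c_statistics = pd.DataFrame(c_rows)
    c_statistics.to_csv(out / "c_statistics.csv", index=False)
    files["c_statistics"] = "c_statistics.csv"

    # --- derivation -------------------------------------------------------
    decisions = None
    if config.run_derivation:
        decisions = run_extension_analysis(
            kept,
            config.resolve_models(),
            encodings=config.encodings,
            imputation=config.imputation,
            seed=sub_seeds[3],
        )
        decisions.to_csv(out / "inclusion_decisions.csv", index=False)
        files["inclusion_decisions"] = "inclusion_decisions.csv"

    wall = time.time() - t0
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "stage_seeds": sub_seeds,
        "files": files,
        "software": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "wall_clock_s": round(wall, 3),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)

    return RunReport(
        output_dir=out,
        exclusions=report,
        group_sizes=group_sizes,
        median_followup=median_followup,
        median_risk=median_risk,
        high_risk_fraction=high_risk,
        incidence=incidence,
        calibration=calibration,
        c_statistics=c_statistics,
        decisions=decisions,
        seed=config.seed,
        wall_clock_s=wall,
        files=files,
    )
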