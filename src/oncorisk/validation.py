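"""Predictive-performance assessment for 10-year risk scores.

Cumulative incidence is reported two ways, matching how risk-score
validation is usually done and how it arguably should be done:

* ``km_cumulative_incidence`` — the complement of the Kaplan–Meier survival
  estimate, treating deaths as censorings ("naïve" incidence, the
  convention under which the score was derived);
* ``aalen_johansen_cif`` — the cause-specific cumulative incidence function
  with death as a competing risk, which is never above the Kaplan–Meier
  complement on the same data.

Calibration compares mean predicted 10-year risk with the naïve
Kaplan–Meier observed risk per decile of predicted risk; discrimination is
Harrell's C over comparable pairs, computed on a seeded random subsample
(the full pairwise computation is quadratic in cohort size).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import AalenJohansenFitter, KaplanMeierFitter

__all__ = [
    "CumulativeIncidenceCurve",
    "ConcordanceResult",
    "km_cumulative_incidence",
    "aalen_johansen_cif",
    "split_risk_groups",
    "calibration_by_decile",
    "harrells_c",
]

EVENT_CODES = {"censored": 0, "cvd": 1, "death": 2}


@dataclass
class CumulativeIncidenceCurve:
    method: str  # "km_complement" | "aalen_johansen"
    times: np.ndarray
    estimate: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    group: str = ""
    event_of_interest: str = "cvd"

    def at(self, t: float) -> float:
        """Step-function value at time t (0 before the first event time)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return float(self.estimate[idx]) if idx >= 0 else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "method": self.method,
                "group": self.group,
                "time": self.times,
                "estimate": self.estimate,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
            }
        )


@dataclass
class ConcordanceResult:
    c_statistic: float
    comparable_pairs: int
    concordant: int
    tied: int
    sample_fraction: float
    seed: int | None = None
    n_used: int = 0


def km_cumulative_incidence(
    times, event_flags, group: str = "", alpha: float = 0.05
) -> CumulativeIncidenceCurve:
    """1 - Kaplan-Meier survival, censoring at death (naïve incidence)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(event_flags, dtype=int)
    if np.any(times <= 0):
        raise ValueError("follow-up times must be positive")
    if events.sum() == 0:
        warnings.warn("no events; cumulative incidence is identically zero")
    kmf = KaplanMeierFitter(alpha=alpha)
    kmf.fit(times, events, label="s")
    surv = kmf.survival_function_["s"]
    ci = kmf.confidence_interval_survival_function_
    return CumulativeIncidenceCurve(
        method="km_complement",
        times=surv.index.to_numpy(dtype=float),
        estimate=1.0 - surv.to_numpy(),
        ci_lower=1.0 - ci.iloc[:, 1].to_numpy(),  # upper survival bound
        ci_upper=1.0 - ci.iloc[:, 0].to_numpy(),
        group=group,
    )


def aalen_johansen_cif(
    times, event_types, group: str = "", alpha: float = 0.05, seed: int = 0
) -> CumulativeIncidenceCurve:
    """Aalen–Johansen cumulative incidence of the CVD event, death competing.

    ``event_types`` holds 0/1/2 codes or the strings censored/cvd/death.
    """
    times = np.asarray(times, dtype=float)
    ev = np.asarray(event_types)
    if ev.dtype.kind in "UO":
        unknown = set(np.unique(ev)) - set(EVENT_CODES)
        if unknown:
            raise ValueError(f"unknown event types {sorted(unknown)}")
        ev = np.vectorize(EVENT_CODES.get)(ev)
    ev = ev.astype(int)
    if not np.isin(ev, [0, 1, 2]).all():
        raise ValueError("event codes must be 0 (censored), 1 (cvd) or 2 (death)")
    ajf = AalenJohansenFitter(calculate_variance=True, seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # tie-breaking jitter notice
        ajf.fit(times, ev, event_of_interest=1, alpha=alpha)
    est = ajf.cumulative_density_.iloc[:, 0]
    grid = est.index.to_numpy(dtype=float)
    var = (
        ajf.variance_.reindex(est.index).fillna(0.0).to_numpy(dtype=float)
        if hasattr(ajf, "variance_")
        else np.zeros_like(grid)
    )
    half = 1.959963984540054 * np.sqrt(np.maximum(var, 0.0)).ravel()
    vals = est.to_numpy()
    return CumulativeIncidenceCurve(
        method="aalen_johansen",
        times=grid,
        estimate=vals,
        ci_lower=np.clip(vals - half, 0.0, 1.0),
        ci_upper=np.clip(vals + half, 0.0, 1.0),
        group=group,
    )


def split_risk_groups(risks, threshold: float = 0.10) -> np.ndarray:
    """Label risks below the statin-initiation threshold 'low', else 'high'."""
    risks = np.asarray(risks, dtype=float)
    if np.any((risks <= 0) | (risks >= 1)):
        raise ValueError("risks must be in (0, 1)")
    return np.where(risks < threshold, "low", "high")


def calibration_by_decile(
    predictions, times, events, horizon: float = 10.0, n_bins: int = 10
) -> pd.DataFrame:
    """Mean predicted vs naïve-KM observed risk per decile of predicted risk."""
    pred = np.asarray(predictions, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(pred) == 0:
        raise ValueError("empty input")
    if len(np.unique(pred)) < n_bins:
        warnings.warn("fewer distinct risks than bins; using fewer bins")
    bins = pd.qcut(pred, n_bins, labels=False, duplicates="drop")
    beyond = horizon > times.max()
    if beyond:
        warnings.warn(
            "horizon beyond last observed time; using estimate at last event time"
        )
    rows = []
    for b in np.unique(bins):
        m = bins == b
        kmf = KaplanMeierFitter().fit(times[m], events[m])
        observed = 1.0 - float(
            kmf.survival_function_.iloc[:, 0].iloc[-1]
            if beyond
            else kmf.predict(horizon)
        )
        rows.append(
            {
                "decile": int(b) + 1,
                "n": int(m.sum()),
                "events": int(events[m].sum()),
                "mean_predicted": float(pred[m].mean()),
                "observed": observed,
                "difference": float(pred[m].mean()) - observed,
                "truncated_at_last_time": bool(beyond),
            }
        )
    return pd.DataFrame(rows)


def harrells_c(
    scores,
    times,
    events,
    sample_fraction: float = 0.1,
    seed: int | None = None,
) -> ConcordanceResult:
    """Harrell's C over comparable pairs on a seeded random subsample.

    A pair is comparable when the member with the strictly smaller observed
    time had the event; it is concordant when that member also has the
    higher score, and score ties count one half.  Pairs tied on time are
    not comparable.
    """
    scores = np.asarray(scores, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if not 0 < sample_fraction <= 1:
        raise ValueError("sample_fraction must be in (0, 1]")
    n = len(scores)
    if sample_fraction < 1:
        rng = np.random.default_rng(seed)
        idx = rng.choice(n, size=max(2, int(round(n * sample_fraction))), replace=False)
        scores, times, events = scores[idx], times[idx], events[idx]
        n = len(idx)

    order = np.argsort(times, kind="mergesort")
    s, t, e = scores[order], times[order], events[order]
    comparable = concordant = tied = 0
    chunk = 512
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        block = slice(start, stop)
        # pairs (i in block with event) x (j with t_j > t_i)
        later = t[None, :] > t[block, None]  # strict: time ties not comparable
        usable = later & (e[block, None] == 1)
        comparable += int(usable.sum())
        diff = s[block, None] - s[None, :]
        concordant += int((usable & (diff > 0)).sum())
        tied += int((usable & (diff == 0)).sum())
    if comparable == 0:
        raise ValueError("no comparable pairs")
    return ConcordanceResult(
        c_statistic=(concordant + 0.5 * tied) / comparable,
        comparable_pairs=comparable,
        concordant=concordant,
        tied=tied,
        sample_fraction=sample_fraction,
        seed=seed,
        n_used=n,
    )
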