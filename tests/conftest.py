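import math

import numpy as np
import pandas as pd
import pytest

import oncorisk as ok
from oncorisk.scoring import CoefficientSet, FPTransformSpec, Term


@pytest.fixture(scope="session")
def default_models():
    return {s: ok.default_coefficient_set(s) for s in ("male", "female")}


@pytest.fixture(scope="session")
def small_cohort():
    """Study-condition cohort at small scale, exclusions applied."""
    cfg = ok.SimulationConfig(n_matched_sets=400, seed=7)
    kept, _ = ok.apply_exclusions(ok.generate_cohort(cfg))
    return kept.reset_index(drop=True)


@pytest.fixture
def toy_coefficients():
    """Three-term set with hand-checkable arithmetic (no interactions)."""
    terms = [
        Term(
            name="age",
            transform=FPTransformSpec(powers=(0.5, -1.0), pre_scale=10.0),
            coefficients=[0.4, -2.0],
        ),
        Term(name="sbp", transform=FPTransformSpec(powers=(1.0,)), coefficients=[0.01]),
        Term(
            name="smoking",
            levels=["non", "ex", "heavy"],
            coefficients=[0.2, 0.7],
        ),
    ]
    return CoefficientSet(
        sex="male",
        baseline_survival_10y=0.9,
        terms=terms,
        centering_means={
            "age_1": 2.5,
            "age_2": 0.16,
            "sbp": 130.0,
            "smoking_ex": 0.25,
            "smoking_heavy": 0.10,
        },
        substitution_values={"sbp": 130.0, "smoking": "non"},
    )


@pytest.fixture
def toy_record():
    return pd.DataFrame(
        {
            "age_at_index": [40.0],
            "sbp": [140.0],
            "smoking": ["heavy"],
        }
    )


def brute_force_c(scores, times, events):
    """Exhaustive pair enumeration of Harrell's C (independent oracle).

    Comparable: strictly smaller time is an event; concordant: that subject
    has the higher score; score ties count one half.
    """
    n = len(scores)
    comparable = concordant = tied = 0
    for i in range(n):
        for j in range(n):
            if i == j or times[i] >= times[j] or events[i] != 1:
                continue
            comparable += 1
            if scores[i] > scores[j]:
                concordant += 1
            elif scores[i] == scores[j]:
                tied += 1
    if comparable == 0:
        raise ValueError("no comparable pairs")
    return (concordant + 0.5 * tied) / comparable, comparable, concordant, tied


def breslow_partial_loglik(beta, x, times, events):
    """Explicit Cox partial log-likelihood (no ties in the fixtures used)."""
    beta = np.atleast_1d(beta)
    x = np.atleast_2d(x)
    lp = x @ beta
    ll = 0.0
    for i in np.flatnonzero(events):
        at_risk = times >= times[i]
        ll += lp[i] - math.log(np.exp(lp[at_risk]).sum())
    return ll
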