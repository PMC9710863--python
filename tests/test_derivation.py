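import math

import numpy as np
import pandas as pd
import pytest

import oncorisk as ok
from oncorisk.cohort import SimulationConfig
from oncorisk.derivation import (
    CoxFit,
    ImputationConfig,
    ModelSpec,
    build_design,
    evaluate_inclusion,
    fit_cox,
    hr_at_mean_age,
    impute,
    nelson_aalen,
    pool_rubin,
    run_extension_analysis,
)
from .conftest import breslow_partial_loglik


class TestNelsonAalen:
    def test_hand_computation(self):
        got = nelson_aalen([1, 2, 3], [1, 1, 1])
        assert got == pytest.approx([1 / 3, 1 / 3 + 1 / 2, 1 / 3 + 1 / 2 + 1], abs=1e-12)

    def test_no_events_zero(self):
        assert np.allclose(nelson_aalen([1, 2, 3], [0, 0, 0]), 0.0)

    def test_single_event_among_n(self):
        # event at the earliest time: all n=4 at risk, hazard jumps by 1/4
        got = nelson_aalen([5.0, 1.0, 6.0, 7.0], [0, 1, 0, 0])
        assert got == pytest.approx([0.25, 0.25, 0.25, 0.25], abs=1e-12)
        # with an earlier censoring the risk set shrinks accordingly
        got = nelson_aalen([1.0, 2.0, 3.0, 4.0], [0, 1, 0, 0])
        assert got == pytest.approx([0.0, 1 / 3, 1 / 3, 1 / 3], abs=1e-12)


class TestRubinPooling:
    @staticmethod
    def _fit(beta, var, n=100):
        idx = pd.Index(["x"])
        return CoxFit(
            params=pd.Series([beta], idx),
            cov=pd.DataFrame([[var]], index=idx, columns=idx),
            n=n,
            n_events=50,
        )

    def test_hand_formulas(self):
        pooled = pool_rubin([self._fit(0.1, 0.01), self._fit(0.2, 0.01),
                             self._fit(0.3, 0.01)])
        assert pooled.beta["x"] == pytest.approx(0.2, abs=1e-15)
        assert pooled.W["x"] == pytest.approx(0.01, abs=1e-15)
        assert pooled.B["x"] == pytest.approx(0.01, abs=1e-15)
        assert pooled.T["x"] == pytest.approx(0.01 + (4 / 3) * 0.01, abs=1e-15)

    def test_identical_fits_no_between_variance(self):
        pooled = pool_rubin([self._fit(0.5, 0.04)] * 3)
        assert pooled.B["x"] == 0.0
        assert pooled.T["x"] == pooled.W["x"]

    def test_two_null_fits(self):
        pooled = pool_rubin([self._fit(0.0, 0.04), self._fit(0.0, 0.04)])
        assert pooled.beta["x"] == 0.0
        assert pooled.T["x"] == pytest.approx(0.04)

    def test_total_variance_dominates_within(self):
        rng = np.random.default_rng(0)
        fits = [self._fit(rng.normal(), 0.02) for _ in range(5)]
        pooled = pool_rubin(fits)
        assert (pooled.T >= pooled.W - 1e-15).all()

    def test_mismatched_terms_rejected(self):
        idx2 = pd.Index(["y"])
        other = CoxFit(pd.Series([0.1], idx2),
                       pd.DataFrame([[0.01]], index=idx2, columns=idx2), 100, 50)
        with pytest.raises(ValueError, match="mismatched"):
            pool_rubin([self._fit(0.1, 0.01), other])


class TestInclusionRule:
    @pytest.mark.parametrize(
        "ihr, p, meets",
        [
            (1.16, 0.0001, True),
            (1.07, 0.02, False),
            (1.59, 0.0001, True),
            (1.04, 0.19, False),
            (1.27, 0.0001, True),
            (1.10, 0.001, False),   # boundary: strict > 1.10
            (0.90, 0.001, False),   # boundary: strict < 0.90
            (0.85, 0.001, True),    # protective variables qualify too
            (1.50, 0.01, False),    # boundary: strict P < 0.01
        ],
    )
    def test_rule(self, ihr, p, meets):
        assert evaluate_inclusion("cancer", ihr, p).meets is meets

    def test_monotone_in_effect_size_outside_band(self):
        flags = [evaluate_inclusion("v", ihr, 0.001).meets
                 for ihr in (1.11, 1.3, 2.0, 5.0)]
        assert flags == [True] * 4
        with pytest.raises(ValueError):
            evaluate_inclusion("v", -1.0, 0.5)


class TestCoxFit:
    def test_grid_search_oracle_six_subjects(self):
        times = np.array([1.0, 2.5, 3.0, 4.2, 5.1, 6.0])
        events = np.array([1, 1, 0, 1, 0, 1])
        x = np.array([1.2, -0.4, 0.8, 0.3, -1.0, -0.2])
        df = pd.DataFrame({"x": x, "__t": times, "__e": events})
        from lifelines import CoxPHFitter

        cph = CoxPHFitter().fit(df, duration_col="__t", event_col="__e")
        grid = np.arange(-3.0, 3.0, 1e-4)
        ll = [breslow_partial_loglik(np.array([b]), x[:, None], times, events)
              for b in grid]
        assert cph.params_["x"] == pytest.approx(grid[int(np.argmax(ll))], abs=1e-3)

    def test_null_two_group_recovery(self):
        rng = np.random.default_rng(12)
        n = 3000
        g = (rng.random(n) < 0.5).astype(float)
        t = rng.exponential(5.0, n)
        c = rng.exponential(8.0, n)
        df = pd.DataFrame(
            {"followup_time": np.minimum(t, c), "event_cvd": (t <= c).astype(int)}
        )
        design = pd.DataFrame({"g": g - g.mean()})
        fit = fit_cox(df, design=design)
        z = fit.params["g"] / math.sqrt(fit.cov.loc["g", "g"])
        assert abs(z) < 3.0

    def test_recovers_binary_log_hr(self):
        cfg = SimulationConfig(
            n_matched_sets=2500, matching_ratio=2, seed=77,
            female_fraction=0.0, compact_model=True,
        ).with_uniform_cancer_effect(math.log(1.5))
        df = ok.generate_cohort(cfg)
        fit = fit_cox(
            df, spec=ModelSpec(base=cfg.true_model["male"], cancer_encoding="binary")
        )
        beta, se = fit.params["cancer"], math.sqrt(fit.cov.loc["cancer", "cancer"])
        assert beta - 1.96 * se < math.log(1.5) < beta + 1.96 * se


class TestHrAtMeanAge:
    def test_null_coefficient_gives_unit_hr(self):
        pooled = pool_rubin(
            [TestRubinPooling._fit(0.0, 0.01), TestRubinPooling._fit(0.0, 0.01)]
        )
        ihr, (lo, hi), p = hr_at_mean_age(pooled, "x")
        assert ihr == 1.0 and lo < 1.0 < hi

    def test_centering_identity(self):
        pooled = pool_rubin(
            [TestRubinPooling._fit(math.log(1.16), 0.01)] * 2
        )
        ihr, _, _ = hr_at_mean_age(pooled, "x")
        assert ihr == pytest.approx(1.16, abs=1e-12)

    def test_equivalence_with_uncentered_age_refit(self):
        """Fitting with the age product uncentred and evaluating at the mean
        age reproduces the centred fit's HR (linear reparameterisation)."""
        cfg = SimulationConfig(
            n_matched_sets=500, matching_ratio=2, seed=55,
            female_fraction=0.0, compact_model=True,
        ).with_uniform_cancer_effect(math.log(1.4))
        df = ok.generate_cohort(cfg)
        spec = ModelSpec(base=cfg.true_model["male"], cancer_encoding="binary")
        centred, means = build_design(df, spec)
        fit_c = fit_cox(df, design=centred)

        uncentred = centred.copy()
        age_col = spec.base.age_column
        age_mean = means[age_col]
        age_raw = centred[age_col].to_numpy() + age_mean
        for col in centred.columns:
            if col.endswith(":age"):
                uncentred[col] = centred[col.split(":")[0]].to_numpy() * age_raw
        fit_u = fit_cox(df, design=uncentred)
        # evaluate the uncentred interaction at the mean age component
        b_eval = fit_u.params["cancer"] + fit_u.params["cancer:age"] * age_mean
        assert b_eval == pytest.approx(fit_c.params["cancer"], abs=1e-5)

    def test_absent_term_rejected(self):
        pooled = pool_rubin([TestRubinPooling._fit(0.1, 0.01)] * 2)
        with pytest.raises(KeyError):
            hr_at_mean_age(pooled, "nope")


@pytest.fixture(scope="module")
def complete_cohort():
    cfg = SimulationConfig(
        n_matched_sets=400, matching_ratio=2, seed=88,
        female_fraction=0.0, compact_model=True,
    )
    return ok.generate_cohort(cfg), cfg


class TestImpute:

    def test_no_missing_gives_identical_copies(self, complete_cohort):
        df, cfg = complete_cohort
        spec = ModelSpec(base=cfg.true_model["male"], cancer_encoding="binary")
        out = impute(df, ImputationConfig(m=5, seed=1), spec)
        assert len(out) == 5
        for d in out:
            pd.testing.assert_frame_equal(d, df)

    def test_m_complete_datasets(self, complete_cohort):
        df, cfg = complete_cohort
        miss = ok.inject_missingness(df, {"sbp": 0.3, "smoking": 0.2}, seed=2)
        spec = ModelSpec(base=cfg.true_model["male"], cancer_encoding="binary")
        out = impute(miss, ImputationConfig(m=5, seed=3), spec)
        assert len(out) == 5
        for d in out:
            assert d["sbp"].notna().all() and d["smoking"].notna().all()
        # imputations differ between datasets (parameter + residual draws)
        assert not out[0]["sbp"].equals(out[1]["sbp"])
        # observed values untouched
        obs = miss["sbp"].notna()
        assert np.allclose(out[0].loc[obs, "sbp"], miss.loc[obs, "sbp"])

    def test_imputed_values_within_observed_support(self, complete_cohort):
        df, cfg = complete_cohort
        miss = ok.inject_missingness(df, {"chol_hdl_ratio": 0.4}, seed=4)
        spec = ModelSpec(base=cfg.true_model["male"], cancer_encoding="binary")
        out = impute(miss, ImputationConfig(m=2, seed=5), spec)
        obs = miss.loc[miss["chol_hdl_ratio"].notna(), "chol_hdl_ratio"]
        filled = out[0].loc[miss["chol_hdl_ratio"].isna(), "chol_hdl_ratio"]
        assert filled.between(obs.min(), obs.max()).all()

    def test_mi_more_efficient_than_complete_case(self):
        """Across seeded replicates the Rubin-pooled cancer estimate has
        lower empirical MSE than the complete-case estimate when 40% of two
        predictors are missing completely at random."""
        truth = math.log(1.3)
        err_mi, err_cc = [], []
        for rep in range(40):
            cfg = SimulationConfig(
                n_matched_sets=350, matching_ratio=2, seed=3000 + rep,
                female_fraction=0.0, compact_model=True,
            ).with_uniform_cancer_effect(truth)
            df = ok.generate_cohort(cfg)
            miss = ok.inject_missingness(
                df, {"sbp": 0.4, "chol_hdl_ratio": 0.4}, seed=rep
            )
            spec = ModelSpec(base=cfg.true_model["male"], cancer_encoding="binary")
            datasets = impute(miss, ImputationConfig(m=3, seed=rep), spec)
            pooled = pool_rubin([fit_cox(d, spec=spec) for d in datasets])
            err_mi.append(pooled.beta["cancer"] - truth)
            cc = miss.dropna(subset=["sbp", "chol_hdl_ratio"]).reset_index(drop=True)
            fit = fit_cox(cc, spec=spec)
            err_cc.append(fit.params["cancer"] - truth)
        assert np.mean(np.square(err_mi)) < np.mean(np.square(err_cc))

    def test_rejects_single_imputation(self):
        with pytest.raises(ValueError):
            ImputationConfig(m=1)


class TestExtensionAnalysis:
    def test_detects_strong_binary_effect(self):
        """Power check: with a generating log-HR of ln(1.3) the inclusion
        decision fires in nearly all replicates at this sample size."""
        hits = 0
        reps = 12
        for rep in range(reps):
            cfg = SimulationConfig(
                n_matched_sets=3500, matching_ratio=3, seed=5000 + rep,
                female_fraction=0.0, compact_model=True,
            ).with_uniform_cancer_effect(math.log(1.3))
            df = ok.generate_cohort(cfg)
            tab = run_extension_analysis(
                df,
                {s: cfg.true_model[s] for s in ("male", "female")},
                encodings=("binary",),
                imputation=ImputationConfig(m=2),
                seed=rep,
            )
            hits += int(tab.loc[tab["level"] == "cancer", "meets"].iloc[0])
        assert hits / reps >= 0.9

    def test_three_level_separates_haematological_from_solid(self):
        """Haematological-only effect ln(1.6): the haematological level meets
        the rule and the solid level does not, in a majority of replicates."""
        freq = dict.fromkeys(ok.SimulationConfig(10).site_frequencies, 0.0)
        # boost haematological sites so the stratum has adequate events
        freq.update(
            {
                "non_hodgkin_lymphoma": 0.15,
                "leukaemia": 0.12,
                "multiple_myeloma": 0.08,
                "lung": 0.15,
                "colorectal": 0.20,
                "bladder": 0.10,
                "prostate": 0.20,
            }
        )
        effects = {s: 0.0 for s in freq}
        effects.update(
            {
                "non_hodgkin_lymphoma": math.log(1.6),
                "leukaemia": math.log(1.6),
                "multiple_myeloma": math.log(1.6),
            }
        )
        haem_ok = solid_ok = 0
        reps = 6
        for rep in range(reps):
            cfg = SimulationConfig(
                n_matched_sets=2500, matching_ratio=2, seed=7000 + rep,
                female_fraction=0.0, compact_model=True,
                site_frequencies=freq, cancer_effects=effects,
            )
            df = ok.generate_cohort(cfg)
            tab = run_extension_analysis(
                df,
                {s: cfg.true_model[s] for s in ("male", "female")},
                encodings=("three_level",),
                imputation=ImputationConfig(m=2),
                seed=rep,
            ).set_index("level")
            haem_ok += int(tab.loc["cancer_haematological", "meets"])
            solid_ok += int(not tab.loc["cancer_solid", "meets"])
        assert haem_ok > reps / 2
        assert solid_ok > reps / 2

    def test_inestimable_site_flagged_not_dropped(self):
        cfg = SimulationConfig(n_matched_sets=300, matching_ratio=2, seed=13,
                               female_fraction=0.0, compact_model=True)
        df = ok.generate_cohort(cfg)
        # force one observed site to have no events among carriers
        site = df["cancer_site"].to_numpy()
        some = site[site != "none"][0]
        df.loc[df["cancer_site"] == some, "event_cvd"] = 0
        tab = run_extension_analysis(
            df,
            {s: cfg.true_model[s] for s in ("male", "female")},
            encodings=("site_specific",),
            imputation=ImputationConfig(m=2),
            seed=1,
        )
        row = tab[tab["level"] == f"cancer_{some}"]
        assert len(row) == 1
        assert not row["estimable"].iloc[0]
        assert not row["meets"].iloc[0]

    def test_requires_both_groups(self):
        cfg = SimulationConfig(n_matched_sets=50, seed=2)
        df = ok.generate_cohort(cfg)
        only = df[df["group"] == "survivor"]
        with pytest.raises(ValueError, match="both"):
            run_extension_analysis(
                only, {s: cfg.true_model[s] for s in ("male", "female")}
            )
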