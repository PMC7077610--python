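"""Mixed-model fitting, df bookkeeping, ladders and reports."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import optimize

from affectvar import (
    ChangeDesign,
    ConfigError,
    FitError,
    GrowthFit,
    ModelSpec,
    assign_df,
    classify_term,
    effort_ladder,
    fit_growth_model,
    hypothesis_report,
    model_sequence,
    performance_ladder,
    simple_slopes,
    substitute_covariate,
)
from affectvar.growth_models import build_exog

from conftest import make_study_scale_long

STUDY_N_OBS, STUDY_N_PART = 2996, 214


def small_mixed_data(rng, n_groups=20, per_group=6, tau=1.0, sigma=1.0, beta=(1.0, 2.0, -0.5)):
    g = np.repeat(np.arange(n_groups), per_group)
    x1 = rng.normal(size=n_groups * per_group)
    x2 = rng.normal(size=n_groups * per_group)
    y = (
        beta[0]
        + beta[1] * x1
        + beta[2] * x2
        + np.repeat(tau * rng.normal(size=n_groups), per_group)
        + sigma * rng.normal(size=n_groups * per_group)
    )
    return pd.DataFrame({"participant_id": g, "y": y, "x1": x1, "x2": x2})


class TestTermClassification:
    @pytest.mark.parametrize(
        "term, expected",
        [
            ("SA", "level1"),
            ("RA2", "level1"),
            ("SA:spin", "level1"),
            ("TA:spin:effort", "level1"),
            ("spin", "between"),
            ("effort", "between"),
            ("spin:effort", "between"),
            ("gender", "between"),
        ],
    )
    def test_time_code_rule(self, term, expected):
        assert classify_term(term) == expected

    def test_counting_oracle_tiny(self):
        # 3 participants x 2 sessions, one level-1 term: 6 - 3 - 1 = 2
        assert assign_df("level1", 6, 3, 1, 0) == 2

    def test_design_too_rich_raises(self):
        with pytest.raises(FitError):
            assign_df("between", 60, 10, 0, 12)


class TestPrintedDfArithmetic:
    """The counting rule reproduces every df printed for the study's models."""

    def _dfs(self, spec):
        l1 = sum(1 for t in spec.terms if classify_term(t) == "level1")
        bt = sum(1 for t in spec.terms if classify_term(t) == "between")
        return (
            assign_df("level1", STUDY_N_OBS, STUDY_N_PART, l1, bt) if l1 else None,
            assign_df("between", STUDY_N_OBS, STUDY_N_PART, l1, bt),
        )

    def test_effort_ladder_dfs(self):
        ladder = effort_ladder()
        assert self._dfs(ladder[0])[0] == 2777
        assert self._dfs(ladder[1])[1] == 203
        assert self._dfs(ladder[2])[1] == 201
        assert self._dfs(ladder[3])[0] == 2775
        assert self._dfs(ladder[4])[0] == 2771

    def test_performance_ladder_dfs(self):
        ladder = performance_ladder()  # RA2 pruned after step 1
        assert self._dfs(ladder[0])[0] == 2777
        assert self._dfs(ladder[1])[1] == 203
        assert self._dfs(ladder[2])[1] == 201
        assert self._dfs(ladder[3])[1] == 200
        assert self._dfs(ladder[4])[0] == 2769
        assert self._dfs(ladder[5])[0] == 2763

    def test_emotional_stability_substitution_dfs(self):
        # the ancillary refits: effort ladder with spin/pulse -> emotional stability
        es = [substitute_covariate(s) for s in effort_ladder()]
        assert self._dfs(es[3])[0] == 2776  # SA:ES model
        assert self._dfs(es[4])[0] == 2774  # TA:ES model
        es_perf = [substitute_covariate(s) for s in performance_ladder()]
        assert self._dfs(es_perf[4])[0] == 2772
        assert self._dfs(es_perf[5])[0] == 2769


class TestFitGrowthModel:
    def test_tau_fixed_zero_equals_ols(self, rng):
        data = small_mixed_data(rng, tau=0.0)
        spec = ModelSpec(outcome="y", terms=("x1", "x2"), fix_tau2=0.0)
        fit = fit_growth_model(data, spec)
        X = sm.add_constant(data[["x1", "x2"]])
        ols = sm.OLS(data["y"], X).fit()
        assert np.allclose(fit.table["B"].to_numpy(), ols.params.to_numpy(), atol=1e-6)
        assert fit.tau2 == 0.0

    def test_ml_fit_matches_hand_profiled_likelihood(self, rng):
        """Independent oracle: brute-force marginal ML on a tiny instance."""
        data = small_mixed_data(rng, n_groups=8, per_group=5)
        fit = fit_growth_model(data, ModelSpec(outcome="y", terms=("x1", "x2")))

        X = np.column_stack([np.ones(len(data)), data.x1, data.x2])
        y = data.y.to_numpy()
        groups = data.participant_id.to_numpy()

        def negll(params):
            tau2, sigma2 = np.exp(params)
            ll = 0.0
            # GLS beta given variance components
            XtVX = np.zeros((3, 3))
            XtVy = np.zeros(3)
            blocks = []
            for gid in np.unique(groups):
                idx = groups == gid
                m = idx.sum()
                V = sigma2 * np.eye(m) + tau2 * np.ones((m, m))
                Vi = np.linalg.inv(V)
                blocks.append((idx, V, Vi))
                XtVX += X[idx].T @ Vi @ X[idx]
                XtVy += X[idx].T @ Vi @ y[idx]
            beta = np.linalg.solve(XtVX, XtVy)
            for idx, V, Vi in blocks:
                r = y[idx] - X[idx] @ beta
                ll += -0.5 * (
                    len(r) * np.log(2 * np.pi)
                    + np.linalg.slogdet(V)[1]
                    + r @ Vi @ r
                )
            return -ll

        res = optimize.minimize(negll, x0=[0.0, 0.0], method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12})
        assert fit.loglik == pytest.approx(-res.fun, abs=1e-4)
        assert fit.tau2 == pytest.approx(np.exp(res.x[0]), rel=1e-2, abs=1e-3)

    def test_row_permutation_leaves_estimates_unchanged(self, small_long):
        spec = effort_ladder()[0]
        a = fit_growth_model(small_long, spec)
        shuffled = small_long.sample(frac=1.0, random_state=9)
        b = fit_growth_model(shuffled, spec)
        assert np.allclose(a.table["B"], b.table["B"], atol=1e-8)
        assert a.loglik == pytest.approx(b.loglik, abs=1e-8)

    def test_infinite_spin_refused_with_participant_names(self, small_long):
        data = small_long.copy()
        data.loc[data.index[:3], "spin"] = np.inf
        with pytest.raises(FitError, match="spin"):
            fit_growth_model(data, effort_ladder()[2])

    def test_missing_term_column_is_config_error(self, small_long):
        with pytest.raises(ConfigError, match="nonexistent"):
            fit_growth_model(small_long, ModelSpec(outcome="effort", terms=("nonexistent",)))


class TestModelSequence:
    def test_effort_ladder_loglik_nondecreasing(self, small_long):
        fits, comparison = model_sequence(small_long, "effort")
        assert len(fits) == 5
        assert (comparison["delta_loglik"].dropna() >= -1e-6).all()

    def test_performance_ladder_structure(self, small_long):
        fits, comparison = model_sequence(small_long, "performance")
        assert len(fits) == 6
        assert "RA2" in fits[0].spec.terms
        assert (comparison["delta_loglik"].dropna() >= -1e-6).all()

    def test_ra2_pruning_follows_step1_significance(self, small_long):
        fits, _ = model_sequence(small_long, "performance", alpha=0.05)
        ra2_sig = fits[0].coef("RA2")["p"] < 0.05
        for f in fits[1:]:
            assert ("RA2" in f.spec.terms) == ra2_sig
        # any p counts as non-significant at alpha ~ 0 -> always pruned;
        # at alpha = 1 the quadratic always survives
        fits_prune, _ = model_sequence(small_long, "performance", alpha=1e-12)
        assert all("RA2" not in f.spec.terms for f in fits_prune[1:])
        fits_keep, _ = model_sequence(small_long, "performance", alpha=1.0)
        assert all("RA2" in f.spec.terms for f in fits_keep[1:])


class TestSubstituteCovariate:
    def test_sa_products_collapse_to_es(self):
        spec = effort_ladder()[3]  # ... + SA:spin + SA:pulse
        es = substitute_covariate(spec)
        assert "SA:emotional_stability" in es.terms
        assert not any("spin" in t or "pulse" in t for t in es.terms)
        # the trait mains map onto the ES covariate already present (2 -> 0)
        # and the two SA products collapse onto one SA:ES term (2 -> 1)
        assert len(es.terms) == len(spec.terms) - 3
        assert es.terms.count("emotional_stability") == 1

    def test_idempotent_without_traits(self):
        spec = ModelSpec(outcome="effort", terms=("SA", "TA", "gender"))
        assert substitute_covariate(spec).terms == spec.terms


class TestHypothesisReport:
    def test_six_families_all_testable_on_full_ladders(self, small_long):
        eff, _ = model_sequence(small_long, "effort")
        perf, _ = model_sequence(small_long, "performance")
        rep = hypothesis_report(eff, perf)
        assert sorted(rep["hypothesis"].unique()) == [f"H{i}" for i in range(1, 7)]
        assert len(rep) == 14  # H6 carries two terms per trait
        assert rep["testable"].all()
        assert rep.loc[rep.hypothesis.isin(["H4", "H5"]), "one_tailed"].all()

    def test_missing_models_marked_untestable(self, small_long):
        eff, _ = model_sequence(small_long, "effort")
        perf, _ = model_sequence(small_long, "performance")
        rep = hypothesis_report(eff[:3], perf[:4])
        assert not rep.loc[rep.hypothesis == "H4", "testable"].any()
        assert not rep.loc[rep.hypothesis == "H6", "testable"].any()
        assert rep.loc[rep.hypothesis == "H1", "testable"].all()

    def test_negative_generated_interaction_recovered_in_sign(self):
        """A strong negative SA x spin effect keeps its sign across refits."""
        gamma = {
            "Intercept": 7.9, "SA": -0.04, "TA": 0.98, "RA": -0.76,
            "SA2": -0.04, "RA2": 0.08, "spin": -0.1, "pulse": 0.1,
            "SA:spin": -0.06, "SA:pulse": -0.05,
        }
        spec = ModelSpec(
            outcome="effort",
            terms=("SA", "TA", "RA", "SA2", "RA2", "spin", "pulse", "SA:spin", "SA:pulse"),
        )
        signs = []
        for rep in range(20):
            long = make_study_scale_long(seed=1000 + rep, gamma=gamma).rename(
                columns={"outcome": "effort"}
            )
            fit = fit_growth_model(long, spec)
            signs.append(fit.coef("SA:spin")["B"] < 0)
        assert np.mean(signs) >= 0.95


class TestSimpleSlopes:
    def _toy_fit(self, sa_spin=0.5):
        terms = ("SA", "spin", "SA:spin")
        table = pd.DataFrame(
            {
                "term": ["Intercept", *terms],
                "class": ["between", "level1", "between", "level1"],
                "B": [1.0, 2.0, 1.0, sa_spin],
                "SE": [0.1] * 4,
                "t": [1.0] * 4,
                "df": [10] * 4,
                "p": [0.5] * 4,
                "p_one_tailed": [0.25] * 4,
            }
        )
        spec = ModelSpec(outcome="y", terms=terms, name="toy")
        return GrowthFit(spec, table, tau2=1.0, sigma2=1.0, loglik=-1.0,
                         n_obs=40, n_participants=10, converged=True)

    def _toy_data(self, rng):
        return pd.DataFrame(
            {
                "participant_id": np.arange(40) // 4,
                "session_index": np.tile([1, 2, 3, 4], 10),
                "spin": np.repeat(rng.normal(1.0, 0.4, 10), 4),
                "y": rng.normal(size=40),
            }
        )

    def test_predicted_gap_matches_hand_arithmetic(self, rng):
        data = self._toy_data(rng)
        fit = self._toy_fit(sa_spin=0.5)
        out = simple_slopes(fit, data, "spin", ChangeDesign(14, 7))
        m, sd = data.spin.mean(), data.spin.std(ddof=1)
        final = out[out.session_index == 14].set_index("level")["predicted"]
        # gap at SA=13: (2 SD) * (spin main 1.0 + 13 * 0.5)
        expected_gap = 2 * sd * (1.0 + 13 * 0.5)
        assert final["high"] - final["low"] == pytest.approx(expected_gap, abs=1e-8)

    def test_zero_interaction_gives_parallel_curves(self, rng):
        data = self._toy_data(rng)
        out = simple_slopes(self._toy_fit(sa_spin=0.0), data, "spin", ChangeDesign(14, 7))
        gaps = (
            out.pivot(index="session_index", columns="level", values="predicted")
            .eval("high - low")
        )
        assert np.allclose(gaps, gaps.iloc[0])

    def test_one_row_per_session_per_level(self, rng):
        out = simple_slopes(self._toy_fit(), self._toy_data(rng), "spin", ChangeDesign(14, 7))
        assert len(out) == 28
        assert set(out.level) == {"high", "low"}

    def test_requires_interaction(self, rng):
        fit = self._toy_fit()
        with pytest.raises(ConfigError):
            simple_slopes(fit, self._toy_data(rng), "pulse", ChangeDesign(14, 7))


class TestExogConstruction:
    def test_product_terms_multiply_columns(self, small_long):
        X = build_exog(small_long, ("SA", "spin", "SA:spin"))
        assert np.allclose(X["SA:spin"], X["SA"] * X["spin"])
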