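"""Cox engine: likelihood oracle, Newton fit, selection tools."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest

from canopyhazard.hazard import (
    CoxFrailtyHazard,
    ModelSpec,
    cox_partial_loglik,
    fit_by_mode,
    fit_cox,
    lr_tests,
    model_ladder,
    stepwise_aic,
    table1_specs,
    vif,
)


def brute_partial_loglik(X, start, stop, event, beta, ties):
    """Hand-expanded partial likelihood: explicit loops, no shared code with
    the implementation (the independent oracle)."""
    X = np.asarray(X, float)
    eta = [float(np.dot(x, beta)) for x in X]
    ll = 0.0
    for t in sorted({stop[i] for i in range(len(stop)) if event[i]}):
        D = [i for i in range(len(stop)) if event[i] and stop[i] == t]
        R = [i for i in range(len(stop))
             if stop[i] >= t and (start is None or start[i] < t)]
        sum_r = sum(math.exp(eta[i]) for i in R)
        sum_d = sum(math.exp(eta[i]) for i in D)
        ll += sum(eta[i] for i in D)
        d = len(D)
        for l in range(d):
            if ties == "efron":
                ll -= math.log(sum_r - (l / d) * sum_d)
            else:
                ll -= math.log(sum_r)
    return ll


def random_micro(rng, n_max=8, with_start=False, tie_prone=True):
    n = rng.integers(2, n_max + 1)
    X = rng.normal(size=(n, 2))
    if tie_prone:
        stop = rng.integers(1, 5, size=n).astype(float)
    else:
        stop = rng.uniform(0.5, 5.0, size=n)
    event = rng.integers(0, 2, size=n)
    if event.sum() == 0:
        event[rng.integers(0, n)] = 1
    start = None
    if with_start:
        start = np.where(rng.random(n) < 0.5, 0.0, np.floor(stop * rng.uniform(0, 0.9, n) * 2) / 2)
        start = np.minimum(start, stop - 0.5)
        start = np.maximum(start, 0.0)
    return X, start, stop, event


class TestPartialLikelihoodOracle:
    @pytest.mark.parametrize("ties", ["efron", "breslow"])
    @pytest.mark.parametrize("with_start", [False, True])
    def test_micro_datasets(self, ties, with_start):
        rng = np.random.default_rng(42)
        for _ in range(150):
            X, start, stop, event = random_micro(rng, with_start=with_start)
            beta = rng.normal(scale=0.7, size=2)
            got = cox_partial_loglik(X, stop, event, beta, start=start, ties=ties)
            want = brute_partial_loglik(X, start, stop, event, beta, ties)
            assert got == pytest.approx(want, abs=1e-8)

    def test_beta_zero_risk_set_sizes(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            X, _, stop, event = random_micro(rng, tie_prone=False)
            got = cox_partial_loglik(X, stop, event, np.zeros(2))
            sizes = [np.sum(stop >= t) for t in stop[event.astype(bool)]]
            assert got == pytest.approx(-np.sum(np.log(sizes)), abs=1e-10)

    def test_two_subject_closed_form(self):
        for beta in (-1.0, 0.0, 0.7, 2.0):
            got = cox_partial_loglik(np.array([[1.0], [0.0]]), [1.0, 2.0], [1, 0], [beta])
            assert got == pytest.approx(beta - np.log(np.exp(beta) + 1.0), abs=1e-12)

    def test_efron_vs_breslow_on_tied_instance(self):
        X = np.array([[1.0], [0.5], [-0.2], [0.0]])
        stop = np.array([1.0, 1.0, 2.0, 2.0])
        event = np.array([1, 1, 1, 0])
        beta = [0.4]
        efron = cox_partial_loglik(X, stop, event, beta, ties="efron")
        breslow = cox_partial_loglik(X, stop, event, beta, ties="breslow")
        assert efron == pytest.approx(brute_partial_loglik(X, None, stop, event, beta, "efron"))
        assert breslow == pytest.approx(brute_partial_loglik(X, None, stop, event, beta, "breslow"))
        assert efron >= breslow  # Efron subtracts part of the death mass

    def test_gradient_matches_finite_differences(self):
        from canopyhazard.hazard import _partial_quantities

        rng = np.random.default_rng(7)
        for _ in range(20):
            X, start, stop, event = random_micro(rng, n_max=8, with_start=True)
            beta = rng.normal(scale=0.5, size=2)
            _, g, H = _partial_quantities(X, start, stop, event.astype(bool), X @ beta)
            eps = 1e-6
            for j in range(2):
                db = np.zeros(2)
                db[j] = eps
                f1 = cox_partial_loglik(X, stop, event, beta + db, start=start)
                f0 = cox_partial_loglik(X, stop, event, beta - db, start=start)
                assert g[j] == pytest.approx((f1 - f0) / (2 * eps), abs=1e-5, rel=1e-5)

    def test_nonfinite_predictor_named(self):
        X = np.array([[1.0], [np.inf]])
        with pytest.raises(FloatingPointError, match="record 1"):
            cox_partial_loglik(X, [1.0, 2.0], [1, 1], [1.0])

    def test_all_censored_warns_zero(self):
        with pytest.warns(UserWarning, match="censored"):
            ll = cox_partial_loglik(np.ones((3, 1)), [1, 2, 3], [0, 0, 0], [0.5])
        assert ll == 0.0


def _records(n=600, beta=(0.5, -0.3), seed=0, censor=2.0, ties=True, clusters=None,
             theta=0.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, len(beta)))
    eta = X @ np.array(beta)
    if clusters is not None:
        b = rng.normal(0, np.sqrt(theta), clusters)
        plot = np.repeat(np.arange(clusters), n // clusters)[:n]
        eta = eta + b[plot]
    else:
        plot = None
    t = rng.exponential(1.0 / np.exp(eta - eta.mean()))
    c = rng.exponential(censor, n)
    time = np.minimum(t, c)
    event = (t <= c).astype(int)
    if ties:
        time = np.round(time, 1) + 0.05
    df = pd.DataFrame({f"x{i}": X[:, i] for i in range(len(beta))})
    df["time"], df["event"] = time, event
    if plot is not None:
        df["plot_id"] = [f"P{p}" for p in plot]
    return df


class TestFit:
    def test_matches_lifelines(self):
        import lifelines

        df = _records()
        est = CoxFrailtyHazard(frailty=False, tol=1e-12).fit(
            df[["x0", "x1"]], df[["time", "event"]]
        )
        cph = lifelines.CoxPHFitter().fit(
            df[["x0", "x1", "time", "event"]], duration_col="time", event_col="event",
            fit_options={"precision": 1e-9},
        )
        np.testing.assert_allclose(est.coef_, cph.params_.values, rtol=1e-5)
        np.testing.assert_allclose(est.se_, cph.standard_errors_.values, rtol=1e-5)
        assert est.loglik_ == pytest.approx(cph.log_likelihood_, rel=1e-9)
        # residual disagreement is the reference solver's stopping rule, not
        # ours: our solution is the exact stationary point
        from canopyhazard.hazard import _partial_quantities

        X = df[["x0", "x1"]].values
        _, g, _ = _partial_quantities(
            X, None, df["time"].values, df["event"].values.astype(bool), X @ est.coef_
        )
        assert np.abs(g).max() < 1e-8
        assert est.loglik_ >= cph.log_likelihood_ - 1e-10

    def test_scale_equivariance(self):
        df = _records(seed=3)
        a = CoxFrailtyHazard(frailty=False).fit(df[["x0", "x1"]], df[["time", "event"]])
        scaled = df.copy()
        scaled["x0"] = scaled["x0"] * 10.0
        b = CoxFrailtyHazard(frailty=False).fit(scaled[["x0", "x1"]], scaled[["time", "event"]])
        assert b.coef_[0] == pytest.approx(a.coef_[0] / 10.0, rel=1e-6)
        assert b.loglik_ == pytest.approx(a.loglik_, rel=1e-9)
        assert b.aic_ == pytest.approx(a.aic_, rel=1e-9)
        np.testing.assert_allclose(b.chi2_, a.chi2_, rtol=1e-5)

    def test_wald_equals_coef_over_se_squared(self):
        df = _records(seed=5)
        est = CoxFrailtyHazard(frailty=False).fit(df[["x0", "x1"]], df[["time", "event"]])
        np.testing.assert_allclose(est.chi2_, (est.coef_ / est.se_) ** 2)

    def test_wald_close_to_lr(self):
        """On a well-behaved fit the Wald and likelihood-ratio chi-squares for
        a single term agree within 15 %."""
        df = _records(n=1500, beta=(0.3, -0.2), seed=8)
        df["plot_id"] = "P0"
        spec = ModelSpec(tree_terms=(), species_terms=("x0", "x1"), frailty=False)
        out = lr_tests(df, spec)
        for _, row in out.iterrows():
            assert abs(row["lr_chi2"] - row["wald_chi2"]) < 0.15 * row["lr_chi2"]

    def test_zero_variance_term_rejected(self):
        df = _records(n=50)
        df["x0"] = 1.0
        with pytest.raises(ValueError, match="zero-variance"):
            CoxFrailtyHazard(frailty=False).fit(df[["x0", "x1"]], df[["time", "event"]])

    def test_no_events_null_fit(self):
        df = _records(n=30)
        df["event"] = 0
        with pytest.warns(UserWarning, match="no events"):
            est = CoxFrailtyHazard(frailty=False).fit(df[["x0"]], df[["time", "event"]])
        assert est.loglik_ == 0.0

    def test_separation_flagged(self):
        # a covariate that perfectly orders deaths before censorings
        df = pd.DataFrame(
            {
                "x0": [3.0, 2.5, 2.0, -2.0, -2.5, -3.0],
                "time": [1.0, 2.0, 3.0, 10.0, 11.0, 12.0],
                "event": [1, 1, 1, 0, 0, 0],
            }
        )
        with pytest.warns(UserWarning, match="monotone likelihood"):
            est = CoxFrailtyHazard(frailty=False, max_iter=200).fit(
                df[["x0"]], df[["time", "event"]]
            )
        assert est.separation_flag_

    def test_theta_zero_for_homogeneous_clusters(self):
        df = _records(n=1200, seed=11, clusters=12, theta=0.0)
        est = CoxFrailtyHazard(frailty=True).fit(
            df[["x0", "x1"]], df[["time", "event"]], cluster=df["plot_id"]
        )
        assert est.theta_ < 0.02

    def test_fixed_theta_near_profiled(self):
        df = _records(n=1500, seed=12, clusters=15, theta=0.5)
        prof = CoxFrailtyHazard(frailty=True).fit(
            df[["x0", "x1"]], df[["time", "event"]], cluster=df["plot_id"]
        )
        fixed = CoxFrailtyHazard(frailty=True, theta=prof.theta_).fit(
            df[["x0", "x1"]], df[["time", "event"]], cluster=df["plot_id"]
        )
        np.testing.assert_allclose(fixed.coef_, prof.coef_, rtol=1e-6)


class TestSpecAndSelection:
    def _sim_records(self, n=1200, seed=0, beta_x1=0.4, beta_x2=0.0):
        df = _records(n=n, beta=(beta_x1, beta_x2), seed=seed)
        df = df.rename(columns={"x0": "mean_growth", "x1": "wood_density"})
        df["plot_id"] = "P0"
        return df

    def test_spec_hierarchy_enforced(self):
        with pytest.raises(ValueError, match="quadratic"):
            ModelSpec(tree_terms=("D2",), species_terms=())

    def test_null_model_aic_consistency(self):
        df = self._sim_records()
        null = fit_cox(df, ModelSpec(tree_terms=(), species_terms=(), frailty=False))
        assert null.aic == pytest.approx(-2.0 * null.loglik)
        ll = cox_partial_loglik(
            np.zeros((len(df), 0)), df["time"].values, df["event"].values
        )
        assert null.loglik == pytest.approx(ll)

    def test_ladder_duplicate_specs_identical(self):
        df = self._sim_records()
        spec = ModelSpec(tree_terms=(), species_terms=("mean_growth",), frailty=False)
        ladder = model_ladder(df, [spec, spec])
        assert ladder["aic"].iloc[0] == pytest.approx(ladder["aic"].iloc[1])
        assert ladder["delta_aic"].iloc[0] == 0.0

    def test_ladder_failed_fit_marked(self):
        df = self._sim_records()
        bad = ModelSpec(tree_terms=(), species_terms=("nonexistent",), frailty=False)
        good = ModelSpec(tree_terms=(), species_terms=("mean_growth",), frailty=False)
        ladder = model_ladder(df, [good, bad])
        assert ladder["failed"].sum() == 1
        assert not ladder[ladder["failed"]]["converged"].any()

    def test_stepwise_guarantee_and_trace(self):
        df = self._sim_records(beta_x2=0.0, seed=4)
        full = ModelSpec(tree_terms=(), species_terms=("mean_growth", "wood_density"),
                         frailty=False)
        selected, trace = stepwise_aic(df, full)
        aic_sel = fit_cox(df, selected).aic
        aic_full = fit_cox(df, full).aic
        aic_null = fit_cox(df, ModelSpec(tree_terms=(), species_terms=(), frailty=False)).aic
        assert aic_sel <= min(aic_full, aic_null) + 1e-9
        assert (trace["step"] == 0).sum() == 1
        assert len(trace) > 1  # every candidate recorded

    def test_stepwise_respects_size_hierarchy(self):
        rng = np.random.default_rng(2)
        df = self._sim_records(seed=9)
        df["D"] = rng.uniform(0.1, 1.0, len(df))
        df["D2"] = df["D"] ** 2
        full = ModelSpec(tree_terms=("D", "D2"), species_terms=("mean_growth",),
                         frailty=False)
        selected, trace = stepwise_aic(df, full)
        # no candidate may contain D2 without D
        for terms in trace["terms"]:
            assert not ("D2" in terms and "D" not in terms)


class TestVif:
    def test_orthogonal_predictors(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=400)
        b = rng.normal(size=400)
        b -= a * (a @ b) / (a @ a)  # exactly orthogonal sample
        df = pd.DataFrame({"a": a, "b": b})
        v = vif(df, ["a", "b"])
        assert np.allclose(v.values, 1.0, atol=1e-8)

    def test_duplicated_predictor_infinite(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=100)
        df = pd.DataFrame({"a": a, "b": a.copy(), "c": rng.normal(size=100)})
        v = vif(df, ["a", "b", "c"])
        assert np.isinf(v["a"]) and np.isinf(v["b"])

    def test_r2_point_nine_gives_ten(self):
        rng = np.random.default_rng(2)
        n = 500
        a = rng.normal(size=n)
        e = rng.normal(size=n)
        a = (a - a.mean()) / a.std()
        e -= a * (a @ e) / (a @ a)
        e = (e - e.mean()) / e.std()
        b = np.sqrt(0.9) * a + np.sqrt(0.1) * e  # sample R^2 exactly 0.9
        v = vif(pd.DataFrame({"a": a, "b": b}), ["a", "b"])
        assert v["b"] == pytest.approx(10.0, rel=1e-6)


class TestFitByMode:
    def test_single_mode_skips_other(self):
        df = _records(n=300, seed=3)
        df["plot_id"] = "P0"
        df["death_mode"] = np.where(df["event"] == 1, "standing", "not_applicable")
        spec = ModelSpec(tree_terms=(), species_terms=("x0", "x1"), frailty=False)
        out = fit_by_mode(df, spec)
        assert isinstance(out["broken_uprooted"], str)
        assert out["standing"].n_events == df["event"].sum()

    def test_exchangeable_modes_agree(self):
        rng = np.random.default_rng(9)
        df = _records(n=2000, seed=9)
        df["plot_id"] = "P0"
        modes = np.where(rng.random(len(df)) < 0.5, "standing", "broken_uprooted")
        df["death_mode"] = np.where(df["event"] == 1, modes, "not_applicable")
        spec = ModelSpec(tree_terms=(), species_terms=("x0",), frailty=False)
        out = fit_by_mode(df, spec)
        a, b = out["standing"], out["broken_uprooted"]
        joint_se = np.hypot(a.se[0], b.se[0])
        assert abs(a.coef[0] - b.coef[0]) < 2.5 * joint_se
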