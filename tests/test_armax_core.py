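"""armax_core: prediction, simulation, and PEM estimation.

The independent oracles live in this file: a naive direct-recursion
predictor/simulator, a scipy.optimize minimisation of an independently coded
prediction-error loss, and statsmodels' state-space ARIMA on the pure-ARMA
reduction of the model.
"""

import json

import numpy as np
import pytest
from scipy import optimize

import radonarmax as rx
from radonarmax.armax_core import pack_theta, unpack_theta

from conftest import make_bundle

# ---------------------------------------------------------------------------
# independent oracles


def recursion_predict(params, order, y, u_map, t):
    """One-step prediction by direct recursion (independent of the package).

    Residuals are formed sequentially from index max_lag on, zero before.
    """
    maxlag = order.max_lag
    eps = np.zeros(len(y))
    for s in range(maxlag, t + 1):
        yhat = params.intercept
        for j, aj in enumerate(params.a, start=1):
            yhat -= aj * y[s - j]
        for ch, coeffs in params.b.items():
            for j, bj in enumerate(coeffs):
                yhat += bj * u_map[ch][s - order.nk - j]
        for j, cj in enumerate(params.c, start=1):
            yhat += cj * eps[s - j]
        eps[s] = y[s] - yhat
        if s == t:
            return yhat
    raise AssertionError("t below max lag")


def recursion_simulate(params, order, u_map, n, y_init=None, noise=None):
    """Free-run simulation by direct recursion (independent of the package)."""
    na = order.na
    y = np.zeros(n + na)
    if y_init is not None:
        y[:na] = y_init
    e = np.zeros(n) if noise is None else np.asarray(noise)
    for t in range(n):
        s = t + na
        acc = params.intercept + e[t]
        for j, aj in enumerate(params.a, start=1):
            acc -= aj * y[s - j]
        for ch, coeffs in params.b.items():
            for j, bj in enumerate(coeffs):
                lag = order.nk + j
                acc += bj * (u_map[ch][t - lag] if t - lag >= 0 else 0.0)
        for j, cj in enumerate(params.c, start=1):
            acc += cj * (e[t - j] if t - j >= 0 else 0.0)
        y[s] = acc
    return y[na:]


def pem_loss_reference(theta, order, y, u, maxlag):
    """Independently coded PEM loss (single input channel named 'temperature')."""
    na, nb, nc = order.na, order.nb_map["temperature"], order.nc
    a = theta[:na]
    b = theta[na : na + nb]
    c = theta[na + nb : na + nb + nc]
    mu = theta[-1]
    n = len(y)
    eps = np.zeros(n)
    loss = 0.0
    for t in range(maxlag, n):
        yhat = mu
        for j in range(na):
            yhat -= a[j] * y[t - 1 - j]
        for j in range(nb):
            yhat += b[j] * u[t - order.nk - j]
        for j in range(nc):
            yhat += c[j] * eps[t - 1 - j]
        eps[t] = y[t] - yhat
        loss += eps[t] ** 2
    return loss


# ---------------------------------------------------------------------------
# one-step prediction


class TestPredictOneStep:
    def test_pure_gain_model(self):
        order = rx.ARMAXOrder(na=0, nb=(0, 1, 0, 0), nc=0)
        params = rx.ARMAXParameters(a=[], b={"temperature": [2.0]}, c=[])
        bundle = make_bundle(np.zeros(5), temperature=[3.0, 3.0, 3.0, 3.0, 3.0])
        assert rx.predict_one_step(params, order, bundle, 2) == pytest.approx(6.0)

    def test_ar1_prediction(self):
        # y(t) = 0.5 y(t-1) + e  <=>  a1 = -0.5
        order = rx.ARMAXOrder(na=1, nb=(0, 0, 0, 0), nc=0)
        params = rx.ARMAXParameters(a=[-0.5], b={}, c=[])
        bundle = make_bundle(np.array([10.0, 10.0, 4.0]))
        assert rx.predict_one_step(params, order, bundle, 1) == pytest.approx(5.0)

    def test_insufficient_history_raises(self):
        order = rx.ARMAXOrder(na=2, nb=(0, 0, 0, 0), nc=0)
        params = rx.ARMAXParameters(a=[-0.5, 0.1], b={}, c=[])
        bundle = make_bundle(np.arange(10.0) + 1)
        with pytest.raises(rx.InsufficientDataError):
            rx.predict_one_step(params, order, bundle, 1)

    def test_matches_direct_recursion_oracle(self):
        rng = np.random.default_rng(7)
        order = rx.ARMAXOrder(na=2, nb=(1, 2, 0, 0), nc=2)
        params = rx.ARMAXParameters(
            a=[-0.6, 0.08],
            b={"pressure": [0.5], "temperature": [1.0, -0.3]},
            c=[0.4, 0.1],
            intercept=2.0,
        )
        n = 60
        y = rng.normal(10, 2, n)
        u = {"pressure": rng.normal(0, 1, n), "temperature": rng.normal(0, 1, n)}
        bundle = make_bundle(np.abs(y), pressure=u["pressure"], temperature=u["temperature"])
        bundle.radon = y
        for t in (5, 20, 59):
            ours = rx.predict_one_step(params, order, bundle, t)
            ref = recursion_predict(params, order, y, u, t)
            assert ours == pytest.approx(ref, abs=1e-12)


# ---------------------------------------------------------------------------
# free-run simulation


class TestSimulateFreeRun:
    def test_static_gain_step_response(self):
        order = rx.ARMAXOrder(na=0, nb=(0, 1, 0, 0), nc=0)
        params = rx.ARMAXParameters(a=[], b={"temperature": [2.0]}, c=[])
        y = rx.simulate_free_run(params, order, {"temperature": np.ones(20)})
        np.testing.assert_allclose(y[order.nk :], 2.0)

    def test_ar1_step_converges_to_dc_gain(self):
        order = rx.ARMAXOrder(na=1, nb=(0, 1, 0, 0), nc=0)
        params = rx.ARMAXParameters(a=[-0.5], b={"temperature": [1.0]}, c=[])
        y = rx.simulate_free_run(params, order, {"temperature": np.ones(300)})
        assert abs(y[-1] - 1.0 / (1.0 - 0.5)) < 1e-6

    def test_dc_gain_law_random_stable_models(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            a1 = rng.uniform(-0.9, 0.9)
            b1 = rng.uniform(-2, 2)
            mu = rng.uniform(-5, 5)
            order = rx.ARMAXOrder(na=1, nb=(1, 0, 0, 0), nc=0)
            params = rx.ARMAXParameters(
                a=[a1], b={"pressure": [b1]}, c=[], intercept=mu
            )
            u0 = rng.uniform(-3, 3)
            y = rx.simulate_free_run(params, order, {"pressure": np.full(600, u0)})
            assert abs(y[-1] - params.steady_state({"pressure": u0})) < 1e-6

    def test_innovation_inversion_round_trip(self):
        rng = np.random.default_rng(12)
        order = rx.ARMAXOrder(na=2, nb=(1, 0, 0, 0), nc=2)
        params = rx.ARMAXParameters(
            a=[-1.1, 0.3], b={"pressure": [0.8]}, c=[0.5, 0.2], intercept=4.0
        )
        n = 400
        e = rng.normal(0, 1, n)
        u = {"pressure": rng.normal(1000, 3, n)}
        y = rx.simulate_free_run(params, order, u, noise=e)
        # invert the transfer form: e = (A y - B u - mu) / C, zero initial state
        from scipy import signal

        Ay = signal.lfilter(params.a_poly, [1.0], y)
        Bu = np.zeros(n)
        Bu[1:] = 0.8 * u["pressure"][:-1]
        ehat = signal.lfilter([1.0], params.c_poly, Ay - Bu - 4.0)
        np.testing.assert_allclose(ehat, e, atol=1e-9)

    def test_matches_direct_recursion_oracle(self):
        rng = np.random.default_rng(21)
        order = rx.ARMAXOrder(na=2, nb=(1, 1, 0, 0), nc=1)
        params = rx.ARMAXParameters(
            a=[-0.7, 0.12],
            b={"pressure": [0.4], "temperature": [-0.9]},
            c=[0.3],
            intercept=1.5,
        )
        n = 100
        u = {"pressure": rng.normal(0, 1, n), "temperature": rng.normal(0, 1, n)}
        e = rng.normal(0, 1, n)
        y_init = [2.0, 3.0]
        ours = rx.simulate_free_run(params, order, u, y_init=y_init, noise=e)
        ref = recursion_simulate(params, order, u, n, y_init=y_init, noise=e)
        np.testing.assert_allclose(ours, ref, atol=1e-12)

    def test_unstable_model_warns_but_returns(self):
        order = rx.ARMAXOrder(na=1, nb=(0, 1, 0, 0), nc=0)
        params = rx.ARMAXParameters(a=[-1.05], b={"temperature": [1.0]}, c=[])
        with pytest.warns(rx.UnstableModelWarning):
            y = rx.simulate_free_run(params, order, {"temperature": np.ones(50)})
        assert y.shape == (50,)

    def test_simulation_equals_prediction_without_feedback(self):
        """With na=0 and nc=0 the free run and one-step predictor coincide."""
        rng = np.random.default_rng(5)
        order = rx.ARMAXOrder(na=0, nb=(0, 2, 0, 0), nc=0)
        params = rx.ARMAXParameters(a=[], b={"temperature": [1.2, -0.4]}, c=[], intercept=3.0)
        n = 50
        u = rng.normal(0, 1, n)
        bundle = make_bundle(rng.normal(5, 1, n), temperature=u)
        sim = rx.simulate_free_run(params, order, {"temperature": u})
        yhat, _ = rx.one_step_predictions(params, order, bundle)
        ok = np.isfinite(yhat)
        np.testing.assert_allclose(sim[ok], yhat[ok], atol=1e-12)


# ---------------------------------------------------------------------------
# estimation


class TestEstimatePEM:
    def test_noise_free_arx_exact_identification(self):
        rng = np.random.default_rng(2)
        order = rx.ARMAXOrder(na=1, nb=(0, 1, 0, 0), nc=0)
        true = rx.ARMAXParameters(a=[-0.7], b={"temperature": [1.0]}, c=[])
        n = 500
        u = rng.normal(0, 1, n)  # persistently exciting
        y = rx.simulate_free_run(true, order, {"temperature": u})
        bundle = make_bundle(np.zeros(n), temperature=u)
        bundle.radon = y
        fit = rx.estimate_pem(bundle, order)
        assert abs(fit.params.a[0] + 0.7) < 1e-6
        assert abs(fit.params.b["temperature"][0] - 1.0) < 1e-6
        assert abs(fit.params.intercept) < 1e-6

    def test_monte_carlo_a1_recovery(self, estimator_mc_errors):
        """Median |a1 - 0.7| < 0.05 on the ARMAX(1,1,1) benchmark."""
        assert np.median(estimator_mc_errors) < 0.05

    def test_loss_matches_statsmodels_on_arma_reduction(self):
        """Pure-ARMA data: PEM loss within 1% of the statsmodels optimum."""
        sm = pytest.importorskip("statsmodels.tsa.arima.model")
        rng = np.random.default_rng(8)
        order = rx.ARMAXOrder(na=1, nb=(0, 0, 0, 0), nc=1)
        true = rx.ARMAXParameters(a=[-0.7], b={}, c=[0.4])
        n = 2000
        e = rng.normal(0, 1, n)
        y = rx.simulate_free_run(true, order, {}, noise=e, n_samples=n)
        bundle = make_bundle(np.zeros(n))
        bundle.radon = y
        ours = rx.estimate_pem(bundle, order)

        res = sm.ARIMA(y, order=(1, 0, 1), trend="n").fit()
        phi, theta = res.arparams[0], res.maparams[0]
        sm_params = rx.ARMAXParameters(
            a=[-phi], b={}, c=[theta], intercept=0.0
        )
        # evaluate OUR loss functional at the statsmodels optimum
        _, eps_sm = rx.one_step_predictions(sm_params, order, bundle)
        loss_sm = np.nansum(eps_sm**2)
        assert abs(ours.loss - loss_sm) / loss_sm < 0.01

    def test_loss_matches_independent_scipy_optimum(self):
        """Full ARMAX data: GN loss within 1% of a scipy-minimised
        independently coded prediction-error loss."""
        rng = np.random.default_rng(9)
        order = rx.ARMAXOrder(na=1, nb=(0, 1, 0, 0), nc=1)
        true = rx.ARMAXParameters(a=[-0.7], b={"temperature": [1.0]}, c=[0.4])
        n = 2000
        u = rng.normal(0, 1, n)
        e = rng.normal(0, 1, n)
        y = rx.simulate_free_run(true, order, {"temperature": u}, noise=e)
        bundle = make_bundle(np.zeros(n), temperature=u)
        bundle.radon = y
        ours = rx.estimate_pem(bundle, order)

        x0 = np.array([-0.65, 0.9, 0.3, 0.05])  # deliberately off-true start
        ref = optimize.minimize(
            pem_loss_reference,
            x0,
            args=(order, y, u, order.max_lag),
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-10, "maxiter": 4000},
        )
        assert abs(ours.loss - ref.fun) / ref.fun < 0.01

    def test_consistency_error_shrinks_with_n(self):
        """Parameter error smaller at n=4000 than n=500 in >= 18/20 seeds."""
        order = rx.ARMAXOrder(na=1, nb=(0, 1, 0, 0), nc=1)
        true = rx.ARMAXParameters(a=[-0.7], b={"temperature": [1.0]}, c=[0.4])
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            errs = {}
            for n in (500, 4000):
                u = rng.normal(0, 1, n)
                e = rng.normal(0, 1, n)
                y = rx.simulate_free_run(true, order, {"temperature": u}, noise=e)
                bundle = make_bundle(np.zeros(n), temperature=u)
                bundle.radon = y
                fit = rx.estimate_pem(bundle, order)
                theta = pack_theta(fit.params, order)
                theta_true = pack_theta(true, order)
                errs[n] = np.linalg.norm(theta - theta_true)
            wins += errs[4000] < errs[500]
        assert wins >= 18

    def test_residual_whiteness_of_well_specified_fit(self):
        """Ljung-Box below its 99% null quantile in >= 90% of replicates."""
        lb = pytest.importorskip("statsmodels.stats.diagnostic")
        order = rx.ARMAXOrder(na=1, nb=(0, 1, 0, 0), nc=1)
        true = rx.ARMAXParameters(a=[-0.7], b={"temperature": [1.0]}, c=[0.4])
        passed = 0
        n_rep = 20
        for seed in range(n_rep):
            rng = np.random.default_rng(2000 + seed)
            n = 1500
            u = rng.normal(0, 1, n)
            e = rng.normal(0, 1, n)
            y = rx.simulate_free_run(true, order, {"temperature": u}, noise=e)
            bundle = make_bundle(np.zeros(n), temperature=u)
            bundle.radon = y
            fit = rx.estimate_pem(bundle, order)
            eps = fit.residuals[np.isfinite(fit.residuals)]
            out = lb.acorr_ljungbox(eps, lags=[20], model_df=order.na + order.nc)
            from scipy import stats

            crit = stats.chi2.ppf(0.99, 20 - order.na - order.nc)
            passed += float(out["lb_stat"].iloc[0]) < crit
        assert passed / n_rep >= 0.90

    def test_constant_channel_degeneracy_named(self):
        rng = np.random.default_rng(4)
        n = 300
        order = rx.ARMAXOrder(na=1, nb=(0, 1, 0, 0), nc=0)
        bundle = make_bundle(rng.normal(100, 5, n), temperature=np.full(n, 9.0))
        with pytest.raises(rx.DegeneracyError, match="temperature"):
            rx.estimate_pem(bundle, order)

    def test_too_short_creation_window_raises(self):
        bundle, truth = rx.generate(rx.ScenarioConfig(n_hours=200, seed=1))
        with pytest.raises(rx.InsufficientDataError):
            rx.estimate_pem(bundle, truth.order, rx.SplitConfig(30))

    def test_loss_equals_sum_of_squared_residuals(self):
        bundle, truth = rx.generate(rx.ScenarioConfig(n_hours=400, seed=6))
        fit = rx.estimate_pem(bundle, truth.order)
        assert fit.loss == pytest.approx(np.nansum(fit.residuals**2), abs=1e-9)

    def test_fitted_c_is_invertible(self):
        bundle, truth = rx.generate(rx.ScenarioConfig(n_hours=800, seed=9))
        fit = rx.estimate_pem(bundle, truth.order)
        assert fit.params.is_invertible

    def test_masked_holes_do_not_break_fit(self):
        bundle, truth = rx.generate(rx.ScenarioConfig(n_hours=900, seed=10))
        bundle.mask[200:220] = False
        bundle.mask[500:510] = False
        fit = rx.estimate_pem(bundle, truth.order)
        assert fit.converged
        # residuals undefined across each hole's shadow
        assert np.isnan(fit.residuals[200:221]).all()


class TestModelSerialization:
    def test_json_round_trip_is_lossless(self, tmp_path):
        bundle, truth = rx.generate(rx.ScenarioConfig(n_hours=500, seed=13))
        fit = rx.estimate_pem(bundle, truth.order)
        path = tmp_path / "model.json"
        rx.save_model(fit, path)
        back = rx.load_model(path)
        assert back.order == fit.order
        np.testing.assert_array_equal(back.params.a, fit.params.a)
        np.testing.assert_array_equal(back.params.c, fit.params.c)
        for ch in fit.params.b:
            np.testing.assert_array_equal(back.params.b[ch], fit.params.b[ch])
        assert back.params.intercept == fit.params.intercept
        assert back.loss == fit.loss

    def test_schema_checked(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text(json.dumps({"schema": "something-else"}))
        with pytest.raises(rx.ParameterError):
            rx.load_model(path)
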