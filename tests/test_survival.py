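"""Censored lognormal AFT likelihood, MLE fitting and model comparison."""

import math

import numpy as np
import pytest
from sklearn.base import clone

from cnsot import (
    DomainError,
    ExposureDataset,
    ExposureRecord,
    IdentifiabilityError,
    PowerEquationAFT,
    cns_ot_index,
    fit_mle,
    lr_test,
    neg_log_likelihood,
    read_records,
    risk,
    simulate_records,
    wald_test,
    write_records,
)
from cnsot.simulate import SimulationDesign

from conftest import surv_y

TRUTH = dict(c=10.93, mu=8.99, sigma=0.81)


def _sim(seed=0, n=500, **overrides):
    kw = dict(
        po2_levels=(2.3, 2.6, 2.9, 3.2),
        n_per_level=n,
        censor_min=120.0,
        seed=seed,
        condition="immersed",
        **TRUTH,
    )
    kw.update(overrides)
    return simulate_records(SimulationDesign(**kw))


class TestLikelihood:
    def test_single_event_closed_form(self):
        # po2 = 1, time = exp(mu): Z = 0, so NLL = ln(sigma * t * sqrt(2 pi))
        mu, sigma = 9.0, 0.8
        ds = ExposureDataset(po2=[1.0], time=[math.exp(mu)], event=[True])
        expected = math.log(sigma) + mu + 0.5 * math.log(2 * math.pi)
        assert neg_log_likelihood(11.0, mu, sigma, ds) == pytest.approx(
            expected, rel=1e-12
        )

    def test_censored_record_only_increases_nll(self):
        ds = ExposureDataset(po2=[2.8, 3.2], time=[30.0, 45.0], event=[True, True])
        base = neg_log_likelihood(**TRUTH, dataset=ds)
        ds2 = ExposureDataset(
            po2=[2.8, 3.2, 2.6], time=[30.0, 45.0, 120.0], event=[True, True, False]
        )
        assert neg_log_likelihood(**TRUTH, dataset=ds2) >= base

    def test_five_record_sum_matches_high_precision_oracle(self):
        # independent summation with arbitrary-precision normal CDF (sympy)
        import sympy

        c, mu, sigma = 10.93, 8.99, 0.81
        recs = [
            (2.83, 40.0, True),
            (2.83, 120.0, False),
            (3.44, 25.0, True),
            (4.08, 10.0, True),
            (2.26, 120.0, False),
        ]
        total = sympy.Float(0, 40)
        for po2, t, event in recs:
            z = (
                sympy.log(sympy.Float(t, 40))
                - (sympy.Float(mu, 40) - c / sympy.Integer(2) * sympy.log(sympy.Float(po2, 40)))
            ) / sympy.Float(sigma, 40)
            if event:
                total += (
                    sympy.log(sympy.Float(sigma, 40))
                    + sympy.log(sympy.Float(t, 40))
                    + z**2 / 2
                    + sympy.log(2 * sympy.pi) / 2
                )
            else:
                total += -sympy.log(sympy.erfc(z / sympy.sqrt(2)) / 2)
        oracle = float(sympy.N(total, 20))
        ds = ExposureDataset(
            po2=[r[0] for r in recs],
            time=[r[1] for r in recs],
            event=[r[2] for r in recs],
        )
        assert neg_log_likelihood(c, mu, sigma, ds) == pytest.approx(
            oracle, rel=1e-10
        )

    def test_sigma_domain(self):
        ds = ExposureDataset(po2=[2.8], time=[30.0], event=[True])
        with pytest.raises(DomainError):
            neg_log_likelihood(10.0, 9.0, 0.0, ds)


class TestFit:
    def test_noise_free_limit_recovers_exponent_exactly(self):
        # deterministic onset times at two PO2 levels pin down c
        ds = _sim(sigma=1e-3, n=50, censor_min=1e9)
        res = fit_mle(ds)
        assert res.converged
        assert res.c == pytest.approx(TRUTH["c"], rel=1e-3)
        assert res.mu == pytest.approx(TRUTH["mu"], rel=1e-3)

    def test_parameter_recovery_within_sampling_error(self):
        ds = _sim(seed=3, n=500)
        res = fit_mle(ds)
        assert res.converged
        for term, truth in TRUTH.items():
            est = getattr(res, term)
            assert abs(est - truth) < 3 * res.se[term]
            assert res.lower95[term] < est < res.upper95[term]

    def test_matches_lifelines_oracle(self):
        import pandas as pd
        from lifelines import LogNormalAFTFitter

        ds = _sim(seed=11, n=250)
        res = fit_mle(ds)
        df = pd.DataFrame(
            {"T": ds.time, "E": ds.event.astype(int), "lnp": np.log(ds.po2)}
        )
        oracle = LogNormalAFTFitter().fit(df, duration_col="T", event_col="E")
        c_oracle = -2.0 * oracle.params_[("mu_", "lnp")]
        mu_oracle = oracle.params_[("mu_", "Intercept")]
        sigma_oracle = math.exp(oracle.params_[("sigma_", "Intercept")])
        assert res.c == pytest.approx(c_oracle, abs=1e-3)
        assert res.mu == pytest.approx(mu_oracle, abs=1e-3)
        assert res.sigma == pytest.approx(sigma_oracle, abs=1e-4)
        assert res.log_likelihood == pytest.approx(oracle.log_likelihood_, rel=1e-9)

    def test_fitted_model_is_the_risk_transform(self):
        # the event-time CDF and the dose-index risk are the same object
        ds = _sim(seed=5, n=200)
        res = fit_mle(ds)
        est = PowerEquationAFT().fit(ds.po2, surv_y(ds))
        p = res.params
        for t, po2 in [(20.0, 2.4), (60.0, 2.9), (110.0, 3.2)]:
            via_index = risk(cns_ot_index(t, po2, p.c), p)
            via_cdf = est.predict_risk(np.array([po2]), t)[0]
            assert via_cdf == pytest.approx(via_index, rel=1e-9)

    def test_reparameterisation_time_units(self):
        # measuring time in seconds shifts mu by ln 60, leaves c and sigma
        ds = _sim(seed=7, n=300)
        ds_sec = ExposureDataset(
            po2=ds.po2, time=ds.time * 60.0, event=ds.event
        )
        res_min = fit_mle(ds)
        res_sec = fit_mle(ds_sec)
        assert res_sec.c == pytest.approx(res_min.c, abs=1e-4)
        assert res_sec.sigma == pytest.approx(res_min.sigma, abs=1e-5)
        assert res_sec.mu - res_min.mu == pytest.approx(math.log(60), abs=1e-4)

    def test_kc_interval_is_lognormal_around_exp_2mu(self):
        res = fit_mle(_sim(seed=9, n=300))
        assert res.kc == pytest.approx(math.exp(2 * res.mu), rel=1e-12)
        z95 = 1.959963984540054
        assert res.lower95["kc"] == pytest.approx(
            math.exp(2 * res.mu - z95 * 2 * res.se["mu"]), rel=1e-9
        )
        assert res.upper95["kc"] == pytest.approx(
            math.exp(2 * res.mu + z95 * 2 * res.se["mu"]), rel=1e-9
        )

    def test_single_po2_level_unidentifiable(self):
        ds = _sim(po2_levels=(2.8,), n=50)
        with pytest.raises(IdentifiabilityError):
            fit_mle(ds)

    def test_all_censored_rejected(self):
        ds = ExposureDataset(
            po2=[2.3, 2.9], time=[120.0, 120.0], event=[False, False]
        )
        with pytest.raises(IdentifiabilityError):
            fit_mle(ds)

    def test_report_terms_table(self):
        res = fit_mle(_sim(seed=13, n=200))
        df = res.to_frame()
        assert list(df.columns) == ["term", "estimate", "se", "lower95", "upper95"]
        assert set(df["term"]) == {"kc", "c", "mu", "sigma"}
        assert "log_likelihood" in res.to_json()


class TestSklearnProtocol:
    def test_get_set_params_and_clone(self):
        est = PowerEquationAFT(n_starts=3, tol=1e-6)
        assert est.get_params()["n_starts"] == 3
        est2 = clone(est).set_params(n_starts=2)
        assert est2.get_params()["n_starts"] == 2

    def test_fit_predict_score(self):
        ds = _sim(seed=17, n=200)
        est = PowerEquationAFT().fit(ds.po2.reshape(-1, 1), surv_y(ds))
        assert est.converged_
        med = est.predict(np.array([[2.5], [3.2]]))
        assert med[0] > med[1]  # higher PO2, earlier onset
        assert est.score(ds.po2, surv_y(ds)) < 0.0


class TestComparisons:
    def test_wald_identical_fits_give_zero(self):
        res = fit_mle(_sim(seed=19, n=300))
        t = wald_test(res, res)
        assert t.statistic == pytest.approx(0.0, abs=1e-9)
        assert t.p_value == pytest.approx(1.0)

    def test_lr_statistic_nonnegative_and_null_split_large_p(self):
        ds = _sim(seed=21, n=600)
        half = len(ds) // 2
        rng = np.random.default_rng(21)
        idx = rng.permutation(len(ds))
        a, b = idx[:half], idx[half:]
        ds_a = ExposureDataset(po2=ds.po2[a], time=ds.time[a], event=ds.event[a])
        ds_b = ExposureDataset(po2=ds.po2[b], time=ds.time[b], event=ds.event[b])
        t = lr_test(ds_a, ds_b)
        assert t.statistic >= 0.0
        assert t.p_value > 0.05

    def test_printed_parameter_sets_are_distinguishable(self):
        # immersed vs dry truth at realistic sizes: decisive rejection
        ds_i = _sim(seed=23, n=120)
        ds_d = simulate_records(
            SimulationDesign(
                (2.6, 2.9, 3.3, 3.67), 120, 180.0, 12.99, 11.34, 0.65,
                seed=24, condition="dry",
            )
        )
        w = wald_test(fit_mle(ds_i), fit_mle(ds_d))
        lr = lr_test(ds_i, ds_d)
        assert w.p_value < 0.001
        assert lr.p_value < 0.001


class TestRecordsIO:
    def test_round_trip(self, tmp_path):
        ds = _sim(seed=25, n=40)
        path = tmp_path / "records.csv"
        write_records(ds, path)
        df = read_records(path)
        back = ExposureDataset.from_frame(df, condition="immersed")
        assert np.array_equal(back.po2, ds.po2)
        assert np.allclose(back.time, ds.time)
        assert np.array_equal(back.event, ds.event)

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("po2_bar,time_min\n2.8,30\n")
        with pytest.raises(DomainError, match="event"):
            read_records(path)

    def test_record_validation(self):
        with pytest.raises(DomainError):
            ExposureRecord(po2=2.8, time=0.0, event=True)
        with pytest.raises(DomainError):
            ExposureRecord(po2=0.0, time=10.0, event=False)
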