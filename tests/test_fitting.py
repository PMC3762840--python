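"""Maximum-likelihood fitting: recovery, diagnostics, cost schemes."""

import numpy as np
import pytest
from statsmodels.stats.stattools import durbin_watson

from hyperkin import (
    InputFunction,
    KineticParameters,
    MetaboliteTimeSeries,
    ValidationError,
    cost,
    derived_plasma_curve,
    fit,
)
from hyperkin.fitting import FitOptions
from hyperkin.synthetic import generate_timeseries, invitro_input, invitro_kinetics


@pytest.fixture(scope="module")
def invivo_truth():
    return KineticParameters(k_PL=0.02, k_LP=0.01, r_P=0.07, r_L=0.05)


@pytest.fixture(scope="module")
def invivo_bolus():
    return InputFunction.raised_cosine(40.0, 2.0, 5.0)


class TestParameterRecovery:
    def test_noiseless_two_site_recovery(self, invivo_truth, invivo_bolus, invivo_acq):
        ts = generate_timeseries(invivo_truth, invivo_bolus, invivo_acq)
        res = fit(
            ts, "two_site", invivo_acq,
            FitOptions(input_mode="raised_cosine", vary_r_P=True, seed=1),
        )
        assert res.converged
        assert res.params_hat.k_PL == pytest.approx(0.02, rel=0.01)
        assert res.params_hat.k_LP == pytest.approx(0.01, rel=0.05)
        assert res.params_hat.r_L == pytest.approx(0.05, rel=0.05)
        assert all(np.isfinite(v) for v in res.std_errors.values())

    def test_noiseless_three_site_recovery(self, invitro_acq):
        p3 = KineticParameters(
            k_PL=0.02, k_LP=0.01,
            r_P=invitro_acq.effective_rate("pyruvate"),
            r_L=invitro_acq.effective_rate("lactate"),
            k_LE=0.06, k_EL=0.02, model_kind="three_site",
        )
        ts = generate_timeseries(p3, invitro_input(lead_s=6.0), invitro_acq)
        res = fit(ts, "three_site", invitro_acq,
                  FitOptions(cost_scheme="modified", seed=0))
        assert res.converged
        assert res.params_hat.k_PL == pytest.approx(0.02, rel=0.03)

    def test_noisy_recovery_is_unbiased(self, invivo_truth, invivo_bolus, invivo_acq):
        errs = []
        for i in range(10):
            ts = generate_timeseries(
                invivo_truth, invivo_bolus, invivo_acq, noise_sigma=0.01, seed=300 + i
            )
            res = fit(
                ts, "two_site", invivo_acq,
                FitOptions(input_mode="raised_cosine", vary_r_P=True, seed=1,
                           n_starts=4),
            )
            errs.append(res.params_hat.k_PL / 0.02 - 1)
        assert abs(np.median(errs)) < 0.05

    def test_deterministic_given_seed(self, invivo_truth, invivo_bolus, invivo_acq):
        ts = generate_timeseries(
            invivo_truth, invivo_bolus, invivo_acq, noise_sigma=0.01, seed=7
        )
        opts = FitOptions(input_mode="raised_cosine", seed=3, n_starts=4)
        r1 = fit(ts, "two_site", invivo_acq, opts)
        r2 = fit(ts, "two_site", invivo_acq, opts)
        assert r1.params_hat == r2.params_hat

    def test_zero_lactate_is_flagged(self, invivo_acq):
        t = np.arange(64) * 2.0
        ts = MetaboliteTimeSeries(
            t,
            {"pyruvate": 100 * np.exp(-0.05 * t), "lactate_total": np.zeros(64)},
        )
        res = fit(ts, "two_site", invivo_acq)
        assert not res.converged
        assert res.params_hat.k_PL == 0.0


class TestCost:
    def _pair(self):
        t = np.arange(16) * 2.0
        data = MetaboliteTimeSeries(
            t, {"pyruvate": np.exp(-0.05 * t), "lactate_total": 0.3 * np.exp(-0.04 * t)}
        )
        model = MetaboliteTimeSeries(
            t,
            {"pyruvate": np.exp(-0.06 * t), "lactate_total": 0.28 * np.exp(-0.04 * t)},
        )
        return data, model

    def test_perfect_fit_costs_zero(self):
        data, _ = self._pair()
        assert cost(data, data) == 0.0

    def test_quadratic_scaling(self):
        data, model = self._pair()
        base = cost(data, model)
        doubled = MetaboliteTimeSeries(
            data.times_s,
            {lab: data[lab] + 2 * (model[lab] - data[lab]) for lab in data.labels},
        )
        assert cost(data, doubled) == pytest.approx(4 * base, rel=1e-9)

    def test_modified_matches_least_squares_on_equal_scales(self):
        # when every channel has peak 1 the weights are uniform and the
        # two schemes order a toy misfit set identically
        t = np.arange(16) * 2.0
        data = MetaboliteTimeSeries(
            t, {"pyruvate": np.exp(-0.05 * t), "lactate_total": np.exp(-0.04 * t)}
        )
        misfits = []
        for eps in (0.01, 0.03, 0.07):
            misfits.append(
                MetaboliteTimeSeries(
                    t, {lab: data[lab] + eps for lab in data.labels}
                )
            )
        ls = [cost(data, m, "least_squares") for m in misfits]
        mod = [cost(data, m, "modified") for m in misfits]
        assert np.argsort(ls).tolist() == np.argsort(mod).tolist()
        np.testing.assert_allclose(ls, mod, rtol=1e-9)

    def test_mismatched_grids_error(self):
        data, model = self._pair()
        shifted = MetaboliteTimeSeries(
            data.times_s + 1.0, dict(data.signals)
        )
        with pytest.raises(ValidationError):
            cost(data, shifted)


class TestDerivedPlasmaCurve:
    def test_shape_and_integral(self, invivo_truth, invivo_bolus, invivo_acq):
        ts = generate_timeseries(invivo_truth, invivo_bolus, invivo_acq)
        res = fit(
            ts, "two_site", invivo_acq,
            FitOptions(input_mode="raised_cosine", vary_r_P=True, seed=1),
        )
        curve = derived_plasma_curve(res)
        f = res.input_hat
        t_peak = curve.times_s[np.argmax(curve["input"])]
        assert t_peak == pytest.approx(f.onset_s + f.duration_s / 2, abs=ts.dt)
        integral = np.trapezoid(curve["input"], curve.times_s)
        assert integral == pytest.approx(f.amplitude * f.duration_s / 2, rel=0.01)

    def test_in_vitro_fit_has_no_plasma_curve(self, invitro_record, invitro_acq):
        res = fit(invitro_record, "two_site", invitro_acq,
                  FitOptions(input_mode="bolus", seed=0, n_starts=4))
        with pytest.raises(ValidationError):
            derived_plasma_curve(res)


@pytest.fixture(scope="module")
def transport_data(invitro_acq):
    p3 = KineticParameters(
        k_PL=0.03, k_LP=0.015,
        r_P=invitro_acq.effective_rate("pyruvate"),
        r_L=invitro_acq.effective_rate("lactate"),
        k_LE=0.2, k_EL=0.05, model_kind="three_site",
    )
    return generate_timeseries(
        p3, invitro_input(lead_s=6.0), invitro_acq, noise_sigma=3e-5, seed=42
    )


class TestResidualDiagnostics:
    def test_two_site_misfit_leaves_structured_residuals(
        self, transport_data, invitro_acq
    ):
        opts = FitOptions(cost_scheme="modified", seed=0, n_starts=4)
        res2 = fit(transport_data, "two_site", invitro_acq, opts)
        res3 = fit(transport_data, "three_site", invitro_acq, opts)
        dw2 = durbin_watson(res2.residuals["lactate_total"])
        dw3 = durbin_watson(res3.residuals["lactate_total"])
        assert dw2 < 1.0  # strong positive lag-1 autocorrelation
        assert dw3 > dw2 + 0.4  # transport model whitens the residuals

    def test_transport_model_raises_k_PL_estimate(self, transport_data, invitro_acq):
        opts = FitOptions(cost_scheme="modified", seed=0, n_starts=4)
        k2 = fit(transport_data, "two_site", invitro_acq, opts).params_hat.k_PL
        k3 = fit(transport_data, "three_site", invitro_acq, opts).params_hat.k_PL
        assert k3 >= k2


class TestValidation:
    def test_too_few_samples(self, invivo_acq):
        t = np.arange(5) * 2.0
        ts = MetaboliteTimeSeries(
            t, {"pyruvate": np.ones(5), "lactate_total": np.ones(5)}
        )
        with pytest.raises(ValidationError):
            fit(ts, "two_site", invivo_acq)

    def test_missing_alanine_channel(self, invitro_record, invitro_acq):
        with pytest.raises(ValidationError):
            fit(invitro_record, "two_site_alanine", invitro_acq)
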