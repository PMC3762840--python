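"""Forward simulation: analytic oracles, LTI properties, RF modes."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from hyperkin import (
    InputFunction,
    KineticParameters,
    MetaboliteTimeSeries,
    ValidationError,
    relaxation_correct,
    simulate,
)
from hyperkin.simulate import system_matrix

from conftest import decay_horizon


def reldiff(a, b):
    scale = max(np.max(np.abs(a)), np.max(np.abs(b)))
    return np.max(np.abs(a - b)) / scale


class TestTwoSiteOracles:
    def test_no_forward_conversion_gives_zero_lactate(self, raised_cosine_input):
        p = KineticParameters(k_PL=0.0, k_LP=0.01, r_P=0.07, r_L=0.05)
        ts = simulate(p, raised_cosine_input, t_end_s=100.0, dt_s=0.5)
        np.testing.assert_array_equal(ts["lactate_total"], 0.0)

    def test_bolus_biexponential_closed_form(self):
        # delta bolus, k_LP = 0: L(t) = P0 k_PL (e^{-a t} - e^{-b t})/(b - a)
        p = KineticParameters(k_PL=0.02, k_LP=0.0, r_P=0.07, r_L=0.05)
        ts = simulate(p, InputFunction.bolus(2.0, 0.0), t_end_s=300.0, dt_s=0.5)
        a, b = p.r_L, p.r_P + p.k_PL
        t = ts.times_s
        L = 2.0 * p.k_PL * (np.exp(-a * t) - np.exp(-b * t)) / (b - a)
        assert reldiff(ts["lactate_total"], L) < 1e-3
        np.testing.assert_allclose(ts["pyruvate"], 2.0 * np.exp(-b * t), rtol=1e-9)

    @pytest.mark.parametrize("model_kind", ["two_site", "three_site", "two_site_alanine"])
    def test_against_adaptive_integrator(self, model_kind, raised_cosine_input):
        """Independent oracle: generic stiff ODE solver on the same system."""
        kw = dict(k_PL=0.03, k_LP=0.012, r_P=0.06, r_L=0.04, model_kind=model_kind)
        if model_kind == "three_site":
            kw.update(k_LE=0.08, k_EL=0.03)
        if model_kind == "two_site_alanine":
            kw.update(k_PA=0.01, k_AP=0.002, r_A=0.05)
        p = KineticParameters(**kw)
        ts = simulate(p, raised_cosine_input, t_end_s=200.0, dt_s=2.0)

        A, labels = system_matrix(p)

        def rhs(t, x):
            dx = A @ x
            dx[0] += float(raised_cosine_input.evaluate(t))
            return dx

        sol = solve_ivp(
            rhs, (0, 200.0), np.zeros(A.shape[0]), t_eval=ts.times_s,
            rtol=1e-10, atol=1e-13, method="LSODA", max_step=0.5,
        )
        for i, lab in enumerate(labels):
            assert reldiff(ts[lab], sol.y[i]) < 1e-6


class TestLTIProperties:
    def test_linearity_in_input_amplitude(self, two_site_params):
        base = InputFunction.raised_cosine(1.0, 2.0, 10.0)
        ref = simulate(two_site_params, base, 150.0, 1.0)
        for alpha in (0.5, 2.0):
            scaled = InputFunction.raised_cosine(alpha, 2.0, 10.0)
            out = simulate(two_site_params, scaled, 150.0, 1.0)
            for lab in ref.labels:
                assert reldiff(out[lab], alpha * ref[lab]) < 1e-3

    def test_superposition_of_inputs(self, two_site_params):
        # both smooth so that tabulating their sum introduces no bias
        f1 = InputFunction.raised_cosine(1.0, 2.0, 8.0)
        f2 = InputFunction.raised_cosine(0.5, 15.0, 5.0)
        o1 = simulate(two_site_params, f1, 150.0, 1.0)
        o2 = simulate(two_site_params, f2, 150.0, 1.0)
        # piecewise-linear tabulation of f1+f2 on a fine grid
        tt = np.linspace(0.0, 30.0, 3001)
        fsum = InputFunction.from_samples(tt, f1.evaluate(tt) + f2.evaluate(tt))
        osum = simulate(two_site_params, fsum, 150.0, 1.0)
        for lab in o1.labels:
            assert reldiff(osum[lab], o1[lab] + o2[lab]) < 1e-3

    def test_three_site_reduces_to_two_site(self, raised_cosine_input):
        p2 = KineticParameters(k_PL=0.02, k_LP=0.01, r_P=0.07, r_L=0.05)
        p3 = KineticParameters(
            k_PL=0.02, k_LP=0.01, r_P=0.07, r_L=0.05, model_kind="three_site"
        )
        t2 = simulate(p2, raised_cosine_input, 200.0, 1.0)
        t3 = simulate(p3, raised_cosine_input, 200.0, 1.0)
        assert reldiff(t3["lactate_intra"], t2["lactate_total"]) < 1e-3
        assert np.max(np.abs(t3["lactate_extra"])) < 1e-12

    def test_alanine_reduces_to_two_site(self, raised_cosine_input):
        p2 = KineticParameters(k_PL=0.02, k_LP=0.01, r_P=0.07, r_L=0.05)
        pa = KineticParameters(
            k_PL=0.02, k_LP=0.01, r_P=0.07, r_L=0.05, r_A=0.04,
            model_kind="two_site_alanine",
        )
        t2 = simulate(p2, raised_cosine_input, 200.0, 1.0)
        ta = simulate(pa, raised_cosine_input, 200.0, 1.0)
        assert reldiff(ta["lactate_total"], t2["lactate_total"]) < 1e-3
        assert np.max(np.abs(ta["alanine"])) == 0.0

    def test_terminal_decay(self, two_site_params):
        f = InputFunction.raised_cosine(1.0, 2.0, 10.0)
        t_end = 12.0 + decay_horizon(two_site_params, margin=16.0)
        ts = simulate(two_site_params, f, t_end, 1.0)
        for lab in ts.labels:
            peak = ts[lab].max()
            assert ts[lab][-1] < 1e-6 * peak

    def test_grid_refinement_convergence(self, two_site_params, raised_cosine_input):
        coarse = simulate(two_site_params, raised_cosine_input, 150.0, 2.0)
        fine = simulate(two_site_params, raised_cosine_input, 150.0, 1.0)
        for lab in coarse.labels:
            assert reldiff(coarse[lab], fine[lab][::2]) < 1e-3

    def test_signals_nonnegative_and_start_zero(self, two_site_params):
        f = InputFunction.raised_cosine(1.0, 4.0, 6.0)
        ts = simulate(two_site_params, f, 100.0, 0.5)
        pre = ts.times_s < 4.0
        assert np.all(ts["lactate_total"][pre] == 0.0)
        for lab in ts.labels:
            assert np.all(ts[lab] >= 0.0)


class TestValidationAndModes:
    def test_bad_dt_rejected(self, two_site_params, raised_cosine_input):
        with pytest.raises(ValidationError):
            simulate(two_site_params, raised_cosine_input, 100.0, 0.0)

    def test_grid_must_cover_input(self, two_site_params):
        f = InputFunction.raised_cosine(1.0, 0.0, 50.0)
        with pytest.raises(ValidationError):
            simulate(two_site_params, f, 20.0, 1.0)

    def test_discrete_mode_close_to_continuous(self, invitro_acq):
        """The pulsed simulator should roughly track the effective-rate one.

        The continuous form folds -ln(cos theta)/TR into r_i; at a 10 deg
        flip the two conventions differ at the percent level.  We only
        check gross agreement here; the residual difference is a property
        of the approximation, not a defect.
        """
        from hyperkin.synthetic import invitro_kinetics

        kin = invitro_kinetics()
        f = InputFunction.bolus(100.0, -6.0)
        cont = simulate(kin, f, 254.0, 2.0)
        disc = simulate(kin, f, 254.0, 2.0, acq=invitro_acq, rf_mode="discrete")
        assert reldiff(cont["pyruvate"], disc["pyruvate"]) < 0.05


class TestRelaxationCorrect:
    def test_zero_rate_is_identity(self, invitro_record):
        r0 = {lab: 0.0 for lab in invitro_record.labels}
        out = relaxation_correct(invitro_record, r0)
        for lab in invitro_record.labels:
            np.testing.assert_array_equal(out[lab], invitro_record[lab])

    def test_pure_decay_becomes_constant(self):
        t = np.arange(0.0, 100.0, 0.1)
        ts = MetaboliteTimeSeries(t, {"pyruvate": np.exp(-0.05 * t)})
        out = relaxation_correct(ts, {"pyruvate": 0.05})
        np.testing.assert_allclose(out["pyruvate"], 1.0, rtol=5e-3)

    def test_one_way_conversion_accumulates(self):
        # k_LP = 0: corrected lactate must plateau once the input has ended
        p = KineticParameters(k_PL=0.02, k_LP=0.0, r_P=0.07, r_L=0.05)
        f = InputFunction.raised_cosine(1.0, 0.0, 10.0)
        ts = simulate(p, f, 400.0, 0.5)
        out = relaxation_correct(ts, {"pyruvate": 0.07, "lactate_total": 0.05})
        tail = out["lactate_total"][int(0.8 * ts.n):]
        assert np.ptp(tail) / tail.mean() < 0.01

    def test_missing_label_errors(self, invitro_record):
        with pytest.raises(ValidationError):
            relaxation_correct(invitro_record, {"pyruvate": 0.05})
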