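"""Maximum-likelihood kinetic model fitting for metabolite time series.

Under independent Gaussian noise with equal variance per timepoint, the
maximum-likelihood estimate of the rate constants minimises a (weighted)
sum of squared residuals between the data and the forward-simulated model
curves.  Rates are optimised on a log scale (keeping every iterate
positive), with a small multi-start scheme around moment-based initial
guesses for robustness against local minima.

Input-function handling mirrors the two experimental regimes:

* **in vitro** (``input_mode='bolus'``): injection happens outside the
  magnet before acquisition starts, so the input is an instantaneous
  bolus at a fitted lead time before the first sample, and the fit
  interpolates the missing early curve back to the injection.
* **in vivo** (``input_mode='raised_cosine'``): the arterial delivery is
  co-estimated as a raised-cosine bolus (amplitude, onset, duration).
* ``input_mode='fixed'``: a known input function is supplied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import ConvergenceError, ValidationError
from .models import (
    LABEL_ALANINE,
    LABEL_LACTATE,
    LABEL_PYRUVATE,
    AcquisitionParameters,
    InputFunction,
    KineticParameters,
    MetaboliteTimeSeries,
)
from .simulate import simulate

__all__ = ["FitOptions", "FitResult", "fit", "cost", "derived_plasma_curve"]

_LOG_RATE_LO, _LOG_RATE_HI = math.log(1e-6), math.log(10.0)


@dataclass
class FitOptions:
    """Tunable settings for :func:`fit`.

    Attributes
    ----------
    input_mode:
        ``'bolus'`` (in vitro; default), ``'raised_cosine'`` (in vivo
        co-estimation) or ``'fixed'`` (known ``input_function``).
    input_function:
        Required when ``input_mode='fixed'``.
    vary_r_L, vary_r_P:
        Whether the effective relaxation rates are free parameters.  By
        default ``r_L`` is fitted (it sits in the AUC-ratio denominator)
        while ``r_P`` is fixed from the acquisition T1 + RF loss, since it
        trades off against the input shape.
    cost_scheme:
        ``'least_squares'`` (uniform weights) or ``'modified'``
        (channel-scale-normalised weights, see :func:`cost`).
    n_starts:
        Number of optimiser starts (first is the heuristic guess).
    seed:
        Seed for the multi-start perturbations.
    """

    input_mode: str = "bolus"
    input_function: InputFunction | None = None
    vary_r_L: bool = True
    vary_r_P: bool = False
    vary_k_AP: bool = False
    cost_scheme: str = "least_squares"
    n_starts: int = 8
    seed: int = 0
    max_lead_s: float = 60.0

    def __post_init__(self) -> None:
        if self.input_mode not in ("bolus", "raised_cosine", "fixed"):
            raise ValidationError(f"unknown input_mode {self.input_mode!r}")
        if self.input_mode == "fixed" and self.input_function is None:
            raise ValidationError("input_mode='fixed' requires input_function")
        if self.cost_scheme not in ("least_squares", "modified"):
            raise ValidationError(f"unknown cost_scheme {self.cost_scheme!r}")
        if self.n_starts < 1:
            raise ValidationError("n_starts must be >= 1")


@dataclass
class FitResult:
    """Outcome of a kinetic model fit."""

    params_hat: KineticParameters
    input_hat: InputFunction | None
    std_errors: dict[str, float]
    fitted_curves: MetaboliteTimeSeries
    residuals: MetaboliteTimeSeries
    objective_value: float
    converged: bool
    model_kind: str
    n_obs: int = 0
    message: str = ""


def cost(
    data: MetaboliteTimeSeries,
    model_curves: MetaboliteTimeSeries,
    scheme: str = "least_squares",
) -> float:
    """Weighted sum of squared residuals between data and model curves.

    ``least_squares`` uses unit weights (plain SSR; the ML objective for
    equal-variance Gaussian noise).  ``modified`` normalises each
    metabolite channel by its peak absolute data value, so that the
    low-amplitude lactate (and alanine) channels are not swamped by the
    pyruvate channel — the scheme used for in vitro records.  With
    channels of equal scale the two orderings coincide.
    """
    if data.n != model_curves.n or not np.allclose(
        data.times_s, model_curves.times_s, rtol=1e-9, atol=1e-9
    ):
        raise ValidationError("data and model curves must share one time grid")
    labels = [lab for lab in data.labels if lab in model_curves]
    if not labels:
        raise ValidationError("no shared metabolite labels between data and model")
    total = 0.0
    for lab in labels:
        w = 1.0
        if scheme == "modified":
            peak = np.max(np.abs(data[lab]))
            w = 1.0 / peak if peak > 0 else 1.0
        elif scheme != "least_squares":
            raise ValidationError(f"unknown cost scheme {scheme!r}")
        total += float(np.sum((w * (data[lab] - model_curves[lab])) ** 2))
    return total


# ---------------------------------------------------------------------------
# parameter vector plumbing


class _ParamSpec:
    """Maps between the optimiser vector and model/input parameters."""

    def __init__(self, model_kind, acq, options, data):
        self.model_kind = model_kind
        self.acq = acq
        self.options = options
        self.t_max = float(data.times_s[-1] - data.times_s[0])
        self.names: list[str] = []
        self.transforms: list[str] = []  # 'log' | 'lin'
        self.lo: list[float] = []
        self.hi: list[float] = []

        rate_names = ["k_PL", "k_LP"]
        if model_kind == "three_site":
            rate_names += ["k_LE", "k_EL"]
        if model_kind == "two_site_alanine":
            rate_names += ["k_PA"] + (["k_AP"] if options.vary_k_AP else [])
        if options.vary_r_L:
            rate_names.append("r_L")
        if options.vary_r_P:
            rate_names.append("r_P")
        for nm in rate_names:
            self._add(nm, "log", _LOG_RATE_LO, _LOG_RATE_HI)

        if options.input_mode == "bolus":
            self._add("bolus_amplitude", "log", math.log(1e-12), math.log(1e12))
            self._add("bolus_lead_s", "lin", 0.0, options.max_lead_s)
        elif options.input_mode == "raised_cosine":
            self._add("input_amplitude", "log", math.log(1e-12), math.log(1e12))
            self._add("input_onset_s", "lin", 0.0, 0.35 * self.t_max)
            self._add("input_duration_s", "log", math.log(0.5), math.log(0.5 * self.t_max))

    def _add(self, name, transform, lo, hi):
        self.names.append(name)
        self.transforms.append(transform)
        self.lo.append(lo)
        self.hi.append(hi)

    @property
    def n(self) -> int:
        return len(self.names)

    def encode(self, natural: dict[str, float]) -> np.ndarray:
        x = np.empty(self.n)
        for i, (nm, tr) in enumerate(zip(self.names, self.transforms)):
            v = natural[nm]
            x[i] = math.log(max(v, 1e-300)) if tr == "log" else v
            x[i] = min(max(x[i], self.lo[i]), self.hi[i])
        return x

    def decode(self, x: np.ndarray) -> dict[str, float]:
        out = {}
        for i, (nm, tr) in enumerate(zip(self.names, self.transforms)):
            out[nm] = math.exp(x[i]) if tr == "log" else float(x[i])
        return out

    def build(self, x: np.ndarray):
        """Natural-space kinetic parameters + input function from vector x."""
        v = self.decode(x)
        fixed = {
            "r_P": self.acq.effective_rate("pyruvate"),
            "r_L": self.acq.effective_rate("lactate"),
            "r_A": self.acq.effective_rate("alanine")
            if self.model_kind == "two_site_alanine"
            else 0.0,
        }
        kw = dict(model_kind=self.model_kind, **fixed)
        for nm in ("k_PL", "k_LP", "k_LE", "k_EL", "k_PA", "k_AP", "r_L", "r_P"):
            if nm in v:
                kw[nm] = v[nm]
        kw.setdefault("k_PL", 0.0)
        params = KineticParameters(**kw)
        if self.options.input_mode == "bolus":
            input_fn = InputFunction.bolus(v["bolus_amplitude"], onset_s=-v["bolus_lead_s"])
        elif self.options.input_mode == "raised_cosine":
            input_fn = InputFunction.raised_cosine(
                v["input_amplitude"], v["input_onset_s"], v["input_duration_s"]
            )
        else:
            input_fn = self.options.input_function
        return params, input_fn


def _initial_guess(spec: _ParamSpec, data, acq, options) -> dict[str, float]:
    P = data[LABEL_PYRUVATE]
    L = data[LABEL_LACTATE]
    dt = data.dt
    r_L0 = acq.effective_rate("lactate")
    r_P0 = acq.effective_rate("pyruvate")
    sumP = float(np.sum(P))
    ratio0 = float(np.sum(L)) / sumP if sumP > 0 else 0.3
    k_LP0 = 0.01
    k_PL0 = float(np.clip(ratio0 * (r_L0 + k_LP0), 1e-4, 0.5))
    lam_P0 = r_P0 + k_PL0
    guess = {
        "k_PL": k_PL0,
        "k_LP": k_LP0,
        "k_LE": 0.02,
        "k_EL": 0.01,
        "k_PA": 0.005,
        "k_AP": 1e-3,
        "r_L": r_L0,
        "r_P": r_P0,
    }
    if LABEL_ALANINE in data and sumP > 0:
        r_A0 = acq.effective_rate("alanine")
        guess["k_PA"] = float(
            np.clip(np.sum(data[LABEL_ALANINE]) / sumP * r_A0, 1e-4, 0.2)
        )
    if options.input_mode == "bolus":
        lead0 = 5.0
        p_start = P[0] if P[0] > 0 else max(np.max(P), 1.0)
        guess["bolus_amplitude"] = float(p_start * math.exp(lam_P0 * lead0))
        guess["bolus_lead_s"] = lead0
    elif options.input_mode == "raised_cosine":
        dur0 = min(6.0, 0.4 * spec.t_max)
        total_in = max(sumP * dt * lam_P0, 1e-6)
        guess["input_amplitude"] = 2.0 * total_in / dur0
        t_peak = float(data.times_s[int(np.argmax(P))] - data.times_s[0])
        guess["input_onset_s"] = float(np.clip(t_peak - dur0, 0.0, 0.3 * spec.t_max))
        guess["input_duration_s"] = dur0
    return guess


def fit(
    data: MetaboliteTimeSeries,
    model_kind: str,
    acq: AcquisitionParameters,
    options: FitOptions | None = None,
) -> FitResult:
    """Maximum-likelihood fit of an exchange model to metabolite curves.

    Parameters
    ----------
    data:
        Uniformly sampled series containing ``pyruvate`` and
        ``lactate_total`` (plus ``alanine`` for the alanine-extended
        model); at least 10 samples.
    model_kind:
        ``'two_site'``, ``'three_site'`` or ``'two_site_alanine'``.
    acq:
        Supplies the fixed effective relaxation rates (T1 + RF loss) for
        any relaxation parameter not being fitted.
    options:
        See :class:`FitOptions`.

    Notes
    -----
    The fit is deterministic for a fixed ``options.seed``.  A record with
    an identically zero lactate channel is non-identifiable and returns a
    flagged (non-converged) result rather than arbitrary numbers.
    """
    options = options or FitOptions()
    if data.n < 10:
        raise ValidationError("need at least 10 samples to fit")
    needed = [LABEL_PYRUVATE, LABEL_LACTATE]
    if model_kind == "two_site_alanine":
        needed.append(LABEL_ALANINE)
    for lab in needed:
        if lab not in data:
            raise ValidationError(f"fit requires label {lab!r} in the data")
    dt = data.dt  # validates uniformity

    times0 = data.times_s - data.times_s[0]
    channels = needed
    weights = {}
    for lab in channels:
        if options.cost_scheme == "modified":
            peak = np.max(np.abs(data[lab]))
            weights[lab] = 1.0 / peak if peak > 0 else 1.0
        else:
            weights[lab] = 1.0

    spec = _ParamSpec(model_kind, acq, options, data)

    if np.max(np.abs(data[LABEL_LACTATE])) <= 1e-12 * max(np.max(np.abs(data[LABEL_PYRUVATE])), 1e-300):
        return _degenerate_result(data, model_kind, acq, spec, options)

    y = np.concatenate([weights[lab] * data[lab] for lab in channels])
    t_end = float(times0[-1])

    def model_series(x) -> MetaboliteTimeSeries:
        params, input_fn = spec.build(x)
        return simulate(params, input_fn, t_end_s=t_end, dt_s=dt)

    def residual(x):
        try:
            sim = model_series(x)
        except (ValidationError, FloatingPointError):
            return np.full(y.size, 1e6)
        return np.concatenate([weights[lab] * sim[lab] for lab in channels]) - y

    guess = _initial_guess(spec, data, acq, options)
    x0 = spec.encode(guess)
    rng = np.random.default_rng(options.seed)
    starts = [x0]
    for _ in range(options.n_starts - 1):
        pert = x0.copy()
        for i, tr in enumerate(spec.transforms):
            if tr == "log":
                pert[i] += rng.normal(0.0, 0.5)
            else:
                width = spec.hi[i] - spec.lo[i]
                pert[i] += rng.uniform(-0.15, 0.15) * width
        starts.append(np.clip(pert, spec.lo, spec.hi))

    best = None
    for x_start in starts:
        res = least_squares(
            residual,
            x_start,
            bounds=(spec.lo, spec.hi),
            method="trf",
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-10,
            max_nfev=400 * spec.n,
        )
        if best is None or res.cost < best.cost:
            best = res

    params_hat, input_hat = spec.build(best.x)
    fitted = model_series(best.x)
    fitted = MetaboliteTimeSeries(
        data.times_s.copy(), {lab: fitted[lab] for lab in fitted.labels}
    )
    residual_ts = MetaboliteTimeSeries(
        data.times_s.copy(),
        {lab: data[lab] - fitted[lab] for lab in channels},
    )
    objective = 2.0 * best.cost  # least_squares cost = 0.5 * SSR
    std_errors = _std_errors(best, spec)
    converged = bool(best.success) and all(np.isfinite(list(std_errors.values())))
    return FitResult(
        params_hat=params_hat,
        input_hat=None if options.input_mode == "bolus" else input_hat,
        std_errors=std_errors,
        fitted_curves=fitted,
        residuals=residual_ts,
        objective_value=objective,
        converged=converged,
        model_kind=model_kind,
        n_obs=y.size,
        message=best.message,
    )


def _std_errors(res, spec: _ParamSpec) -> dict[str, float]:
    """Gauss-Newton standard errors, propagated to natural units."""
    m, p = res.fun.size, spec.n
    values = spec.decode(res.x)
    if m <= p:
        return {nm: float("inf") for nm in spec.names}
    s2 = 2.0 * res.cost / (m - p)
    try:
        cov = s2 * np.linalg.pinv(res.jac.T @ res.jac)
        diag = np.clip(np.diag(cov), 0.0, None)
    except np.linalg.LinAlgError:  # pragma: no cover
        return {nm: float("inf") for nm in spec.names}
    out = {}
    for i, (nm, tr) in enumerate(zip(spec.names, spec.transforms)):
        se = math.sqrt(diag[i])
        out[nm] = values[nm] * se if tr == "log" else se
    return out


def _degenerate_result(data, model_kind, acq, spec, options):
    """All-zero lactate: k_PL is unidentifiable; return a flagged result."""
    params = KineticParameters(
        k_PL=0.0,
        k_LP=0.0,
        r_P=acq.effective_rate("pyruvate"),
        r_L=acq.effective_rate("lactate"),
        r_A=acq.effective_rate("alanine") if model_kind == "two_site_alanine" else 0.0,
        model_kind=model_kind,
    )
    zeros = {lab: np.zeros(data.n) for lab in data.labels}
    flat = MetaboliteTimeSeries(data.times_s.copy(), zeros)
    resid = MetaboliteTimeSeries(
        data.times_s.copy(), {lab: data[lab].copy() for lab in data.labels}
    )
    return FitResult(
        params_hat=params,
        input_hat=None,
        std_errors={nm: float("inf") for nm in spec.names},
        fitted_curves=flat,
        residuals=resid,
        objective_value=float(sum(np.sum(v**2) for v in data.signals.values())),
        converged=False,
        model_kind=model_kind,
        n_obs=data.n,
        message="lactate channel is identically zero; k_PL not identifiable",
    )


def derived_plasma_curve(fit_result: FitResult) -> MetaboliteTimeSeries:
    """Fitted parametric input (plasma pyruvate delivery) on the data grid.

    Only available for in vivo fits that co-estimated a parametric input;
    in vitro bolus fits carry no input model and raise.
    """
    f = fit_result.input_hat
    if f is None or f.shape == "instantaneous_bolus":
        raise ValidationError(
            "fit has no parametric input model (in vitro mode); "
            "no plasma curve can be derived"
        )
    t = fit_result.fitted_curves.times_s
    return MetaboliteTimeSeries(t.copy(), {"input": f.evaluate(t - t[0])})
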