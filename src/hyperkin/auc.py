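"""Model-free AUC-ratio analysis and its closed-form model predictions.

The central identity: for first-order exchange with effective lactate
relaxation ``r_L``, the ratio of the total areas under the lactate and
pyruvate signal curves equals

    AUC(L) / AUC(P) = k_PL / (r_L + gamma * k_LP)

where ``gamma = (k_EL + r_L) / (k_LE + k_EL + r_L)`` accounts for
MCT-mediated lactate membrane transport (``gamma = 1`` without transport,
recovering the 2-site form ``k_PL / (r_L + k_LP)``).  The identity follows
from the lactate rate equation alone, so the ratio is independent of the
input function, of the pyruvate relaxation rate, and of any side pathway
draining pyruvate (e.g. alanine).  It makes the plain ratio of summed peak
areas a model-free surrogate for the forward rate constant k_PL.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConvergenceError, UndefinedRatioError, ValidationError
from .models import LABEL_LACTATE, LABEL_PYRUVATE, KineticParameters, MetaboliteTimeSeries

__all__ = [
    "AucResult",
    "auc_ratio",
    "predicted_ratio_two_site",
    "predicted_ratio_three_site",
    "predicted_ratio",
    "gamma_factor",
    "truncation_corrected_ratio",
]


@dataclass(frozen=True)
class AucResult:
    """Summed-signal areas and their lactate/pyruvate ratio.

    ``auc_by_label`` holds plain sample sums (arbitrary units x samples);
    the common factor dt cancels in ``ratio``.
    """

    auc_by_label: dict[str, float]
    ratio: float
    n_samples_used: int
    truncated_prefix: int = 0


def auc_ratio(
    ts: MetaboliteTimeSeries,
    numerator: str = LABEL_LACTATE,
    denominator: str = LABEL_PYRUVATE,
    method: str = "sum",
    truncated_prefix: int = 0,
) -> AucResult:
    """Discrete AUC ratio of two metabolite curves.

    With uniformly sampled data the AUC integral is approximated by the
    plain sum of samples (``method='sum'``; the spacing cancels in the
    ratio).  Non-uniform grids must use ``method='trapezoid'``.

    Raises
    ------
    UndefinedRatioError
        If the denominator metabolite sums to zero.
    ValidationError
        If a required label is absent, or the grid is non-uniform while
        ``method='sum'``.
    """
    for label in (numerator, denominator):
        if label not in ts:
            raise ValidationError(
                f"time series lacks required label {label!r}; has {list(ts.labels)}"
            )
    if method == "sum":
        if not ts.is_uniform():
            raise ValidationError(
                "plain-sum AUC requires a uniform time grid; use method='trapezoid'"
            )
        aucs = {lab: float(np.sum(sig)) for lab, sig in ts.signals.items()}
    elif method == "trapezoid":
        aucs = {
            lab: float(np.trapezoid(sig, ts.times_s)) for lab, sig in ts.signals.items()
        }
    else:
        raise ValidationError(f"unknown AUC method {method!r}")
    denom = aucs[denominator]
    if denom <= 0:
        raise UndefinedRatioError(
            f"AUC of {denominator!r} is {denom}; ratio undefined"
        )
    return AucResult(
        auc_by_label=aucs,
        ratio=aucs[numerator] / denom,
        n_samples_used=ts.n,
        truncated_prefix=truncated_prefix,
    )


def predicted_ratio_two_site(p: KineticParameters) -> float:
    """Closed-form AUC ratio of the 2-site model: ``k_PL / (r_L + k_LP)``.

    Reduces to ``k_PL / r_L`` for a one-way reaction (``k_LP = 0``).
    """
    denom = p.r_L + p.k_LP
    if denom <= 0:
        raise UndefinedRatioError("r_L + k_LP must be > 0 for a finite AUC ratio")
    return p.k_PL / denom


def gamma_factor(k_LE: float, k_EL: float, r_L: float) -> float:
    """Transport attenuation factor ``(k_EL + r_L) / (k_LE + k_EL + r_L)``.

    Lies in (0, 1]; equals 1 exactly when there is no lactate transport
    (``k_LE = k_EL = 0``), and tends to 0 as efflux dominates.
    """
    for name, v in (("k_LE", k_LE), ("k_EL", k_EL), ("r_L", r_L)):
        if v < 0:
            raise ValidationError(f"{name} must be >= 0 (got {v})")
    denom = k_LE + k_EL + r_L
    if denom <= 0:
        raise UndefinedRatioError("k_LE + k_EL + r_L must be > 0")
    return (k_EL + r_L) / denom


def predicted_ratio_three_site(p: KineticParameters) -> float:
    """Closed-form total-lactate AUC ratio of the 3-site model.

    ``k_PL / (r_L + gamma * k_LP)``; with zero transport gamma = 1 and the
    2-site expression is recovered exactly.
    """
    g = gamma_factor(p.k_LE, p.k_EL, p.r_L)
    denom = p.r_L + g * p.k_LP
    if denom <= 0:
        raise UndefinedRatioError("r_L + gamma * k_LP must be > 0")
    return p.k_PL / denom


def predicted_ratio(p: KineticParameters) -> float:
    """Model-appropriate closed-form AUC ratio for ``p.model_kind``.

    The alanine branch only drains pyruvate, so the alanine-extended model
    shares the 2-site lactate/pyruvate expression.
    """
    if p.model_kind == "three_site":
        return predicted_ratio_three_site(p)
    return predicted_ratio_two_site(p)


def truncation_corrected_ratio(fit) -> float:
    """Model-derived AUC ratio evaluated at fitted parameters.

    Records that miss their first samples (injection before acquisition)
    bias the raw sum ratio, because the early bolus-era pyruvate area is
    lost; the closed-form ratio at the fitted rate constants refers to the
    complete curves and therefore corrects for the missing points.

    Parameters
    ----------
    fit:
        A converged :class:`~hyperkin.fitting.FitResult`.
    """
    if not fit.converged:
        raise ConvergenceError("cannot derive a corrected ratio from a failed fit")
    return predicted_ratio(fit.params_hat)
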