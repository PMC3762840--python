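"""Domain types for hyperpolarized [1-13C]pyruvate exchange kinetics.

The hyperpolarized magnetization created by dissolution DNP is a
non-renewable pool: every metabolite signal decays with an *effective*
relaxation rate ``r_i`` that combines intrinsic T1 decay with the loss
caused by repeated RF excitation at flip angle ``theta`` every repetition
time TR.  The types here describe an acquisition, the first-order exchange
network (pyruvate <-> lactate, optional lactate membrane transport and an
alanine side branch), the pyruvate delivery (input) function ``P_in(t)``,
and sampled metabolite signal curves on a uniform time grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ValidationError

__all__ = [
    "MODEL_KINDS",
    "LABEL_PYRUVATE",
    "LABEL_LACTATE",
    "LABEL_LACTATE_INTRA",
    "LABEL_LACTATE_EXTRA",
    "LABEL_ALANINE",
    "AcquisitionParameters",
    "KineticParameters",
    "InputFunction",
    "MetaboliteTimeSeries",
    "effective_relaxation",
]

MODEL_KINDS = ("two_site", "three_site", "two_site_alanine")

LABEL_PYRUVATE = "pyruvate"
LABEL_LACTATE = "lactate_total"
LABEL_LACTATE_INTRA = "lactate_intra"
LABEL_LACTATE_EXTRA = "lactate_extra"
LABEL_ALANINE = "alanine"

#: Canonical metabolite labels accepted in time-series containers.
CANONICAL_LABELS = (
    LABEL_PYRUVATE,
    LABEL_LACTATE,
    LABEL_LACTATE_INTRA,
    LABEL_LACTATE_EXTRA,
    LABEL_ALANINE,
)

#: Common synonyms normalised on file input.
LABEL_SYNONYMS = {
    "p": LABEL_PYRUVATE,
    "pyr": LABEL_PYRUVATE,
    "pyruvate": LABEL_PYRUVATE,
    "l": LABEL_LACTATE,
    "lac": LABEL_LACTATE,
    "lactate": LABEL_LACTATE,
    "lactate_total": LABEL_LACTATE,
    "l_i": LABEL_LACTATE_INTRA,
    "lactate_intra": LABEL_LACTATE_INTRA,
    "l_e": LABEL_LACTATE_EXTRA,
    "lactate_extra": LABEL_LACTATE_EXTRA,
    "a": LABEL_ALANINE,
    "ala": LABEL_ALANINE,
    "alanine": LABEL_ALANINE,
    "pyruvate_hydrate": "pyruvate_hydrate",
}


def effective_relaxation(
    t1_s: float, flip_angle_deg: float, repetition_time_s: float
) -> float:
    """Effective decay rate (/s) of a hyperpolarized signal under sampling.

    Combines intrinsic longitudinal relaxation with the polarization spent
    by RF excitation, in the continuous-loss approximation

        r = 1/T1 - ln(cos theta) / TR

    which treats the per-pulse survival factor ``cos theta`` as a smooth
    exponential loss.  Valid for 0 <= theta < 90 degrees.

    Parameters
    ----------
    t1_s:
        Intrinsic T1 of the resonance, seconds (> 0; ``inf`` allowed).
    flip_angle_deg:
        Excitation flip angle theta in degrees.
    repetition_time_s:
        Repetition time TR between excitations, seconds.
    """
    if not (0 <= flip_angle_deg < 90):
        raise ValidationError(
            f"flip angle must satisfy 0 <= theta < 90 deg (got {flip_angle_deg}); "
            "cos(theta) <= 0 breaks the RF-loss model"
        )
    if not t1_s > 0:
        raise ValidationError(f"T1 must be positive (got {t1_s})")
    if not repetition_time_s > 0:
        raise ValidationError(f"TR must be positive (got {repetition_time_s})")
    return 1.0 / t1_s - math.log(math.cos(math.radians(flip_angle_deg))) / repetition_time_s


@dataclass(frozen=True)
class AcquisitionParameters:
    """Pulse-and-acquire acquisition settings and intrinsic T1s.

    Attributes
    ----------
    flip_angle_deg:
        Excitation angle theta, degrees; 0 <= theta < 90.
    repetition_time_s:
        TR between spectra, seconds.
    n_timepoints:
        Number of dynamic spectra acquired (>= 2).
    t1_pyruvate_s, t1_lactate_s, t1_alanine_s:
        Intrinsic T1 per metabolite, seconds.
    """

    flip_angle_deg: float
    repetition_time_s: float
    n_timepoints: int
    t1_pyruvate_s: float
    t1_lactate_s: float
    t1_alanine_s: float = 30.0

    def __post_init__(self) -> None:
        if not (0 <= self.flip_angle_deg < 90):
            raise ValidationError(
                f"flip_angle_deg must be in [0, 90) (got {self.flip_angle_deg})"
            )
        if not self.repetition_time_s > 0:
            raise ValidationError("repetition_time_s must be > 0")
        if self.n_timepoints < 2:
            raise ValidationError("n_timepoints must be >= 2")
        for name in ("t1_pyruvate_s", "t1_lactate_s", "t1_alanine_s"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0")

    @property
    def duration_s(self) -> float:
        return self.n_timepoints * self.repetition_time_s

    def effective_rate(self, metabolite: str) -> float:
        """RF-loss-corrected effective relaxation rate for one metabolite."""
        t1 = {
            "pyruvate": self.t1_pyruvate_s,
            "lactate": self.t1_lactate_s,
            "alanine": self.t1_alanine_s,
        }[metabolite]
        return effective_relaxation(t1, self.flip_angle_deg, self.repetition_time_s)


@dataclass(frozen=True)
class KineticParameters:
    """Rate constants of one first-order exchange model.

    All rates in /s.  ``k_PL``/``k_LP`` are the apparent forward/reverse
    pyruvate<->lactate exchange constants (LDH activity); ``k_LE``/``k_EL``
    the MCT-mediated lactate efflux/influx across the cell membrane (3-site
    model only); ``k_PA``/``k_AP`` the alanine branch (ALT).  ``r_P``,
    ``r_L``, ``r_A`` are *effective* relaxation rates of the observed
    signals; intracellular and extracellular lactate share the single
    ``r_L``.
    """

    k_PL: float
    k_LP: float = 0.0
    r_P: float = 0.0
    r_L: float = 0.0
    k_LE: float = 0.0
    k_EL: float = 0.0
    k_PA: float = 0.0
    k_AP: float = 0.0
    r_A: float = 0.0
    model_kind: str = "two_site"

    def __post_init__(self) -> None:
        if self.model_kind not in MODEL_KINDS:
            raise ValidationError(
                f"model_kind must be one of {MODEL_KINDS} (got {self.model_kind!r})"
            )
        for name in ("k_PL", "k_LP", "r_P", "r_L", "k_LE", "k_EL", "k_PA", "k_AP", "r_A"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValidationError(f"{name} must be finite and >= 0 (got {v})")
        if self.model_kind == "two_site" and (self.k_LE or self.k_EL):
            raise ValidationError("two_site model forces k_LE = k_EL = 0")
        if self.model_kind != "two_site_alanine" and (self.k_PA or self.k_AP):
            raise ValidationError("alanine rates require model_kind='two_site_alanine'")

    def with_rates(self, **rates: float) -> "KineticParameters":
        """Return a copy with some rates replaced."""
        return replace(self, **rates)


@dataclass(frozen=True)
class InputFunction:
    """Parametric pyruvate delivery curve ``P_in(t)`` (signal/s).

    Shapes
    ------
    ``raised_cosine``
        ``A * (1 - cos(2*pi*(t-onset)/duration)) / 2`` on
        [onset, onset+duration], zero outside.  Models the smooth in vivo
        bolus (tail-vein injection over ~5 s).
    ``rectangular``
        Constant ``A`` on [onset, onset+duration].
    ``instantaneous_bolus``
        A delta function delivering total signal ``amplitude`` at
        ``onset_s`` (may be negative, i.e. before the acquisition grid
        starts, for the in vitro injection-outside-the-magnet regime).
        ``evaluate`` returns 0 almost everywhere; simulators treat it as a
        state jump.
    ``sampled``
        Piecewise-linear interpolation of ``samples`` (two-column array of
        time/value pairs), zero outside their range.
    """

    shape: str
    amplitude: float = 1.0
    onset_s: float = 0.0
    duration_s: float = 0.0
    samples: np.ndarray | None = None

    _SHAPES = ("raised_cosine", "rectangular", "instantaneous_bolus", "sampled")

    def __post_init__(self) -> None:
        if self.shape not in self._SHAPES:
            raise ValidationError(f"unknown input shape {self.shape!r}")
        if self.amplitude < 0:
            raise ValidationError("amplitude must be >= 0")
        if self.shape in ("raised_cosine", "rectangular") and not self.duration_s > 0:
            raise ValidationError(f"{self.shape} input requires duration_s > 0")
        if self.shape == "sampled":
            arr = np.asarray(self.samples, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
                raise ValidationError("sampled input needs an (n, 2) array of (t, value)")
            if np.any(np.diff(arr[:, 0]) <= 0):
                raise ValidationError("sampled input times must be strictly increasing")
            if np.any(arr[:, 1] < 0):
                raise ValidationError("input function must be nonnegative")
            object.__setattr__(self, "samples", arr)

    # -- constructors -------------------------------------------------
    @classmethod
    def raised_cosine(cls, amplitude: float, onset_s: float = 0.0, duration_s: float = 5.0):
        return cls("raised_cosine", amplitude, onset_s, duration_s)

    @classmethod
    def rectangular(cls, amplitude: float, onset_s: float = 0.0, duration_s: float = 5.0):
        return cls("rectangular", amplitude, onset_s, duration_s)

    @classmethod
    def bolus(cls, amplitude: float, onset_s: float = 0.0):
        return cls("instantaneous_bolus", amplitude, onset_s)

    @classmethod
    def from_samples(cls, times_s, values):
        return cls("sampled", samples=np.column_stack([times_s, values]))

    # -- evaluation ---------------------------------------------------
    @property
    def end_s(self) -> float:
        if self.shape == "sampled":
            return float(self.samples[-1, 0])
        if self.shape == "instantaneous_bolus":
            return self.onset_s
        return self.onset_s + self.duration_s

    def evaluate(self, t) -> np.ndarray:
        """P_in at time(s) ``t``; vectorized; zero outside the support."""
        t = np.asarray(t, dtype=float)
        if not np.all(np.isfinite(t)):
            raise ValidationError("evaluation time must be finite")
        if self.shape == "instantaneous_bolus":
            return np.zeros_like(t)
        if self.shape == "sampled":
            ts, vs = self.samples[:, 0], self.samples[:, 1]
            return np.interp(t, ts, vs, left=0.0, right=0.0)
        inside = (t >= self.onset_s) & (t <= self.onset_s + self.duration_s)
        if self.shape == "rectangular":
            return np.where(inside, self.amplitude, 0.0)
        phase = 2.0 * np.pi * (t - self.onset_s) / self.duration_s
        return np.where(inside, self.amplitude * (1.0 - np.cos(phase)) / 2.0, 0.0)

    __call__ = evaluate

    def integral(self) -> float:
        """Total delivered signal, closed form where available."""
        if self.shape == "instantaneous_bolus":
            return self.amplitude
        if self.shape == "rectangular":
            return self.amplitude * self.duration_s
        if self.shape == "raised_cosine":
            return self.amplitude * self.duration_s / 2.0
        return float(np.trapezoid(self.samples[:, 1], self.samples[:, 0]))


class MetaboliteTimeSeries:
    """Sampled metabolite signal curves on a shared time grid.

    Parameters
    ----------
    times_s:
        Strictly increasing sample times, seconds.  Most operations assume
        (and check for) uniform spacing.
    signals:
        Mapping of metabolite label -> signal array (same length as
        ``times_s``), arbitrary units.
    """

    def __init__(self, times_s, signals: dict[str, np.ndarray]):
        times = np.asarray(times_s, dtype=float)
        if times.ndim != 1 or times.size < 2:
            raise ValidationError("need a 1-D time grid with >= 2 samples")
        if not np.all(np.isfinite(times)):
            raise ValidationError("time grid contains non-finite values")
        if np.any(np.diff(times) <= 0):
            raise ValidationError("time grid must be strictly increasing")
        sig = {}
        for label, values in signals.items():
            arr = np.asarray(values, dtype=float)
            if arr.shape != times.shape:
                raise ValidationError(
                    f"signal {label!r} length {arr.size} != grid length {times.size}"
                )
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"signal {label!r} contains non-finite values")
            sig[label] = arr
        self.times_s = times
        self.signals = sig

    # -- grid ---------------------------------------------------------
    @property
    def n(self) -> int:
        return self.times_s.size

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.signals)

    def is_uniform(self, rtol: float = 1e-6) -> bool:
        d = np.diff(self.times_s)
        return bool(np.all(np.abs(d - d[0]) <= rtol * abs(d[0])))

    @property
    def dt(self) -> float:
        """Uniform sample spacing; raises on a non-uniform grid."""
        if not self.is_uniform():
            raise ValidationError("time grid is not uniform")
        return float(self.times_s[1] - self.times_s[0])

    # -- access -------------------------------------------------------
    def __getitem__(self, label: str) -> np.ndarray:
        try:
            return self.signals[label]
        except KeyError:
            raise KeyError(f"no signal {label!r}; have {sorted(self.signals)}") from None

    def __contains__(self, label: str) -> bool:
        return label in self.signals

    def copy(self) -> "MetaboliteTimeSeries":
        return MetaboliteTimeSeries(
            self.times_s.copy(), {k: v.copy() for k, v in self.signals.items()}
        )

    def truncate(self, n_first: int) -> "MetaboliteTimeSeries":
        """Drop the first ``n_first`` samples and restart time at zero."""
        if not 0 <= n_first < self.n - 1:
            raise ValidationError(
                f"cannot drop {n_first} of {self.n} samples (need >= 2 left)"
            )
        t = self.times_s[n_first:]
        return MetaboliteTimeSeries(
            t - t[0], {k: v[n_first:].copy() for k, v in self.signals.items()}
        )

    def to_frame(self):
        import pandas as pd

        data = {"time_s": self.times_s}
        data.update(self.signals)
        return pd.DataFrame(data)

    def __repr__(self) -> str:
        return (
            f"MetaboliteTimeSeries(n={self.n}, "
            f"t=[{self.times_s[0]:g}, {self.times_s[-1]:g}] s, "
            f"labels={list(self.signals)})"
        )
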