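"""Exception hierarchy shared across hyperkin modules."""


class HyperkinError(Exception):
    """Base class for all hyperkin errors."""


class ValidationError(HyperkinError, ValueError):
    """Invalid input data, parameters, or configuration (CLI exit code 2)."""


class UndefinedRatioError(HyperkinError, ZeroDivisionError):
    """An AUC ratio (or predicted ratio) has a zero denominator."""


class ConvergenceError(HyperkinError, RuntimeError):
    """A model fit did not converge or is non-identifiable (CLI exit code 3)."""
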