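"""Exception and warning types used across the package."""


class HomeostatError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(HomeostatError, ValueError):
    """A rate-parameter set violates its constraints (negative rate, zero Michaelis constant, ...)."""


class InvalidStateError(HomeostatError, ValueError):
    """A state vector is non-finite, negative, or has the wrong dimension."""


class ConfigError(HomeostatError, ValueError):
    """A run description references unknown models, parameters or species."""


class IntegrationError(HomeostatError, RuntimeError):
    """The stiff solver failed; carries the approximate failure time."""

    def __init__(self, message: str, t_fail: float | None = None):
        super().__init__(message)
        self.t_fail = t_fail


class AnalysisError(HomeostatError, RuntimeError):
    """An analysis operator cannot produce its statistic (e.g. no post-step cycles)."""


class WindupWarning(UserWarning):
    """Inflow/outflow controller set-points are ordered so that the controllers fight each other."""


class ConvergenceWarning(UserWarning):
    """A running average or pre-equilibration has not met its convergence criterion."""
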