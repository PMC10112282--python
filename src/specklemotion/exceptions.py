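"""Exception and warning types shared across the package."""


class ParameterError(ValueError):
    """A physical or model parameter is out of its valid range."""


class GridError(ValueError):
    """A frequency grid is empty, non-uniform, or not symmetric about zero."""


class StackError(ValueError):
    """A speckle stack has the wrong kind, shape, or too few frames."""


class DecayNotReachedError(RuntimeError):
    """A correlation curve never falls below the 1/e threshold.

    Carries ``last_lag``, the largest lag available in the curve, so callers
    can decide whether to simulate for longer.
    """

    def __init__(self, last_lag: float):
        super().__init__(
            f"correlation excess never falls to 1/e within the lag range "
            f"(last lag {last_lag:g} s)"
        )
        self.last_lag = last_lag


class ResolutionWarning(UserWarning):
    """The requested lags are under-resolved by the frequency grid."""
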