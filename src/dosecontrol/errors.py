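"""Exception types shared across the package."""


class InvalidCovariatesError(ValueError):
    """Covariate PK formula produced a non-physical (non-positive) value."""


class FitError(RuntimeError):
    """A regression / breakpoint fit could not be carried out."""


class EstimationError(ValueError):
    """A PD / death-rate estimate fell outside its admissible domain."""


class OptimizationError(RuntimeError):
    """The control optimizer encountered a non-finite cost."""
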