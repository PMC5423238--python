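"""Exception hierarchy shared across the package."""


class ZcspecError(Exception):
    """Base class for all package-specific errors."""


class DomainError(ZcspecError, ValueError):
    """An argument is outside the domain an operation supports
    (extrapolation, negative concentration, incompatible delta-lambda, ...)."""


class ParseError(ZcspecError, ValueError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(ZcspecError, ValueError):
    """Structurally valid input violates a semantic invariant
    (non-monotone wavelengths, too-short grid, mismatched lengths, ...)."""


class SingularDesignError(ZcspecError, ValueError):
    """A regression design is singular (e.g. all concentrations identical)."""


class SelectionError(ZcspecError, RuntimeError):
    """No working wavelength satisfies the screening thresholds.

    The message lists the best rejected candidates and the threshold each
    one violates, so the caller can decide whether to relax the criteria.
    """


class StageError(ZcspecError, RuntimeError):
    """A pipeline stage failed; carries the stage name and sample id."""

    def __init__(self, stage: str, message: str, sample_id: str | None = None):
        self.stage = stage
        self.sample_id = sample_id
        where = f"stage '{stage}'" + (f", sample '{sample_id}'" if sample_id else "")
        super().__init__(f"{where}: {message}")
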