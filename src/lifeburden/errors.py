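"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Raised when input data or configuration violates a documented invariant."""


class FitError(RuntimeError):
    """Raised when a rate model fails to converge.

    Carries the cause label so pipeline errors name the offending model.
    """

    def __init__(self, cause: str, message: str):
        self.cause = cause
        super().__init__(f"rate model for cause '{cause}': {message}")
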