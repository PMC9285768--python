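"""Exception types shared across the package."""


class InputError(ValueError):
    """An argument violates a documented precondition."""


class ConfigError(ValueError):
    """A configuration file or parameter set is invalid.

    Carries a list of human-readable violation messages in ``violations``.
    """

    def __init__(self, message: str, violations: list[str] | None = None):
        self.violations = violations or []
        if self.violations:
            message = message + "\n  - " + "\n  - ".join(self.violations)
        super().__init__(message)


class NumericalError(RuntimeError):
    """A solver diverged or produced non-finite values."""
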