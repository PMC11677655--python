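"""Exception hierarchy shared across the package."""


class NanoAromaError(Exception):
    """Base class for all package-specific errors."""


class NotFoundError(NanoAromaError, KeyError):
    """A compound (or other keyed record) is absent from a registry."""

    def __init__(self, name: str):
        super().__init__(name)
        self.name = name

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message plain
        return f"compound not found: {self.name!r}"


class DegenerateInputError(NanoAromaError, ValueError):
    """Input carries no usable signal (e.g. all-zero areas)."""


class InsufficientDataError(NanoAromaError, ValueError):
    """Too few points for the requested estimate."""


class InconsistencyError(NanoAromaError, ValueError):
    """Input violates a bookkeeping constraint (e.g. areas exceed 100%)."""


class MissingPropertyError(NanoAromaError, ValueError):
    """A required physicochemical property is absent for a compound."""


class ExcludedCompoundSignal(NanoAromaError):
    """A compound cannot be scored (absent odor threshold).

    Deliberately distinct from an error condition: callers of the bulk
    scoring chain catch this signal, log the exclusion and continue.
    """

    def __init__(self, name: str, reason: str):
        super().__init__(f"{name}: {reason}")
        self.name = name
        self.reason = reason


class DegenerateProfileError(NanoAromaError, ValueError):
    """The radar profile carries no odor signal at all."""


class CannotNormalizeError(NanoAromaError, ValueError):
    """A release series cannot be converted to fractional form."""


class FitFailureError(NanoAromaError, RuntimeError):
    """Model fitting failed; carries the best iterate seen, if any."""

    def __init__(self, message: str, best=None):
        super().__init__(message)
        self.best = best


class ConfigError(NanoAromaError, ValueError):
    """Run configuration failed validation; message lists every offence."""
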