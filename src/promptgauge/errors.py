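"""Exception hierarchy shared across the package.

Exit-code mapping for the CLI: :class:`InputError` and subclasses -> 2,
:class:`BackendError` -> 3.
"""


class PromptGaugeError(Exception):
    """Base class for all package errors."""


class InputError(PromptGaugeError, ValueError):
    """Invalid user-supplied input (bad argument, malformed file, bad config)."""


class FormatError(InputError):
    """A template or corpus file does not conform to the expected format."""


class RenderError(InputError):
    """Template rendering failed (e.g. required slots missing from context)."""

    def __init__(self, message: str, missing: list[str] | None = None):
        super().__init__(message)
        self.missing = list(missing or [])


class BackendError(PromptGaugeError):
    """A model backend failed; carries the backend's identity."""

    def __init__(self, message: str, backend: str = "unknown"):
        super().__init__(f"[backend={backend}] {message}")
        self.backend = backend


class ContractViolationError(PromptGaugeError):
    """A backend returned values violating its contract (e.g. logprob > 0,
    zero-norm embedding for non-empty text)."""
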