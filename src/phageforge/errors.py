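"""Exception hierarchy for phageforge.

Distinct exception types back the CLI's distinct exit codes, so callers can
tell an impossible design request apart from a repair loop that got stuck or
a chromatogram fit that failed to converge.
"""


class PhageForgeError(Exception):
    """Base class for all package-specific errors."""


class InfeasibleDesignError(PhageForgeError):
    """The design specification cannot be satisfied by any sequence.

    Raised before any search is attempted, e.g. when the requested CG-dimer
    count does not fit in the target length.  The message names the violated
    constraint.
    """


class UnresolvableRepeatError(PhageForgeError):
    """A direct repeat could not be broken by any allowed A<->T mutation."""

    def __init__(self, message: str, window=None):
        super().__init__(message)
        self.window = window


class UnresolvableHairpinError(PhageForgeError):
    """An inverted repeat could not be broken by any allowed A<->T mutation."""

    def __init__(self, message: str, window=None):
        super().__init__(message)
        self.window = window


class FitConvergenceError(PhageForgeError):
    """A chromatogram deconvolution did not converge (used by strict callers)."""


class InputFormatError(PhageForgeError):
    """A malformed input file; carries a line number when available."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message if line is None else f"line {line}: {message}")
        self.line = line
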