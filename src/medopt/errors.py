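"""Exception hierarchy shared across the package.

Validation problems (bad files, malformed arguments) raise
:class:`ValidationError`; numerical problems during fitting or training
raise :class:`ComputationError`.  The CLI maps the former to exit code 2
and the latter to exit code 1.
"""


class MedoptError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(MedoptError, ValueError):
    """Malformed input: bad schema, out-of-range value, bad argument."""


class UnsupportedDesignError(ValidationError):
    """Requested experimental design is outside what the package builds."""


class RangeError(ValidationError):
    """A value lies outside the admissible range; message names the offender."""


class ComputationError(MedoptError, RuntimeError):
    """A numerical procedure failed (singular fit, divergence, ...)."""


class SingularFitError(ComputationError):
    """Least-squares basis is rank deficient; message lists aliased terms."""


class DivergenceError(ComputationError):
    """Training loss became non-finite; advises a lower learning rate."""
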