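"""Exception hierarchy shared across the package."""


class LandbridgeError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(LandbridgeError, ValueError):
    """An argument violates a documented precondition."""


class SaturationError(LandbridgeError, ValueError):
    """A pairwise distance cannot be computed because the multiple-hit
    correction argument is non-positive (sequences too divergent)."""


class DegenerateComparisonError(LandbridgeError, ValueError):
    """No comparable sites remain after pairwise deletion."""


class UndefinedStatisticError(LandbridgeError, ValueError):
    """A summary statistic is undefined on this input (e.g. no
    segregating sites for Tajima's D)."""
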