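"""Exception hierarchy.

The CLI maps these onto exit codes: data/validation problems -> 3,
numerical failures -> 4. Anything else is a bug.
"""


class ScorpalloError(Exception):
    """Base class for package errors."""


class TraitDataError(ScorpalloError, ValueError):
    """Invalid trait table content (missing columns, non-positive traits, ...)."""


class PhyloError(ScorpalloError, ValueError):
    """Invalid tree, Newick syntax error, or tip/species mismatch."""


class NumericalError(ScorpalloError, ArithmeticError):
    """Singular covariance/design, optimizer failure, degenerate sample."""


class ConfigError(ScorpalloError, ValueError):
    """Invalid simulation or pipeline configuration."""
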