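"""Exception hierarchy shared across the package."""


class CochlevolError(Exception):
    """Base class for all package errors."""


class InvalidInputError(CochlevolError, ValueError):
    """Input values violate a precondition (wrong shape, sign, count...)."""


class SingularGeometryError(CochlevolError):
    """Landmark configuration is degenerate (collinear, coincident...)."""


class InsufficientTurnsError(CochlevolError):
    """Spiral path spans less than one full turn."""


class UndefinedAngleError(CochlevolError):
    """A landmark coincides with the spiral center; its angle is undefined."""


class InvalidOutlineError(CochlevolError):
    """Window outline is not a simple closed loop after projection."""


class TreeError(CochlevolError):
    """Base class for phylogeny errors."""


class NewickParseError(TreeError):
    """Malformed Newick or missing branch lengths."""


class UnrootedTreeError(TreeError):
    """Explicitly unrooted trees are not supported."""


class AlignmentError(TreeError):
    """Trait table and tree tips cannot be reconciled."""


class InvalidParameterError(CochlevolError, ValueError):
    """Model parameter outside its permitted domain."""


class IdentifiabilityError(CochlevolError):
    """Model parameters are not identifiable on this tree (e.g. drift on an
    ultrametric tree)."""


class DegenerateDataError(CochlevolError):
    """Data carry no usable variation (constant trait, zero variance...)."""


class ConvergenceError(CochlevolError):
    """Optimizer failed; carries the fallback profile grid when available."""

    def __init__(self, message, profile=None):
        super().__init__(message)
        self.profile = profile


class InvalidComparisonError(CochlevolError, ValueError):
    """Model fits being compared are not comparable (different responses)."""
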