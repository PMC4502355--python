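"""Exception hierarchy for fieldlab.

Exit-code mapping used by the CLI: user/configuration problems are
:class:`UserError` subclasses (exit 1); numerical failures are
:class:`NumericalError` subclasses (exit 2).
"""


class FieldlabError(Exception):
    """Base class for all fieldlab errors."""


class UserError(FieldlabError):
    """Invalid input, configuration, or request."""


class ConfigurationError(UserError):
    """Inconsistent or out-of-range configuration values."""


class LabelingError(UserError):
    """A label code in a volume has no tissue/conductivity mapping."""


class UnknownNameError(UserError):
    """Unknown 10-10 label, montage name, or ROI scheme."""


class GeometryError(UserError):
    """Geometric preconditions violated (ray misses scalp, lattice mismatch...)."""


class PlacementError(UserError):
    """Electrode footprint overlaps an already-stamped electrode."""


class TopologyError(UserError):
    """No conductive path connects the anode(s) to the cathode(s)."""


class MaskError(UserError):
    """Empty or invalid voxel mask."""


class ComparabilityError(UserError):
    """Reports being compared come from different phantoms/ROI sets."""


class NumericalError(FieldlabError):
    """Numerical failure (solver did not converge, ...)."""


class ConvergenceError(NumericalError):
    """Iterative solver failed to reach the requested residual."""
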