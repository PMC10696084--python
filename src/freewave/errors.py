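"""Exception hierarchy.

Exit-code mapping used by the CLI: configuration problems (2), data/input
problems (3), numeric/degenerate problems (4).
"""


class FreewaveError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigurationError(FreewaveError):
    """Invalid or inconsistent configuration."""

    exit_code = 2


class SimulationError(FreewaveError):
    """Phantom / signal simulation failure (e.g. non-positive heart period)."""

    exit_code = 2


class InputError(FreewaveError):
    """Malformed or mismatched input data."""

    exit_code = 3


class GatingError(FreewaveError):
    """Cardiac gating failure (too few triggers, unassignable readouts)."""

    exit_code = 3


class ReconstructionError(FreewaveError):
    """Reconstruction failure (empty k-space cell, NaN/Inf input)."""

    exit_code = 3


class MaskError(FreewaveError):
    """Brain-mask extraction failed (empty mask)."""

    exit_code = 4


class RoiError(FreewaveError):
    """A region of interest is empty or inconsistent."""

    exit_code = 3


class NumericError(FreewaveError):
    """Degenerate numeric situation (zero variance, nonpositive percentile...)."""

    exit_code = 4
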