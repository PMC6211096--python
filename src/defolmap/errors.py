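"""Exception hierarchy.

Configuration errors (bad parameters, missing bands, mismatched indices) are
distinguished from data errors (shape mismatches, nodata hits, empty masks)
so the command-line layer can map them to distinct exit codes.
"""


class DefolmapError(Exception):
    """Base class for all package errors."""


class ConfigurationError(DefolmapError):
    """Invalid parameters, unknown index names, missing bands, bad presets."""


class DataError(DefolmapError):
    """Invalid or inconsistent data: shape mismatch, nodata cell, empty raster."""


class ConvergenceError(DefolmapError):
    """Optimizer failed to converge; carries the iteration trace."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace or []
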