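"""Exception hierarchy shared across the package."""


class HeatspecError(Exception):
    """Base class for all package-specific errors."""


class FormatError(HeatspecError, ValueError):
    """A spectra/physiology table violates its declared dialect."""


class AlignmentError(HeatspecError, ValueError):
    """Spectra do not share a grid, or samples cannot be matched."""


class ValidationError(HeatspecError, ValueError):
    """A domain invariant is violated (ranges, monotonicity, signs)."""


class ConfigError(HeatspecError, ValueError):
    """A run/simulation configuration is inconsistent or incomplete."""


class GridRangeError(HeatspecError, ValueError):
    """A requested wavelength grid falls outside the supported span."""


class WindowError(HeatspecError, ValueError):
    """A spectral window contains too few grid points or lies off-grid."""


class DegenerateMatrixError(HeatspecError, ValueError):
    """A selected column has (numerically) zero norm during projection."""

    def __init__(self, message: str, iteration: int | None = None):
        super().__init__(message)
        self.iteration = iteration


class EmptyFeatureSetError(HeatspecError, ValueError):
    """Feature filtering left no columns (e.g. correlation cut too high)."""
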