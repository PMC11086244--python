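"""Exception types shared across the package."""


class IrisCapError(Exception):
    """Base class for package-specific errors."""


class StabilityError(IrisCapError, ValueError):
    """An AR model has characteristic roots on or outside the unit circle."""


class DegenerateSignalError(IrisCapError, ValueError):
    """Input signal carries no usable information (constant, empty, non-finite)."""


class GridMismatchError(IrisCapError, ValueError):
    """Two spectra (or a spectrum and a query) live on different frequency grids."""
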