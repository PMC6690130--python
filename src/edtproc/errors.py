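"""Exception hierarchy shared by the processing stages.

Exit-code mapping used by the CLI: configuration errors exit 2,
data-validation errors exit 3, algorithmic failures exit 4.
"""


class EdtprocError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigurationError(EdtprocError):
    """Bad or missing configuration / metadata (exit 2)."""

    exit_code = 2


class DataValidationError(EdtprocError):
    """Input data violates a documented invariant (exit 3)."""

    exit_code = 3


class AlgorithmError(EdtprocError):
    """A processing stage could not produce a result (exit 4)."""

    exit_code = 4


class CenteringError(AlgorithmError):
    """Pattern-centre search failed (no beam, too few Friedel pairs)."""


class GeometryError(AlgorithmError):
    """Geometrically impossible request (e.g. g beyond the Ewald sphere)."""


class NoLatticeError(AlgorithmError):
    """Basis search could not index the difference-vector clusters."""


class CoverageError(AlgorithmError):
    """Requested path/slab lies mostly outside the reconstructed volume."""


class ResourceError(EdtprocError):
    """A requested grid would exceed the configured memory cap."""

    exit_code = 2


class FormatOverflowError(EdtprocError):
    """A value does not fit the fixed-width output format."""

    exit_code = 3
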