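"""Exception hierarchy shared across the package."""


class EnzmechError(Exception):
    """Base class for all package-specific errors."""


class FormatError(EnzmechError, ValueError):
    """A file or value violates the expected on-disk format."""


class ConsistencyError(EnzmechError, ValueError):
    """Inputs that must agree (labels, instance ids, annotations) do not."""


class DimensionError(EnzmechError, ValueError):
    """Vectors or datasets defined over different attribute spaces."""


class InputError(EnzmechError, ValueError):
    """A scalar or sequence argument is out of its documented domain."""


class CoverageError(EnzmechError, ValueError):
    """A prediction set does not cover every instance it must score."""


class PartitionError(EnzmechError, ValueError):
    """A cross-validation partition request cannot be satisfied."""


class GenerationError(EnzmechError, RuntimeError):
    """The synthetic generator could not meet its configured targets."""
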