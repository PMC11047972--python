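"""Exception hierarchy shared across the package."""


class NeuroconfError(Exception):
    """Base class for all package-specific errors."""


class StructuralError(NeuroconfError):
    """Reconstruction violates tree invariants (cycle, multiple roots, ...)."""


class DegenerateSegmentError(NeuroconfError):
    """A branching segment could not be extracted (too few nodes/points)."""


class InvalidDirectionError(NeuroconfError):
    """A zero-length vector was supplied where a direction was required."""


class BoundsError(NeuroconfError):
    """A voxel coordinate lies outside the image grid."""


class FormatError(NeuroconfError):
    """An input file could not be parsed."""

    def __init__(self, message, line=None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class ConfigError(NeuroconfError):
    """A configuration file or parameter value is invalid."""


class GenerationError(NeuroconfError):
    """A synthetic fixture could not be generated under the given config."""


class InjectionError(NeuroconfError):
    """No eligible branch exists for the requested artifact injection."""
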