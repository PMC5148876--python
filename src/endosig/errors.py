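"""Exception hierarchy shared across the package."""


class EndosigError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(EndosigError, ValueError):
    """A simulation or run configuration is internally inconsistent."""


class GenerationError(EndosigError, RuntimeError):
    """A synthetic dataset could not be generated under the given constraints."""


class EmptyProfileError(EndosigError, ValueError):
    """No countable dinucleotide sites in the input sequences."""


class FormatError(EndosigError, ValueError):
    """A file or in-memory table violates its format contract."""
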