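"""Exception types shared across the package."""


class BeadphaseError(Exception):
    """Base class for all package errors."""


class ParameterError(BeadphaseError, ValueError):
    """A function argument is outside its documented domain."""


class FormatError(BeadphaseError, ValueError):
    """Malformed input data (CIGAR, barcode set, file contents)."""


class ConfigError(BeadphaseError, ValueError):
    """Invalid pipeline configuration; message carries the key path."""


class ConsistencyError(BeadphaseError, ValueError):
    """Internally inconsistent object set (e.g. phased site without a call)."""
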