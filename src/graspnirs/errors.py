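"""Exception hierarchy.

Validation errors signal inputs that violate a documented domain contract;
format errors signal malformed files; pipeline-order errors signal preprocessing
stages applied out of their documented sequence.
"""


class GraspNirsError(Exception):
    """Base class for all package errors."""


class ValidationError(GraspNirsError, ValueError):
    """An input value violates a documented invariant."""


class FormatError(GraspNirsError, ValueError):
    """A file does not conform to its expected on-disk layout."""


class UnsupportedDataError(GraspNirsError, ValueError):
    """A file is well-formed but describes data outside this package's scope."""


class ConfigError(GraspNirsError, ValueError):
    """A configuration file or object is inconsistent."""


class PipelineOrderError(GraspNirsError, RuntimeError):
    """A preprocessing stage was applied out of sequence."""
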