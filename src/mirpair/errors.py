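"""Exception hierarchy.

Errors are grouped so callers (and the CLI exit-code mapping) can distinguish
bad parameters/configuration, malformed or misaligned input data, and failures
that arise during computation itself.
"""


class MirpairError(Exception):
    """Base class for all package errors."""


class ValidationError(MirpairError):
    """Invalid parameter, configuration value, or precondition violation."""


class FormatError(MirpairError):
    """Malformed input file (duplicate rows, missing reference assay, bad cell)."""


class AlignmentError(MirpairError):
    """Samples or genes do not line up between two inputs."""


class PairingError(MirpairError):
    """Primary/metastasis pairing invariant violated for a patient."""


class InsufficientDataError(MirpairError):
    """Too few observations for the requested statistic."""


class ComputationError(MirpairError):
    """A computation could not be carried out on otherwise valid input."""


class TargetLookupError(MirpairError):
    """A miRNA is absent from every target-set source."""


class OrchestrationError(MirpairError):
    """A pipeline stage's dependency is missing or disabled."""
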