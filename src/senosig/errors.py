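"""Exception hierarchy shared across the package."""


class SenosigError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(SenosigError, ValueError):
    """A simulation or run configuration violates an invariant.

    The message names the offending field.
    """


class InsufficientReplicationError(SenosigError, ValueError):
    """Fewer than the required number of samples per compared arm."""


class UndefinedScoreError(SenosigError, ValueError):
    """An enrichment score is undefined (empty hit set or set == universe)."""


class UndefinedCorrelationError(SenosigError, ValueError):
    """Correlation undefined because one input has zero variance."""


class SignatureNotPresentError(SenosigError, KeyError):
    """None of a signature's genes are present in the dataset."""


class MissingArtifactError(SenosigError, FileNotFoundError):
    """A pipeline stage requires an upstream output that does not exist."""
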