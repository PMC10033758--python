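"""Exception hierarchy shared across the pipeline stages."""


class HyposcapeError(Exception):
    """Base class for all pipeline errors."""


class InvalidParameterError(HyposcapeError, ValueError):
    """A simulation or analysis parameter is outside its valid range."""


class DomainError(HyposcapeError, ValueError):
    """An input value violates a mathematical precondition of an operation."""


class FormatError(HyposcapeError, ValueError):
    """A file or table does not conform to the expected format."""


class PairingError(HyposcapeError, KeyError):
    """A sample barcode cannot be resolved against the pairing manifest."""


class ConfigurationError(HyposcapeError, ValueError):
    """A configuration references columns, genes or labels that do not exist."""
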