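"""Exception hierarchy shared across the pipeline stages."""


class DirSeqError(Exception):
    """Base class for all package errors."""


class ConfigurationError(DirSeqError):
    """A config file, manifest header, or anchor setup is malformed."""


class ValidationError(DirSeqError):
    """An input value violates a domain invariant (bad allele, short flank, ...)."""


class InputError(DirSeqError):
    """Structurally valid input that cannot be processed (missing column/sample, mate
    count mismatch, absent control construct)."""


class InsufficientDataError(DirSeqError):
    """Too few replicates or group members to run a statistical comparison."""
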