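"""Exception types shared across the package."""


class NLRKitError(Exception):
    """Base class for all errors raised by nlrkit."""


class FormatError(NLRKitError):
    """A file does not conform to its declared on-disk format."""


class ValidationError(NLRKitError):
    """An in-memory object violates a contract (bad coordinates, bad config, ...)."""
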