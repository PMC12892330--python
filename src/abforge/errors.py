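"""Exception hierarchy shared across the package."""


class AbforgeError(Exception):
    """Base class for all package errors."""


class RegionError(AbforgeError):
    """A position cannot be assigned to a region, or a region is absent."""


class SequenceError(AbforgeError):
    """Non-canonical residue letters or malformed sequence input."""


class ConfigurationError(AbforgeError):
    """Invalid or incomplete configuration."""


class DatasetError(AbforgeError):
    """Malformed dataset rows or missing annotations."""


class NoCandidateError(AbforgeError):
    """No modification candidate satisfies the active constraints.

    Raised by proposal operators; the engine treats it as a skipped
    cycle rather than a fatal failure.
    """


class ConformationRejected(AbforgeError):
    """A proposal was rejected by the conformation guard before scoring."""


class AdapterError(AbforgeError):
    """An external-tool adapter failed; recorded as a rejected cycle."""
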