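"""Exception hierarchy shared across the package."""


class ChronovegError(Exception):
    """Base class for all package-specific errors."""


class InventoryFormatError(ChronovegError):
    """The inventory file does not conform to the expected table layout."""


class EmptyInventoryError(ChronovegError):
    """The inventory file contains no stem records."""


class DomainError(ChronovegError, ValueError):
    """An input violates a mathematical precondition of an operation."""


class ConfigError(ChronovegError):
    """A simulation or pipeline configuration is infeasible."""
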