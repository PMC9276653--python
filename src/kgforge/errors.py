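"""Exception hierarchy shared across the toolkit."""


class ForgeError(Exception):
    """Base class for all toolkit errors."""


class FormatError(ForgeError):
    """A source file violates its format contract (bad header, truncated record...)."""


class ConfigurationError(ForgeError):
    """An adapter/merge configuration is inconsistent or references missing inputs."""


class RegistryError(ForgeError):
    """A label or abbreviation is not present in the abbreviation registry."""


class ContractError(ForgeError):
    """An operation was called outside its preconditions."""


class StructureError(ForgeError):
    """A chemical structure could not be parsed into a fingerprint."""
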