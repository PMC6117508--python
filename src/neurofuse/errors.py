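"""Exception hierarchy shared across the toolbox."""


class NeurofuseError(Exception):
    """Base class for all toolbox errors."""


class FormatError(NeurofuseError):
    """A file could not be parsed as the expected on-disk format."""


class ContractError(NeurofuseError):
    """Inputs violate a documented precondition of an operation."""
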