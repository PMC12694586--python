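"""Exception hierarchy used across the toolkit."""


class IceseqError(Exception):
    """Base class for all toolkit errors."""


class ConfigurationError(IceseqError):
    """A parameter is outside its documented range or inconsistent."""


class SimulationError(IceseqError):
    """The synthetic-data generator cannot satisfy the requested scenario."""


class InputError(IceseqError):
    """Malformed or inconsistent user input (reads, catalogs, calls)."""


class ParseError(InputError):
    """A standard-format file could not be parsed; carries location context."""


class AdapterError(IceseqError):
    """External alignment records cannot be reconciled with the flank set."""


class AnalysisError(IceseqError):
    """A downstream analysis has no defined result for the given input."""
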