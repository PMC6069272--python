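"""Exception hierarchy for chain configuration, data and parameter errors."""


class MeaflowError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MeaflowError):
    """Invalid chain/unit configuration: unknown kind, bad wiring, bad value."""


class DataError(MeaflowError):
    """Malformed input data: wrong frame length, truncated file, bad row."""


class ParameterError(MeaflowError):
    """Rejected runtime parameter update (static target or out-of-range value)."""


class UnsupportedCostError(MeaflowError):
    """No documented latency/memory formula exists for the requested unit kind."""
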