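"""Exception hierarchy shared across the package."""


class NdoaError(Exception):
    """Base class for all package-specific errors."""


class DataLogParseError(NdoaError):
    """A data-log CSV row could not be parsed; message names file and line."""


class UnsupportedSamplingRateError(NdoaError):
    """The recording's sampling rate differs from the supported 128 Hz."""


class DegenerateSignalError(NdoaError):
    """A window is too regular for the requested statistic (e.g. constant
    signal, single ordinal pattern, zero permutation-entropy energy)."""
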