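"""Exception hierarchy shared across the package."""


class T21MetaError(Exception):
    """Base class for all package errors."""


class ConfigError(T21MetaError):
    """An invalid configuration field. The message names the field."""


class DataError(T21MetaError):
    """Malformed input values (p-values out of range, NaN, non-integer counts...)."""


class DesignError(T21MetaError):
    """An experimental design the method cannot handle (e.g. <2 samples per group)."""


class HarmonizationError(T21MetaError):
    """Feature-id / probe-map mismatch that leaves nothing to analyse."""


class ContractError(T21MetaError):
    """An internal contract violated by a caller (duplicate records, empty input)."""


class GMTParseError(T21MetaError):
    """Malformed GMT gene-set file; message carries the line number."""


class TraceError(T21MetaError):
    """An OCR trace without the structure the Mito Stress indices require."""


class CalibrationError(T21MetaError):
    """A fluorescence ratio outside the calibratable range [Rmin, Rmax)."""
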