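"""Exception types raised across the pipeline."""


class ChipcytoError(Exception):
    """Base class for all package errors."""


class ParameterError(ChipcytoError, ValueError):
    """A configuration or function parameter is outside its valid domain."""


class SchemaError(ChipcytoError, KeyError):
    """An input table is missing a required column or marker."""


class PairingError(ChipcytoError, ValueError):
    """Stained/post-bleach values are not paired cell-by-cell."""


class IntegrityError(ChipcytoError, ValueError):
    """An internal consistency check on assembled data failed."""


class MeasurementError(ChipcytoError, ValueError):
    """A per-cell intensity measurement could not be made."""


class SampleSizeError(ChipcytoError, ValueError):
    """Too few observations for the requested statistic."""
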