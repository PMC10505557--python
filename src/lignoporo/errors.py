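"""Exception hierarchy shared by the analysis modules."""


class LignoporoError(Exception):
    """Base class for package errors."""


class DomainError(LignoporoError, ValueError):
    """An input is outside the mathematical/physical domain of an operation."""


class ConfigurationError(LignoporoError, ValueError):
    """An analysis setting is incompatible with the data (e.g. window > hold)."""


class SegmentationError(LignoporoError, RuntimeError):
    """A programmed isothermal hold could not be located in a thermogram."""


class QuantificationError(LignoporoError, RuntimeError):
    """An image-quantification step produced an unusable result (empty mask...)."""


class DegenerateDataError(LignoporoError, ValueError):
    """Data carry no signal for the requested estimate (all-zero enthalpies...)."""
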