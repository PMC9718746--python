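"""Exception hierarchy shared across the package."""


class YmosaicError(Exception):
    """Base class for all package-specific errors."""


class FormatError(YmosaicError):
    """A file does not conform to its declared on-disk format."""


class AnnotationError(YmosaicError):
    """Gene annotation is missing information required by an operation."""


class ConfigurationError(YmosaicError):
    """A configuration or derived resource is invalid or unusable."""


class EmptyResultError(YmosaicError):
    """An operation produced an empty result where downstream stages need data."""


class JoinError(YmosaicError):
    """Barcode tables that must align do not."""

    def __init__(self, message: str, offenders=None):
        super().__init__(message)
        self.offenders = list(offenders) if offenders is not None else []


class SaturationError(YmosaicError):
    """All ddPCR droplets positive: the Poisson concentration is unbounded."""
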