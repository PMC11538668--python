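"""Exception hierarchy for zonatlas."""


class ZonatlasError(Exception):
    """Base class for all zonatlas errors."""


class FormatError(ZonatlasError):
    """A required file is missing or not in the expected on-disk format."""


class IntegrityError(ZonatlasError):
    """Files are individually readable but mutually inconsistent
    (dimension mismatch, duplicated barcodes, ...)."""


class IncompatibleSamplesError(ZonatlasError):
    """Samples cannot be merged (gene lists differ)."""


class ValidationError(ZonatlasError):
    """An argument violates a documented precondition."""
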