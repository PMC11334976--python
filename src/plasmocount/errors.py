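"""Exception types shared across the pipeline."""


class PlasmocountError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(PlasmocountError, ValueError):
    """An argument violates a documented precondition."""


class UnsupportedFormatError(PlasmocountError, ValueError):
    """An image file is readable but not a 3-channel RGB image."""


class GenerationError(PlasmocountError, RuntimeError):
    """The synthetic-scene generator could not satisfy its constraints."""
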