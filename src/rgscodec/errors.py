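"""Exception hierarchy shared by all modules."""


class RgscError(Exception):
    """Base class for all package errors."""


class DegenerateHistogram(RgscError):
    """Image has a single intensity value; no threshold separates two classes."""


class EmptyForeground(RgscError):
    """No pixel lies above the requested threshold."""


class SeedOutOfBounds(RgscError):
    """Region-growing seed falls outside the image."""


class InvalidFuzzifier(RgscError):
    """Fuzzy c-means weight exponent must satisfy p > 1."""


class DimMismatch(RgscError):
    """Operands have different heights/widths."""


class UnsupportedLevel(RgscError):
    """Confidence level is not one of 90, 95, 99 percent."""


class ImageTooSmall(RgscError):
    """Image below the minimum size for wavelet decomposition."""


class EmptyInput(RgscError):
    """Huffman table requested for an empty frequency map."""


class MalformedPacket(RgscError):
    """Huffman packet violates its framing (Kraft sum, truncated payload)."""


class MalformedStream(RgscError):
    """SPIHT bitstream or container inconsistent with its recorded lengths."""


class BudgetExhausted(RgscError):
    """Internal signal: the bit budget was hit mid-write (caught by the encoder)."""


class InfeasibleSpec(RgscError):
    """Phantom specification cannot be realized (tumor does not fit in the head)."""
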