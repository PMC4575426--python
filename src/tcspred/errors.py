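"""Exception hierarchy shared across the package."""


class TcspredError(Exception):
    """Base class for all package-specific errors."""


class FormatError(TcspredError, ValueError):
    """A file violates its declared format (ragged MSA, bad label token...)."""


class DataError(TcspredError, ValueError):
    """Input data violates a contract (duplicate pairs, empty dataset...)."""


class InsufficientOverlapError(TcspredError):
    """Two MSAs share fewer common species than the configured minimum.

    Downstream, the pair's coevolution features (i2h, MT) are treated as
    missing evidence rather than zero signal.
    """


class MissingFeature(TcspredError):
    """A predictor cannot produce evidence for this pair (degenerate input)."""
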