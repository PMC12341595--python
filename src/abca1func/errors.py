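"""Exception hierarchy for the abca1func pipeline."""


class Abca1Error(Exception):
    """Base class for all abca1func errors."""


class VariantParseError(Abca1Error):
    """Malformed protein-variant name (bad token, unknown residue, ref == alt)."""


class UndefinedEffluxError(Abca1Error):
    """Efflux fraction undefined (medium + lysate signal sums to zero)."""


class PairingError(Abca1Error):
    """Acceptor / no-acceptor well-sets do not belong to the same construct,
    experiment and treatment."""


class ConfigurationError(Abca1Error):
    """Required control (mock or WT) missing, or invalid calibration values."""


class NormalizationError(Abca1Error):
    """No experiment with positive WT specific efflux available for
    normalization, or WT surface signal is zero."""


class InsufficientReplicatesError(Abca1Error):
    """Fewer than two replicate values in a group submitted to a two-sample
    test."""


class UnknownCriterionError(Abca1Error):
    """ACMG criterion token outside the vocabulary, or invalid strength."""


class TableFormatError(Abca1Error):
    """Malformed input table: missing column, bad token or bad value.

    The message names the offending row and column.
    """


class JoinError(Abca1Error):
    """Construct ids present in one result table but absent from another."""
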