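"""Exception hierarchy for the dosimetry pipeline.

Each error class maps to a distinct CLI exit code (see :mod:`fetaldose.cli`).
"""


class FetalDoseError(Exception):
    """Base class for all pipeline errors."""


class GridError(FetalDoseError, ValueError):
    """A length violates the 5-mm slab grid of the phantom."""


class BoundsError(FetalDoseError, ValueError):
    """A position or interval falls outside the modeled phantom extent."""


class CoverageError(FetalDoseError, ValueError):
    """A wide-volume rotation plan cannot cover the requested scan length."""


class ConfigurationError(FetalDoseError, ValueError):
    """Inconsistent scanner/protocol/coefficient configuration."""


class FormatError(FetalDoseError, ValueError):
    """A coefficient or report file violates the expected on-disk format."""


class ParameterError(FetalDoseError, ValueError):
    """Invalid synthetic-coefficient generator parameters."""


class DoseDomainError(FetalDoseError, ValueError):
    """A physically meaningless quantity (negative dose, non-positive DLP)."""
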