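"""Exception hierarchy.

All errors raised on bad user input derive from :class:`PlatefeedError`
so callers (and the CLI) can catch one type; parse errors always name the
offending plate/well rather than a row index.
"""


class PlatefeedError(ValueError):
    """Base class for all platefeed input and modelling errors."""


class PlateFormatError(PlatefeedError):
    """A plate-read file violates the expected grid/long structure."""


class LayoutError(PlatefeedError):
    """Layout or metadata inconsistent with the plate reads."""


class EstimationError(PlatefeedError):
    """Feeding-rate estimation impossible (e.g. a plate without controls)."""


class ModelSpecError(PlatefeedError):
    """Statistical model cannot be fitted as requested."""
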