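"""Exception hierarchy for irquant.

All package-specific errors derive from :class:`IRQuantError` so callers can
catch one base class at pipeline boundaries (the CLI does exactly that).
"""


class IRQuantError(Exception):
    """Base class for all irquant errors."""


class SpectrumFormatError(IRQuantError):
    """A spectrum file is malformed (bad rows, duplicate or non-monotonic grid)."""


class UnsupportedFeatureError(SpectrumFormatError):
    """A JCAMP-DX feature outside the supported AFFN subset was encountered."""


class GridMismatchError(IRQuantError):
    """Two spectra expected to share a wavenumber grid do not."""


class EmptyWindowError(IRQuantError):
    """A wavenumber window does not intersect the spectrum grid."""


class DegenerateSpectrumError(IRQuantError):
    """The normalization anchor has non-positive or vanishing absorbance."""


class ScatterCorrectionError(IRQuantError):
    """MSC regression slope is (near) zero: scan uncorrelated with reference."""


class ModelSelectionError(IRQuantError):
    """No factor count satisfies the correlation threshold."""


class ModelSchemaError(IRQuantError):
    """A model file has an unknown schema version or is corrupted."""


class WindowMismatchError(IRQuantError):
    """A spectrum is incompatible with the window a model was fitted on."""


class ValidationDesignError(IRQuantError):
    """A validation campaign lacks required levels or replicates."""
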