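"""Spectral pretreatments applied in fixed order before regression.

The pipeline is: window extraction -> reference-peak normalization ->
multiplicative signal correction (MSC).  Normalization divides each scan by
its absorbance at the anchor wavenumber (the analyte's strongest window band,
1697.6 cm^-1 by default), cancelling the unstable contact/pressure gain of
ATR measurements.  MSC then regresses each scan on a frozen reference
spectrum (the mean of the normalized, windowed calibration scans) and removes
the fitted additive offset and multiplicative slope — the classic scatter
correction of Geladi, MacDougall & Martens.

The MSC reference is frozen inside the calibration model at fit time:
prediction-time scans are always corrected against the calibration-set mean,
never against statistics of the spectra being predicted.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .exceptions import DegenerateSpectrumError, GridMismatchError, ScatterCorrectionError
from .spectra import Spectrum, extract_window, nearest_index

#: Anchor absorbance below this floor means the scan carries no analyte band.
ANCHOR_FLOOR = 1e-6

#: MSC slopes smaller than this mean the scan is uncorrelated with the reference.
MSC_SLOPE_FLOOR = 1e-8


@dataclasses.dataclass
class PreprocessParams:
    """Frozen preprocessing configuration, serialized inside the model file.

    ``msc_reference`` is ``None`` until a calibration has been fitted; when
    set, it is defined on exactly the ``[window_lo, window_hi]`` grid.
    """

    window_lo: float = 1300.0
    window_hi: float = 1800.0
    norm_wavenumber: float = 1697.6
    msc_reference: Spectrum | None = None

    def __post_init__(self) -> None:
        if not self.window_lo < self.window_hi:
            raise ValueError("window_lo must be < window_hi")
        if not (self.window_lo <= self.norm_wavenumber <= self.window_hi):
            raise ValueError("norm_wavenumber must lie inside the window")


def normalize_at(s: Spectrum, norm_wavenumber: float) -> Spectrum:
    """Divide a spectrum by its absorbance at the grid point nearest the anchor.

    The output equals exactly 1 at the anchor index.  An anchor absorbance at
    or below ``ANCHOR_FLOOR`` signals a scan with no analyte band and raises
    :class:`DegenerateSpectrumError`.
    """
    idx = nearest_index(s, norm_wavenumber)
    anchor = s.absorbance[idx]
    if not anchor > ANCHOR_FLOOR:
        raise DegenerateSpectrumError(
            f"anchor absorbance {anchor:.3g} at {s.wavenumbers[idx]:g} cm-1 "
            f"is not positive"
        )
    out = s.with_absorbance(s.absorbance / anchor)
    assert out.absorbance[idx] == 1.0
    return out


def msc_fit(calibration_spectra: Sequence[Spectrum]) -> Spectrum:
    """Point-wise mean of the calibration spectra: the MSC reference."""
    if len(calibration_spectra) < 2:
        raise ValueError("MSC reference requires at least 2 spectra")
    first = calibration_spectra[0]
    for s in calibration_spectra[1:]:
        if not first.same_grid(s):
            raise GridMismatchError("MSC fit: spectra do not share a grid")
    mean = np.mean([s.absorbance for s in calibration_spectra], axis=0)
    return first.with_absorbance(mean, label="msc_reference")


def msc_apply(
    s: Spectrum, reference: Spectrum, return_coef: bool = False
) -> Spectrum | tuple[Spectrum, float, float]:
    """Correct a scan against the MSC reference.

    Ordinary least squares of the scan on the reference, ``s ~ a + b*ref``;
    the corrected spectrum is ``(s - a) / b``.  Applying the correction to
    the reference itself returns the reference unchanged, and the correction
    exactly inverts any affine distortion ``a + b*ref`` with ``b > 0``.
    """
    if not s.same_grid(reference):
        raise GridMismatchError("MSC apply: scan and reference grids differ")
    ref = reference.absorbance
    ref_c = ref - ref.mean()
    denom = float(ref_c @ ref_c)
    if denom <= 0.0:
        raise ScatterCorrectionError("MSC reference is constant")
    b = float(ref_c @ (s.absorbance - s.absorbance.mean())) / denom
    a = float(s.absorbance.mean() - b * ref.mean())
    if abs(b) < MSC_SLOPE_FLOOR:
        raise ScatterCorrectionError(
            f"MSC slope {b:.3g} below floor: scan uncorrelated with reference"
        )
    corrected = s.with_absorbance((s.absorbance - a) / b)
    if return_coef:
        return corrected, a, b
    return corrected


def preprocess_pipeline(s: Spectrum, p: PreprocessParams) -> Spectrum:
    """Window -> normalize at anchor -> MSC (if a reference is frozen).

    Deterministic: equal inputs give bit-equal outputs.  Errors from the
    individual stages propagate unchanged.
    """
    out = extract_window(s, p.window_lo, p.window_hi)
    out = normalize_at(out, p.norm_wavenumber)
    if p.msc_reference is not None:
        out = msc_apply(out, p.msc_reference)
    return out
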