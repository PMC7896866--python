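"""Absorbance spectra: in-memory model plus CSV and JCAMP-DX input/output.

A :class:`Spectrum` is a single-beam absorbance curve sampled on a uniform,
strictly descending wavenumber grid (descending is the instrument convention
for mid-IR; every reader normalizes to it so windowing arithmetic never has
to branch on orientation).  A :class:`ScanSet` groups repeated scans of one
physical mixture — ten scans per working standard mixture and five per test
mixture by default, matching the repeated-positioning measurement design the
pipeline assumes.

CSV is the canonical interchange format (header ``wavenumber_cm-1,absorbance``);
JCAMP-DX 4.24 is supported read-only for the plain AFFN forms
``(X++(Y..Y))`` and ``XYPOINTS``.
"""

from __future__ import annotations

import dataclasses
import re
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .exceptions import (
    EmptyWindowError,
    GridMismatchError,
    SpectrumFormatError,
    UnsupportedFeatureError,
)

CSV_WAVENUMBER = "wavenumber_cm-1"
CSV_ABSORBANCE = "absorbance"

#: Tolerance on grid-spacing uniformity, in cm^-1.
GRID_SPACING_TOL = 1e-6


@dataclasses.dataclass(frozen=True)
class Spectrum:
    """A sampled absorbance curve on a uniform descending wavenumber grid.

    Parameters
    ----------
    wavenumbers
        Grid in cm^-1, strictly decreasing, constant spacing (to within
        ``GRID_SPACING_TOL``).
    absorbance
        Unitless absorbance values, one per grid point, all finite.
    label
        Free-text identifier (mixture id, scan index, ...).
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        w = np.asarray(self.wavenumbers, dtype=float)
        a = np.asarray(self.absorbance, dtype=float)
        object.__setattr__(self, "wavenumbers", w)
        object.__setattr__(self, "absorbance", a)
        if w.ndim != 1 or a.ndim != 1 or w.size != a.size:
            raise SpectrumFormatError(
                f"wavenumbers and absorbance must be 1-D of equal length "
                f"(got {w.shape} and {a.shape})"
            )
        if w.size == 0:
            raise SpectrumFormatError("empty spectrum")
        if not np.all(np.isfinite(w)):
            raise SpectrumFormatError("non-finite wavenumber in grid")
        if not np.all(np.isfinite(a)):
            raise SpectrumFormatError("non-finite absorbance value")
        if w.size > 1:
            d = np.diff(w)
            if not np.all(d < 0):
                raise SpectrumFormatError("wavenumber grid not strictly decreasing")
            if np.ptp(d) > GRID_SPACING_TOL:
                raise SpectrumFormatError(
                    f"wavenumber grid spacing not uniform (spread {np.ptp(d):.3g} cm-1)"
                )

    def __len__(self) -> int:
        return int(self.wavenumbers.size)

    def with_absorbance(self, a: np.ndarray, label: str | None = None) -> "Spectrum":
        """Copy of this spectrum with new absorbance values on the same grid."""
        return Spectrum(self.wavenumbers, a, self.label if label is None else label)

    def same_grid(self, other: "Spectrum", tol: float = 1e-9) -> bool:
        """True if both spectra share an identical grid (to ``tol`` cm^-1)."""
        return len(self) == len(other) and bool(
            np.all(np.abs(self.wavenumbers - other.wavenumbers) <= tol)
        )


@dataclasses.dataclass
class ScanSet:
    """Repeated scans of one physical mixture, all on one shared grid."""

    spectra: list[Spectrum]
    mixture_id: str

    def __post_init__(self) -> None:
        if not self.spectra:
            raise SpectrumFormatError(f"scan set {self.mixture_id!r} is empty")
        first = self.spectra[0]
        for s in self.spectra[1:]:
            if not first.same_grid(s):
                raise GridMismatchError(
                    f"scan set {self.mixture_id!r}: members do not share a grid"
                )

    def __len__(self) -> int:
        return len(self.spectra)


# ---------------------------------------------------------------------------
# grid helpers


def make_grid(high: float = 2000.0, low: float = 400.0, step: float = 4.0) -> np.ndarray:
    """Uniform descending wavenumber grid from ``high`` down to ``low``."""
    n = int(round((high - low) / step)) + 1
    return high - step * np.arange(n)


def nearest_index(s: Spectrum, target: float) -> int:
    """Index of the grid point closest to ``target`` cm^-1.

    Ties are broken toward the *higher* wavenumber.  Because the grid is
    stored descending, the first minimum of the distance array is the higher
    wavenumber, so ``argmin`` implements the tie-break directly.
    """
    return int(np.argmin(np.abs(s.wavenumbers - target)))


def extract_window(s: Spectrum, lo: float, hi: float) -> Spectrum:
    """Sub-spectrum with all grid points in ``[lo, hi]``, inclusive both ends.

    The original spectrum is untouched.  Raises :class:`EmptyWindowError` if
    the window does not intersect the grid.
    """
    if not lo < hi:
        raise ValueError(f"window bounds must satisfy lo < hi (got {lo}, {hi})")
    eps = 1e-9
    mask = (s.wavenumbers >= lo - eps) & (s.wavenumbers <= hi + eps)
    if not mask.any():
        raise EmptyWindowError(
            f"window [{lo}, {hi}] cm-1 does not intersect grid "
            f"[{s.wavenumbers.min():g}, {s.wavenumbers.max():g}]"
        )
    return Spectrum(s.wavenumbers[mask], s.absorbance[mask], s.label)


# ---------------------------------------------------------------------------
# CSV I/O

_FLOAT_RE = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")


def _is_number(token: str) -> bool:
    return bool(_FLOAT_RE.match(token.strip()))


def read_spectrum_csv(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    label: str | None = None,
) -> Spectrum:
    """Read a two-column (wavenumber, absorbance) CSV file.

    The grid is normalized to descending order regardless of file order;
    duplicate wavenumbers are rejected.  ``dialect`` may map the keys
    ``"wavenumber"`` and ``"absorbance"`` to column names in the file header;
    without it the canonical header names are used when present, otherwise
    the first two columns.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    rows: list[tuple[float, float]] = []
    col_w, col_a = 0, 1
    start = 0
    if lines:
        header = [c.strip() for c in lines[0].split(",")]
        if not all(_is_number(c) for c in header[:2]):
            start = 1
            want_w = (dialect or {}).get("wavenumber", CSV_WAVENUMBER)
            want_a = (dialect or {}).get("absorbance", CSV_ABSORBANCE)
            if want_w in header and want_a in header:
                col_w, col_a = header.index(want_w), header.index(want_a)
            elif dialect is not None:
                raise SpectrumFormatError(
                    f"{path}: columns {want_w!r}/{want_a!r} not found in header {header}"
                )
    for i, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        parts = [p.strip() for p in line.split(",")]
        if len(parts) <= max(col_w, col_a):
            raise SpectrumFormatError(f"{path}: line {i}: expected >=2 columns")
        try:
            rows.append((float(parts[col_w]), float(parts[col_a])))
        except ValueError as exc:
            raise SpectrumFormatError(f"{path}: line {i}: {exc}") from None
    if not rows:
        raise SpectrumFormatError(f"{path}: no data rows")
    w = np.array([r[0] for r in rows])
    a = np.array([r[1] for r in rows])
    if np.unique(w).size != w.size:
        raise SpectrumFormatError(f"{path}: duplicate wavenumber in grid")
    order = np.argsort(w)[::-1]
    return Spectrum(w[order], a[order], path.stem if label is None else label)


def write_spectrum_csv(s: Spectrum, path: str | Path) -> None:
    """Write a spectrum as canonical two-column CSV (descending grid)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"{CSV_WAVENUMBER},{CSV_ABSORBANCE}\n")
        for w, a in zip(s.wavenumbers, s.absorbance):
            fh.write(f"{w:.10g},{a:.12g}\n")


# ---------------------------------------------------------------------------
# JCAMP-DX (read-only AFFN subset)

# Pseudo-digit characters of the SQZ/DIF/DUP compressed forms.  Note that a
# bare "E" inside a token that parses as a float is an exponent, not SQZ.
_PSEUDO_DIGITS = set("@ABCDEFGHIabcdefghiJKLMNOPQRjklmnopqrSTUVWXYZs%")


def _affn_tokens(line: str, path: Path) -> list[float]:
    out = []
    for tok in line.replace(",", " ").split():
        if _is_number(tok):
            out.append(float(tok))
        elif any(c in _PSEUDO_DIGITS for c in tok):
            raise UnsupportedFeatureError(
                f"{path}: SQZ/DIF/DUP compressed JCAMP data not supported"
            )
        else:
            raise SpectrumFormatError(f"{path}: unparseable token {tok!r}")
    return out


def read_spectrum_jcamp(path: str | Path) -> Spectrum:
    """Read a JCAMP-DX file (AFFN ``(X++(Y..Y))`` or ``XYPOINTS`` forms).

    Honors ##XFACTOR/##YFACTOR scaling and checks ##NPOINTS against the data
    count.  A missing ##XUNITS is assumed to be 1/CM with a warning;
    compressed (SQZ/DIF/DUP) data raises :class:`UnsupportedFeatureError`.
    """
    path = Path(path)
    header: dict[str, str] = {}
    data_lines: list[str] = []
    mode = None  # None | "xydata" | "xypoints"
    for raw in path.read_text(encoding="utf-8", errors="replace").splitlines():
        line = raw.split("$$", 1)[0].rstrip()
        if not line:
            continue
        if line.startswith("##"):
            key, _, value = line[2:].partition("=")
            key = key.strip().upper().replace(" ", "")
            value = value.strip()
            if key == "XYDATA":
                mode = "xydata"
                if "X++(Y..Y)" not in value.replace(" ", ""):
                    raise UnsupportedFeatureError(
                        f"{path}: unsupported XYDATA form {value!r}"
                    )
            elif key == "XYPOINTS":
                mode = "xypoints"
            elif key == "END":
                break
            else:
                header[key] = value
        elif mode is not None:
            data_lines.append(line)

    if mode is None:
        raise SpectrumFormatError(f"{path}: no ##XYDATA or ##XYPOINTS block")

    xunits = header.get("XUNITS", "")
    if not xunits:
        warnings.warn(f"{path}: missing ##XUNITS, assuming 1/CM", stacklevel=2)
    elif xunits.upper() not in {"1/CM", "CM-1", "CM^-1"}:
        raise UnsupportedFeatureError(f"{path}: unsupported XUNITS {xunits!r}")

    xfactor = float(header.get("XFACTOR", 1.0))
    yfactor = float(header.get("YFACTOR", 1.0))
    npoints = int(float(header["NPOINTS"])) if "NPOINTS" in header else None

    xs: list[float] = []
    ys: list[float] = []
    if mode == "xypoints":
        for line in data_lines:
            vals = _affn_tokens(line.replace(";", " "), path)
            if len(vals) % 2:
                raise SpectrumFormatError(f"{path}: odd token count in XYPOINTS line")
            xs.extend(vals[0::2])
            ys.extend(vals[1::2])
    else:
        starts: list[float] = []
        counts: list[int] = []
        for line in data_lines:
            vals = _affn_tokens(line, path)
            if len(vals) < 2:
                raise SpectrumFormatError(f"{path}: XYDATA line with no Y values")
            starts.append(vals[0])
            counts.append(len(vals) - 1)
            ys.extend(vals[1:])
        n = len(ys)
        if "FIRSTX" in header and "LASTX" in header and n > 1:
            firstx = float(header["FIRSTX"])
            lastx = float(header["LASTX"])
            xs = list(np.linspace(firstx, lastx, n) / xfactor)
        elif "DELTAX" in header:
            deltax = float(header["DELTAX"]) / xfactor
            xs = []
            for s0, c in zip(starts, counts):
                xs.extend(s0 + deltax * np.arange(c))
        elif len(starts) > 1:
            step = (starts[1] - starts[0]) / counts[0]
            xs = []
            for s0, c in zip(starts, counts):
                xs.extend(s0 + step * np.arange(c))
        else:
            # single line: spacing unknowable for >1 point
            if n > 1:
                raise SpectrumFormatError(
                    f"{path}: cannot infer X spacing (no FIRSTX/LASTX/DELTAX)"
                )
            xs = starts

    if npoints is not None and npoints != len(ys):
        raise SpectrumFormatError(
            f"{path}: NPOINTS={npoints} disagrees with {len(ys)} data values"
        )

    w = np.asarray(xs) * xfactor
    a = np.asarray(ys) * yfactor
    if np.unique(w).size != w.size:
        raise SpectrumFormatError(f"{path}: duplicate wavenumber in grid")
    order = np.argsort(w)[::-1]
    return Spectrum(w[order], a[order], path.stem)


def common_grid(spectra: Iterable[Spectrum]) -> np.ndarray:
    """Shared grid of a collection, or raise :class:`GridMismatchError`."""
    it = iter(spectra)
    first = next(it)
    for s in it:
        if not first.same_grid(s):
            raise GridMismatchError("spectra do not share a common grid")
    return first.wavenumbers
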