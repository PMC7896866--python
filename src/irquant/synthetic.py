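"""Synthetic ATR-FTIR spectra of powder mixtures.

The generator emulates the statistical structure the analysis pipeline
assumes, so calibration, factor selection, prediction and validation are all
exercisable with no instrument: absorbance over 2000-400 cm^-1 at 4 cm^-1
resolution, whose 1800-1300 cm^-1 analysis window is a mass-fraction-weighted
linear (Beer-Lambert) mixture of three component band profiles —

* analyte (sildenafil citrate surrogate): dominant band at 1697.6 cm^-1
  (its window maximum) plus further mid-intensity bands in the window,
* internal standard (paracetamol surrogate): bands at 1651.4, 1609.2,
  1562.2, 1505.2 and 1434.9 cm^-1,
* excipient matrix: broad (sigma >= 30 cm^-1), weak inside the window,
  stronger outside it —

corrupted per scan by a log-normal multiplicative gain (ATR contact
variability), a random linear baseline, independent jitter of the effective
local mass fractions (powder heterogeneity at different scan positions), and
additive white noise.  Band positions follow the real components; heights and
widths are fixture constants of this package, not fits to measured spectra.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` spawning, so campaigns are bit-reproducible.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .quantitation import DEFAULT_P_PAR, STOCK_CONTENT, MixtureRecord, design_r
from .spectra import ScanSet, Spectrum, make_grid


@dataclasses.dataclass(frozen=True)
class GaussianBand:
    center: float  # cm^-1
    height: float  # unitless specific absorbance
    sigma: float  # cm^-1


@dataclasses.dataclass
class BandTable:
    """Component band profiles for the three-component mixture model."""

    analyte: tuple[GaussianBand, ...]
    internal_standard: tuple[GaussianBand, ...]
    matrix: tuple[GaussianBand, ...]


def default_band_table() -> BandTable:
    """Fixture band table.

    Heights are balanced so the analyte and internal-standard profiles carry
    comparable signal energy inside the analysis window; with the scatter
    correction in the pipeline this puts the linear-regression error at the
    working ratio (R ~ 50 %) near the ~1 % relative level a real tablet
    system shows, rather than making the problem artificially easy or hard.
    """
    return BandTable(
        analyte=(
            GaussianBand(1697.6, 1.00, 9.0),  # window maximum
            GaussianBand(1770.0, 0.22, 12.0),
            GaussianBand(1585.0, 0.30, 9.0),
            GaussianBand(1528.0, 0.28, 9.0),
            GaussianBand(1454.0, 0.35, 10.0),
            GaussianBand(1358.0, 0.25, 10.0),
            GaussianBand(1265.0, 0.45, 12.0),  # outside the analysis window
        ),
        internal_standard=(
            GaussianBand(1651.4, 0.64, 9.0),
            GaussianBand(1609.2, 0.52, 8.0),
            GaussianBand(1562.2, 0.44, 8.0),
            GaussianBand(1505.2, 0.48, 8.0),
            GaussianBand(1434.9, 0.40, 9.0),
            GaussianBand(1242.0, 0.50, 12.0),  # outside the analysis window
            GaussianBand(836.0, 0.40, 10.0),
        ),
        matrix=(
            GaussianBand(1640.0, 0.05, 45.0),
            GaussianBand(1370.0, 0.07, 40.0),
            GaussianBand(1050.0, 0.50, 60.0),  # carbohydrate excipients, outside
        ),
    )


@dataclasses.dataclass
class NoiseModel:
    """Per-scan corruption parameters.

    ``scatter_sigma`` is the sd of the log-normal multiplicative gain,
    ``baseline_*`` draw a random linear baseline per scan, ``noise_sigma``
    is additive white noise per grid point, and ``heterogeneity_sigma`` is
    the sd of multiplicative jitter on the effective local mass fractions
    (powder inhomogeneity between scan positions).
    """

    scatter_sigma: float = 0.05
    baseline_slope_sigma: float = 1e-5  # absorbance per cm^-1
    baseline_offset_sigma: float = 5e-3
    noise_sigma: float = 2e-3
    heterogeneity_sigma: float = 0.01

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be >= 0")

    def scaled(self, factor: float) -> "NoiseModel":
        """All sigmas multiplied by ``factor`` (for stress tests)."""
        return NoiseModel(
            *(getattr(self, f.name) * factor for f in dataclasses.fields(self))
        )


NOISELESS = NoiseModel(0.0, 0.0, 0.0, 0.0, 0.0)


def component_spectrum(
    bands: Sequence[GaussianBand], grid: np.ndarray, label: str = ""
) -> Spectrum:
    """Sum of Gaussian bands evaluated on the grid; deterministic."""
    a = np.zeros_like(grid, dtype=float)
    for band in bands:
        a += band.height * np.exp(-((grid - band.center) ** 2) / (2.0 * band.sigma**2))
    return Spectrum(grid, a, label)


def mass_fractions(m: MixtureRecord, content: float | None = None) -> np.ndarray:
    """(analyte, internal standard, matrix) mass fractions of a mixture.

    ``content`` overrides the record's ``c_s`` — used when spectra must be
    generated from a *true* content while the record carries only a nominal
    or hidden one.
    """
    c_s = m.c_s if content is None else content
    if c_s is None:
        raise ValueError("mixture content unknown; pass content= explicitly")
    analyte = m.m_p * c_s
    internal = m.m_par * m.p_par
    matrix = m.m_p * (1.0 - c_s) + m.m_par * (1.0 - m.p_par)
    f = np.array([analyte, internal, matrix])
    return f / f.sum()


def mixture_spectrum(
    m: MixtureRecord,
    bands: BandTable,
    noise: NoiseModel | None,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
    grid: np.ndarray | None = None,
    content: float | None = None,
    label: str = "",
) -> Spectrum:
    """One simulated scan of a mixture; seeded and reproducible.

    ``noise=None`` means the default :class:`NoiseModel`.  With all noise
    sigmas zero the result is the exact fraction-weighted sum of the
    component spectra (Beer-Lambert linearity).
    """
    noise = NoiseModel() if noise is None else noise
    grid = make_grid() if grid is None else grid
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    f = mass_fractions(m, content)
    if noise.heterogeneity_sigma > 0:
        f = f * np.exp(rng.normal(0.0, noise.heterogeneity_sigma, size=3))
        f = f / f.sum()
    comps = [
        component_spectrum(bands.analyte, grid).absorbance,
        component_spectrum(bands.internal_standard, grid).absorbance,
        component_spectrum(bands.matrix, grid).absorbance,
    ]
    ideal = f[0] * comps[0] + f[1] * comps[1] + f[2] * comps[2]
    gain = float(np.exp(rng.normal(0.0, noise.scatter_sigma))) if noise.scatter_sigma else 1.0
    slope = rng.normal(0.0, noise.baseline_slope_sigma) if noise.baseline_slope_sigma else 0.0
    offset = rng.normal(0.0, noise.baseline_offset_sigma) if noise.baseline_offset_sigma else 0.0
    a = gain * ideal + offset + slope * (grid - grid.mean())
    if noise.noise_sigma:
        a = a + rng.normal(0.0, noise.noise_sigma, size=grid.size)
    return Spectrum(grid, a, label or m.mixture_id)


def _solve_powder_mass(
    target_r: float, total_mass: float, c_s: float, p_par: float
) -> float:
    """Powder mass m_p such that design R hits ``target_r`` at fixed total mass."""
    r = target_r / 100.0
    if not 0.0 < r < 1.0:
        raise ValueError(f"target R {target_r} outside (0, 100)")
    m_p = r * total_mass * p_par / (c_s * (1.0 - r) + r * p_par)
    if not 0.0 < m_p < total_mass:
        raise ValueError(f"target R {target_r} unsatisfiable at total mass {total_mass}")
    return m_p


DEFAULT_DESIGN: tuple[tuple[float, int], ...] = (
    (30.0, 2),
    (40.0, 2),
    (50.0, 2),
    (60.0, 2),
    (70.0, 2),
)


def simulate_calibration_campaign(
    design: Sequence[tuple[float, int]] = DEFAULT_DESIGN,
    scans_per_mixture: int = 10,
    noise: NoiseModel | None = None,
    seed: int = 0,
    bands: BandTable | None = None,
    c_s: float = STOCK_CONTENT,
    p_par: float = DEFAULT_P_PAR,
    total_mass: float = 360.0,
    prep_sigma: float = 0.3,
    grid: np.ndarray | None = None,
) -> tuple[list[ScanSet], dict[str, MixtureRecord]]:
    """Simulate the full working-standard campaign.

    For each (target R, duplicates) entry, masses are solved at a fixed
    total mixture mass so the designed R hits the target up to a random
    preparation error (sd ``prep_sigma`` percentage points), weighed masses
    are rounded to the 0.01 mg balance readability, and ``scans_per_mixture``
    seeded scans are generated.  Realized R values follow exactly from the
    recorded masses, so the regression labels carry no error.
    """
    bands = bands or default_band_table()
    noise = NoiseModel() if noise is None else noise
    grid = make_grid() if grid is None else grid
    ss_root = np.random.SeedSequence(seed)
    ss_prep, ss_scans = ss_root.spawn(2)
    rng_prep = np.random.default_rng(ss_prep)
    scan_seeds = iter(ss_scans.spawn(sum(d for _, d in design) * scans_per_mixture))

    scansets: list[ScanSet] = []
    records: dict[str, MixtureRecord] = {}
    for target, duplicates in design:
        for dup in range(1, duplicates + 1):
            realized_target = target + (
                rng_prep.normal(0.0, prep_sigma) if prep_sigma > 0 else 0.0
            )
            m_p = round(_solve_powder_mass(realized_target, total_mass, c_s, p_par), 2)
            m_par = round(total_mass - m_p, 2)
            mid = f"std{target:g}_{dup}"
            rec = MixtureRecord(
                m_p=m_p,
                m_par=m_par,
                p_par=p_par,
                c_s=c_s,
                role="standard",
                mixture_id=mid,
                level_label=f"{target:g}",
            )
            spectra = [
                mixture_spectrum(
                    rec, bands, noise, next(scan_seeds), grid, label=f"{mid}_scan{i}"
                )
                for i in range(scans_per_mixture)
            ]
            scansets.append(ScanSet(spectra, mid))
            records[mid] = rec
    return scansets, records


def simulate_test_mixture(
    true_content: float,
    noise: NoiseModel | None = None,
    seed: int = 0,
    scans: int = 5,
    nominal_content: float = STOCK_CONTENT,
    bands: BandTable | None = None,
    p_par: float = DEFAULT_P_PAR,
    m_par: float = 100.0,
    mixture_id: str = "test",
    grid: np.ndarray | None = None,
) -> tuple[ScanSet, MixtureRecord]:
    """Simulate one unknown test mixture.

    Masses are chosen so the *estimated* R is about 50 % under the nominal
    content; the spectra are generated from the *true* content, which the
    returned record does not carry (``c_s`` is ``None``) — the caller keeps
    the truth for scoring.
    """
    if not 0.0 < true_content < 1.0:
        raise ValueError("true_content must be a fraction in (0, 1)")
    bands = bands or default_band_table()
    noise = NoiseModel() if noise is None else noise
    grid = make_grid() if grid is None else grid
    # estimated R = 50 %  <=>  m_p * nominal_content == m_par * p_par
    m_p = round(m_par * p_par / nominal_content, 2)
    rec = MixtureRecord(
        m_p=m_p, m_par=m_par, p_par=p_par, c_s=None, role="test", mixture_id=mixture_id
    )
    seeds = np.random.SeedSequence(seed).spawn(scans)
    spectra = [
        mixture_spectrum(
            rec, bands, noise, seeds[i], grid, content=true_content,
            label=f"{mixture_id}_scan{i}",
        )
        for i in range(scans)
    ]
    return ScanSet(spectra, mixture_id), rec


def realized_r(records: dict[str, MixtureRecord]) -> dict[str, float]:
    """Designed R of every standard record, from its recorded masses."""
    return {mid: design_r(rec) for mid, rec in records.items()}
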