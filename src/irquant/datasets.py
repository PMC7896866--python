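"""Reference assay records for the worked examples and regression tests.

These are the printed bench records of a sildenafil-citrate tablet assay
using paracetamol as a solid internal standard: weighed masses (mg) and the
R value found for each replicate by the calibration model.  They exercise
the entire post-spectral arithmetic of the package (recovered mass, recovery
rate, content back-calculation, RSD) without any spectra — the same path the
CLI exposes as ``--from-r`` mode.

Each row is ``(m_p, m_par, r_found)``: tablet-powder mass, internal-standard
mass, found R (%).  The stock powder used for the accuracy study contained
``STOCK_CONTENT`` (37.94 % m/m) of analyte; the internal standard was 99.7 %
pure.
"""

from __future__ import annotations

from .quantitation import DEFAULT_P_PAR, STOCK_CONTENT

__all__ = [
    "ACCURACY_LEVELS",
    "PRECISION_DAY1",
    "PRECISION_DAY2",
    "BATCH_N531",
    "DEFAULT_P_PAR",
    "STOCK_CONTENT",
]

#: Accuracy (recovery) study: three R levels (~35 / 50 / 65 %), six
#: replicates each, as (m_p, m_par, found R).
ACCURACY_LEVELS: dict[str, list[tuple[float, float, float]]] = {
    "35": [
        (180.46, 131.07, 34.41),
        (180.35, 131.52, 34.06),
        (180.53, 131.64, 33.86),
        (184.16, 129.62, 35.44),
        (181.18, 130.13, 34.93),
        (182.42, 130.21, 34.90),
    ],
    "50": [
        (268.15, 99.28, 51.02),
        (268.38, 99.25, 50.97),
        (266.25, 99.06, 50.93),
        (268.92, 99.33, 51.02),
        (263.55, 100.29, 49.72),
        (267.32, 99.74, 50.38),
    ],
    "65": [
        (335.69, 71.68, 64.15),
        (334.62, 71.22, 63.77),
        (339.25, 69.43, 65.45),
        (337.47, 71.51, 64.00),
        (334.18, 71.56, 63.87),
        (335.22, 71.89, 63.86),
    ],
}

#: Repeatability: six same-day replicates at the working level (~50 % R).
#: These are the same preparations as the "50" accuracy level.
PRECISION_DAY1: list[tuple[float, float, float]] = list(ACCURACY_LEVELS["50"])

#: Second-day, second-analyst replicates pooled with day 1 for intermediate
#: precision (n = 12).
PRECISION_DAY2: list[tuple[float, float, float]] = [
    (268.12, 100.56, 50.26),
    (266.32, 100.32, 50.30),
    (269.15, 100.38, 50.36),
    (268.06, 100.66, 50.69),
    (264.35, 101.43, 49.37),
    (265.43, 100.27, 50.90),
]

#: Application run: six replicates of a market batch of unknown content.
BATCH_N531: list[tuple[float, float, float]] = [
    (267.28, 100.08, 49.95),
    (269.33, 100.21, 50.88),
    (270.14, 100.13, 50.53),
    (269.66, 100.22, 50.86),
    (268.47, 100.37, 50.36),
    (268.35, 100.04, 51.06),
]
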