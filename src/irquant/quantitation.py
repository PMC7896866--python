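"""Mass-ratio design arithmetic, back-calculation, and assay validation.

The internal-standard design: a tablet powder of analyte mass content c_s
(fraction, m/m) is weighed (m_p, mg) and mixed with the internal standard
paracetamol (m_par, mg, purity p_par).  The designed mass ratio is

    R (%) = 100 * m_p*c_s / (m_p*c_s + m_par*p_par)

and once a calibration model returns a *found* R for a test mixture, the
analyte content of the original powder is back-calculated as

    C (% m/m) = 100 * [R / (100 - R)] * m_par * p_par / m_p,

the exact algebraic inverse of the design equation.  Validation follows the
ICH Q2 pattern: recovery at three R levels (~35/50/65 %), repeatability
(n=6, one day) and intermediate precision (n=12, two days), with the
conventional acceptance limits of 98.0-102.0 % mean recovery and RSD <= 2.0 %.

All internal arithmetic is double precision; rounding (half-up) happens only
at the presentation layer: one decimal for percentages, two for masses in mg.
"""

from __future__ import annotations

import dataclasses
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chemometrics import CalibrationModel, predict_r
from .exceptions import ValidationDesignError
from .spectra import ScanSet

#: Default purity of the pharmaceutical-grade paracetamol internal standard.
DEFAULT_P_PAR = 0.997

#: Analyte mass content of the stock standard tablet powder (fraction, m/m),
#: as assayed by the reference HPLC method.
STOCK_CONTENT = 0.3794

#: Alternative stock-content constant reported by a second assay run of the
#: same material; selectable by configuration, never silently substituted.
ALT_STOCK_CONTENT = 0.3764

RECOVERY_LIMITS = (98.0, 102.0)
RSD_LIMIT = 2.0


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding for presentation values."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclasses.dataclass
class MixtureRecord:
    """Masses and purities defining one standard or test mixture.

    ``c_s`` is the analyte content of the tablet powder: known for standard
    mixtures prepared from stock material, ``None`` for unknowns.
    """

    m_p: float  # tablet powder mass, mg
    m_par: float  # internal standard mass, mg
    p_par: float = DEFAULT_P_PAR
    c_s: float | None = None
    role: str = "standard"
    mixture_id: str = ""
    level_label: str = ""

    def __post_init__(self) -> None:
        if not self.m_p > 0:
            raise ValueError(f"m_p must be positive (got {self.m_p})")
        if self.m_par < 0:
            raise ValueError(f"m_par must be non-negative (got {self.m_par})")
        if not 0 < self.p_par <= 1:
            raise ValueError(f"p_par must be in (0, 1] (got {self.p_par})")
        if self.c_s is not None and not 0 < self.c_s < 1:
            raise ValueError(f"c_s must be in (0, 1) (got {self.c_s})")
        if self.role not in ("standard", "test"):
            raise ValueError(f"role must be 'standard' or 'test' (got {self.role!r})")


def design_r(m: MixtureRecord) -> float:
    """Designed mass ratio R (%) of a mixture with known powder content."""
    if m.c_s is None:
        raise ValueError("design_r requires a known c_s")
    analyte = m.m_p * m.c_s
    internal = m.m_par * m.p_par
    return 100.0 * analyte / (analyte + internal)


def content_from_r(r: float, m: MixtureRecord) -> float:
    """Back-calculated analyte content C (% m/m) of the tablet powder."""
    if not 0.0 < r < 100.0:
        raise ValueError(f"R must be in (0, 100) (got {r})")
    return 100.0 * (r / (100.0 - r)) * m.m_par * m.p_par / m.m_p


def recovered_mass(r: float, m_par: float, p_par: float = DEFAULT_P_PAR) -> float:
    """Analyte mass (mg) implied by a found R and the weighed internal standard."""
    if not 0.0 < r < 100.0:
        raise ValueError(f"R must be in (0, 100) (got {r})")
    return (r / (100.0 - r)) * m_par * p_par


def recovery_rate(recovered: float, m_p: float, c_s: float) -> float:
    """Recovered analyte mass as a percentage of the nominally present mass."""
    if not (m_p > 0 and c_s > 0):
        raise ValueError("m_p and c_s must be positive")
    return 100.0 * recovered / (m_p * c_s)


def rsd(values: Sequence[float]) -> float:
    """Relative standard deviation (%), sample (n-1) standard deviation."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("rsd requires at least 2 values")
    mean = v.mean()
    if mean == 0.0:
        raise ValueError("rsd undefined for zero mean")
    return float(100.0 * v.std(ddof=1) / mean)


# ---------------------------------------------------------------------------
# spectra-free replay of printed assay records (the --from-r path)


def recovery_table(
    rows: Sequence[tuple[float, float, float]],
    p_par: float = DEFAULT_P_PAR,
    c_s: float = STOCK_CONTENT,
) -> pd.DataFrame:
    """Recovery statistics from (m_p, m_par, found R) triples.

    Returns one row per replicate with full-precision ``recovered_mg`` and
    ``recovery_pct`` columns plus presentation-rounded twins.
    """
    out = []
    for m_p, m_par, r in rows:
        rec = recovered_mass(r, m_par, p_par)
        rate = recovery_rate(rec, m_p, c_s)
        out.append(
            {
                "m_p_mg": m_p,
                "m_par_mg": m_par,
                "r_found": r,
                "recovered_mg": rec,
                "recovery_pct": rate,
                "recovered_mg_2dp": round_half_up(rec, 2),
                "recovery_pct_1dp": round_half_up(rate, 1),
            }
        )
    return pd.DataFrame(out)


def content_table(
    rows: Sequence[tuple[float, float, float]],
    p_par: float = DEFAULT_P_PAR,
) -> pd.DataFrame:
    """Contents (% m/m) from (m_p, m_par, found R) triples via the inverse
    design equation, full precision plus 1-dp presentation column."""
    out = []
    for m_p, m_par, r in rows:
        rec = MixtureRecord(m_p=m_p, m_par=m_par, p_par=p_par, role="test")
        c = content_from_r(r, rec)
        out.append(
            {
                "m_p_mg": m_p,
                "m_par_mg": m_par,
                "r_found": r,
                "content_pct": c,
                "content_pct_1dp": round_half_up(c, 1),
            }
        )
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# quantitation of scanned test mixtures


@dataclasses.dataclass
class QuantResult:
    """Per-scan predictions and the back-calculated content of one mixture."""

    r_per_scan: list[float]
    r_mean: float
    content: float  # % m/m
    mixture: MixtureRecord

    @property
    def r_sd(self) -> float:
        return float(np.std(self.r_per_scan, ddof=1)) if len(self.r_per_scan) > 1 else 0.0


def quantify(model: CalibrationModel, scans: ScanSet, m: MixtureRecord) -> QuantResult:
    """Predict R for every scan of a test mixture and back-calculate content.

    Per-scan R values are aggregated by arithmetic mean; the per-scan list is
    retained for dispersion reporting.  Any scan failing preprocessing aborts
    with the scan index in the message.
    """
    if len(scans) == 0:
        raise ValueError("quantify: empty scan set")
    rs = []
    for i, s in enumerate(scans.spectra):
        try:
            rs.append(predict_r(model, s))
        except Exception as exc:
            raise type(exc)(f"scan {i} of {scans.mixture_id!r}: {exc}") from exc
    r_mean = float(np.mean(rs))
    return QuantResult(rs, r_mean, content_from_r(r_mean, m), m)


# ---------------------------------------------------------------------------
# validation battery


@dataclasses.dataclass
class RecoveryLevel:
    label: str
    table: pd.DataFrame  # per-replicate found R / recovered mg / rate
    mean_recovery: float
    rsd_recovery: float
    pass_recovery: bool
    pass_rsd: bool


@dataclasses.dataclass
class PrecisionSummary:
    n: int
    mean_content: float
    rsd_content: float
    pass_rsd: bool


@dataclasses.dataclass
class ValidationReport:
    """Recovery per level plus repeatability / intermediate-precision summaries."""

    levels: list[RecoveryLevel]
    repeatability: PrecisionSummary
    intermediate: PrecisionSummary | None
    linearity_r: float | None  # model correlation over the calibrated R range
    r_range: tuple[float, float] | None

    @property
    def all_pass(self) -> bool:
        ok = all(lv.pass_recovery and lv.pass_rsd for lv in self.levels)
        ok = ok and self.repeatability.pass_rsd
        if self.intermediate is not None:
            ok = ok and self.intermediate.pass_rsd
        return ok


def validate(
    model: CalibrationModel,
    recovery_groups: Mapping[str, Sequence[tuple[ScanSet, MixtureRecord]]],
    repeatability: Sequence[tuple[ScanSet, MixtureRecord]] | None = None,
    intermediate: Sequence[tuple[ScanSet, MixtureRecord]] | None = None,
    min_levels: int = 3,
    min_replicates: int = 6,
    recovery_limits: tuple[float, float] = RECOVERY_LIMITS,
    rsd_limit: float = RSD_LIMIT,
) -> ValidationReport:
    """Run the accuracy/precision battery on scanned standard mixtures.

    ``recovery_groups`` maps a level label (e.g. "35", "50", "65") to its
    replicate (scans, record) pairs; records must carry a known ``c_s``.
    ``repeatability`` defaults to the replicates of the level whose mean
    designed R is closest to 50 %.  ``intermediate``, when given, is pooled
    with the repeatability replicates (second day / second analyst).
    """
    if len(recovery_groups) < min_levels:
        raise ValidationDesignError(
            f"need >= {min_levels} recovery levels, got {len(recovery_groups)}"
        )
    levels: list[RecoveryLevel] = []
    contents_by_label: dict[str, list[float]] = {}
    mean_r_by_label: dict[str, float] = {}
    for label, reps in recovery_groups.items():
        if len(reps) < min_replicates:
            raise ValidationDesignError(
                f"level {label!r}: {len(reps)} replicates, need >= {min_replicates}"
            )
        rows = []
        contents = []
        for scans, rec in reps:
            if rec.c_s is None:
                raise ValidationDesignError(
                    f"level {label!r}: record {rec.mixture_id!r} lacks c_s"
                )
            q = quantify(model, scans, rec)
            recd = recovered_mass(q.r_mean, rec.m_par, rec.p_par)
            rate = recovery_rate(recd, rec.m_p, rec.c_s)
            contents.append(q.content)
            rows.append(
                {
                    "mixture_id": rec.mixture_id,
                    "r_found": q.r_mean,
                    "recovered_mg": recd,
                    "recovery_pct": rate,
                }
            )
        table = pd.DataFrame(rows)
        mean_rec = float(table["recovery_pct"].mean())
        rsd_rec = rsd(table["recovery_pct"])
        levels.append(
            RecoveryLevel(
                label=label,
                table=table,
                mean_recovery=mean_rec,
                rsd_recovery=rsd_rec,
                pass_recovery=recovery_limits[0] <= mean_rec <= recovery_limits[1],
                pass_rsd=rsd_rec <= rsd_limit,
            )
        )
        contents_by_label[label] = contents
        mean_r_by_label[label] = float(
            np.mean([design_r(rec) for _, rec in reps])
        )

    if repeatability is None:
        mid = min(mean_r_by_label, key=lambda lb: abs(mean_r_by_label[lb] - 50.0))
        rep_contents = contents_by_label[mid]
    else:
        if len(repeatability) < min_replicates:
            raise ValidationDesignError(
                f"repeatability: {len(repeatability)} replicates, "
                f"need >= {min_replicates}"
            )
        rep_contents = [
            quantify(model, scans, rec).content for scans, rec in repeatability
        ]
    rep = PrecisionSummary(
        n=len(rep_contents),
        mean_content=float(np.mean(rep_contents)),
        rsd_content=rsd(rep_contents),
        pass_rsd=rsd(rep_contents) <= rsd_limit,
    )

    inter = None
    if intermediate is not None:
        pooled = list(rep_contents) + [
            quantify(model, scans, rec).content for scans, rec in intermediate
        ]
        inter = PrecisionSummary(
            n=len(pooled),
            mean_content=float(np.mean(pooled)),
            rsd_content=rsd(pooled),
            pass_rsd=rsd(pooled) <= rsd_limit,
        )

    diag = model.diagnostics
    return ValidationReport(
        levels=levels,
        repeatability=rep,
        intermediate=inter,
        linearity_r=min(diag.r_c, diag.r_v) if diag else None,
        r_range=(30.0, 70.0),
    )


# ---------------------------------------------------------------------------
# mixture manifest I/O

MANIFEST_COLUMNS = [
    "mixture_id",
    "role",
    "m_p_mg",
    "m_par_mg",
    "p_par",
    "c_s",
    "level_label",
]


def write_manifest(records: Sequence[MixtureRecord], path: str | Path) -> None:
    rows = [
        {
            "mixture_id": r.mixture_id,
            "role": r.role,
            "m_p_mg": r.m_p,
            "m_par_mg": r.m_par,
            "p_par": r.p_par,
            "c_s": "" if r.c_s is None else r.c_s,
            "level_label": r.level_label,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a mixture manifest CSV; returns the raw frame (extra columns such
    as ``r_found`` are preserved for the --from-r replay mode)."""
    df = pd.read_csv(path, dtype={"mixture_id": str, "role": str, "level_label": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns and c != "level_label"]
    if missing:
        raise ValueError(f"{path}: manifest missing columns {missing}")
    return df


def record_from_row(row: Mapping) -> MixtureRecord:
    c_s = row.get("c_s")
    if c_s is None or (isinstance(c_s, float) and np.isnan(c_s)) or c_s == "":
        c_s = None
    else:
        c_s = float(c_s)
    return MixtureRecord(
        m_p=float(row["m_p_mg"]),
        m_par=float(row["m_par_mg"]),
        p_par=float(row.get("p_par", DEFAULT_P_PAR)),
        c_s=c_s,
        role=str(row.get("role", "standard")),
        mixture_id=str(row.get("mixture_id", "")),
        level_label="" if pd.isna(row.get("level_label", "")) else str(row.get("level_label", "")),
    )
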