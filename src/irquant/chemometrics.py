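"""PLS-1 calibration between preprocessed spectra and the mass ratio R.

The regression target R is the mass percentage of analyte over
(analyte + internal standard) in a mixture.  Calibration follows the
one-split design: the repeated scans of each standard mixture are divided
randomly (seeded) into a calibration part (8 scans by default) and a
validation part (2 scans), the split is made per mixture so every mixture
contributes to both sets, and a factor scan reports RMSEC/RMSEV and the
Pearson correlations r_c / r_v for k = 1..k_max latent factors on that one
split.  The selected factor count is the smallest k whose r_c and r_v both
reach the threshold (0.998 by default).

The normative PLS algorithm is NIPALS for a univariate response: per factor,
the weight w is the normalized covariance direction X'y, scores t = Xw,
loadings p = X't/(t't) and q = y't/(t't), then X and y are deflated.  The
final regression vector is b = W (P'W)^{-1} q on centered data.  Factors are
nested, so one fit at k_max yields the whole factor scan.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .exceptions import (
    ModelSchemaError,
    ModelSelectionError,
    WindowMismatchError,
)
from .preprocess import PreprocessParams, msc_fit, normalize_at, preprocess_pipeline
from .spectra import ScanSet, Spectrum, extract_window

MODEL_SCHEMA = "irquant.calibration-model/1"


# ---------------------------------------------------------------------------
# elementary statistics


def rmse(pred: Sequence[float], true: Sequence[float]) -> float:
    """Root mean square error, in R percentage-point units."""
    p = np.asarray(pred, dtype=float)
    t = np.asarray(true, dtype=float)
    if p.shape != t.shape or p.size == 0:
        raise ValueError(f"rmse: shapes {p.shape} and {t.shape} incompatible")
    return float(np.sqrt(np.mean((p - t) ** 2)))


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation coefficient."""
    a = np.asarray(x, dtype=float)
    b = np.asarray(y, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("pearson_r: need equal-length inputs of size >= 3")
    ac = a - a.mean()
    bc = b - b.mean()
    va = float(ac @ ac)
    vb = float(bc @ bc)
    if va == 0.0 or vb == 0.0:
        raise ValueError("pearson_r: constant input")
    return float((ac @ bc) / np.sqrt(va * vb))


# ---------------------------------------------------------------------------
# NIPALS PLS-1


@dataclasses.dataclass
class PLS1Fit:
    """Centered NIPALS PLS-1 factors (nested: the first k columns give the
    k-factor model)."""

    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray  # (p, k) columns w_j, unit length
    x_loadings: np.ndarray  # (p, k) columns p_j
    y_loadings: np.ndarray  # (k,) scalars q_j
    n_factors: int

    def coef(self, k: int | None = None) -> np.ndarray:
        """Regression vector b for the first ``k`` factors (centered form)."""
        k = self.n_factors if k is None else k
        if not 1 <= k <= self.n_factors:
            raise ValueError(f"k={k} outside 1..{self.n_factors}")
        W = self.weights[:, :k]
        P = self.x_loadings[:, :k]
        q = self.y_loadings[:k]
        return W @ np.linalg.solve(P.T @ W, q)

    def predict(self, X: np.ndarray, k: int | None = None) -> np.ndarray:
        return self.y_mean + (np.asarray(X, dtype=float) - self.x_mean) @ self.coef(k)


def nipals_pls1(X: np.ndarray, y: np.ndarray, k: int) -> PLS1Fit:
    """Fit a univariate-response PLS model by NIPALS.

    ``X`` holds one preprocessed spectrum per row; ``y`` the R values (%).
    Data are centered internally and the means stored.  If the residual
    collapses before ``k`` factors, the achieved number is returned with a
    warning.  Deterministic given its inputs.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < 2:
        raise ValueError("nipals_pls1: need at least 2 calibration spectra")
    if y.shape != (n,):
        raise ValueError("nipals_pls1: y length must match rows of X")
    if not 1 <= k <= min(n - 1, p):
        raise ValueError(f"nipals_pls1: k={k} outside 1..min(n-1={n - 1}, p={p})")
    if np.ptp(y) == 0.0:
        raise ValueError("nipals_pls1: zero-variance response")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    E = X - x_mean
    f = y - y_mean

    W = np.zeros((p, k))
    P = np.zeros((p, k))
    q = np.zeros(k)
    achieved = 0
    for j in range(k):
        w = E.T @ f
        nw = np.linalg.norm(w)
        if nw < 1e-12:
            warnings.warn(
                f"nipals_pls1: residual collapsed after {achieved} factors "
                f"(requested {k})",
                stacklevel=2,
            )
            break
        w /= nw
        t = E @ w
        tt = float(t @ t)
        if tt < 1e-24:
            warnings.warn(
                f"nipals_pls1: score variance collapsed after {achieved} factors",
                stacklevel=2,
            )
            break
        pj = E.T @ t / tt
        qj = float(f @ t) / tt
        E = E - np.outer(t, pj)
        f = f - qj * t
        W[:, j], P[:, j], q[j] = w, pj, qj
        achieved += 1

    if achieved == 0:
        raise ValueError("nipals_pls1: response uncorrelated with spectra")
    return PLS1Fit(x_mean, y_mean, W[:, :achieved], P[:, :achieved], q[:achieved], achieved)


# ---------------------------------------------------------------------------
# split plan


@dataclasses.dataclass
class SplitPlan:
    """Seeded per-mixture partition of repeated scans.

    Defaults follow the 10-scans-per-standard design: 8 scans to the
    calibration set and 2 to the validation set from every mixture, so each
    mixture (and hence each R level) is represented in both sets.
    """

    seed: int = 0
    n_cal: int = 8
    n_val: int = 2


def split_calibration_validation(
    scansets: Sequence[ScanSet],
    r_true: Mapping[str, float],
    plan: SplitPlan,
) -> tuple[list[tuple[Spectrum, float]], list[tuple[Spectrum, float]]]:
    """Partition scans into calibration and validation sets.

    ``r_true`` maps mixture_id to the mixture's designed R value.  Returns
    two lists of (spectrum, R) pairs.  Reproducible: the same seed yields
    the identical partition.
    """
    rng = np.random.default_rng(plan.seed)
    cal: list[tuple[Spectrum, float]] = []
    val: list[tuple[Spectrum, float]] = []
    for ss in scansets:
        n = len(ss)
        if n < plan.n_cal + plan.n_val:
            raise ValueError(
                f"mixture {ss.mixture_id!r} has {n} scans, "
                f"needs {plan.n_cal + plan.n_val}"
            )
        r = float(r_true[ss.mixture_id])
        perm = rng.permutation(n)
        for i in perm[: plan.n_cal]:
            cal.append((ss.spectra[i], r))
        for i in perm[plan.n_cal : plan.n_cal + plan.n_val]:
            val.append((ss.spectra[i], r))
    return cal, val


# ---------------------------------------------------------------------------
# factor scan and selection


@dataclasses.dataclass
class FactorScanRow:
    """Diagnostics of the k-factor model on the fixed calibration split."""

    k: int
    rmsec: float
    rmsev: float
    r_c: float
    r_v: float
    rel_err_at_working: float | None  # mean |pred-true|/true x100 near working R

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def _prepare_xy(
    scansets: Sequence[ScanSet],
    r_true: Mapping[str, float],
    plan: SplitPlan,
    params: PreprocessParams,
) -> tuple[PreprocessParams, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Window+normalize all scans, split, freeze the MSC reference on the
    calibration part, and return matrices for both parts."""
    cal, val = split_calibration_validation(scansets, r_true, plan)
    norm = lambda s: normalize_at(
        extract_window(s, params.window_lo, params.window_hi), params.norm_wavenumber
    )
    cal_n = [(norm(s), r) for s, r in cal]
    val_n = [(norm(s), r) for s, r in val]
    reference = msc_fit([s for s, _ in cal_n])
    frozen = PreprocessParams(
        params.window_lo, params.window_hi, params.norm_wavenumber, reference
    )
    from .preprocess import msc_apply  # local to avoid cycle at import time

    X_cal = np.vstack([msc_apply(s, reference).absorbance for s, _ in cal_n])
    X_val = np.vstack([msc_apply(s, reference).absorbance for s, _ in val_n])
    y_cal = np.array([r for _, r in cal_n])
    y_val = np.array([r for _, r in val_n])
    return frozen, X_cal, y_cal, X_val, y_val


def factor_scan(
    scansets: Sequence[ScanSet],
    r_true: Mapping[str, float],
    plan: SplitPlan,
    k_max: int,
    params: PreprocessParams | None = None,
    working_level: float = 50.0,
    working_band: float = 5.0,
) -> list[FactorScanRow]:
    """Try k = 1..k_max factors on one seeded split and report diagnostics.

    ``rel_err_at_working`` is the mean relative error (x100) over validation
    spectra whose true R lies within ``working_band`` percentage points of
    ``working_level``; it is ``None`` when no validation spectrum falls in
    that band.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    params = params or PreprocessParams()
    _, X_cal, y_cal, X_val, y_val = _prepare_xy(scansets, r_true, plan, params)
    k_cap = min(k_max, X_cal.shape[0] - 1, X_cal.shape[1])
    fit = nipals_pls1(X_cal, y_cal, k_cap)
    near = np.abs(y_val - working_level) <= working_band
    rows = []
    for k in range(1, fit.n_factors + 1):
        pc = fit.predict(X_cal, k)
        pv = fit.predict(X_val, k)
        rel = None
        if near.any():
            rel = float(np.mean(np.abs(pv[near] - y_val[near]) / y_val[near]) * 100.0)
        rows.append(
            FactorScanRow(
                k=k,
                rmsec=rmse(pc, y_cal),
                rmsev=rmse(pv, y_val),
                r_c=pearson_r(pc, y_cal),
                r_v=pearson_r(pv, y_val),
                rel_err_at_working=rel,
            )
        )
    return rows


def select_factors(scan: Sequence[FactorScanRow], r_threshold: float = 0.998) -> int:
    """Smallest k whose r_c and r_v both reach the threshold.

    Returning the *first* qualifying k also honors the overfitting guard:
    a larger qualifying k with a larger RMSEV-RMSEC gap is never preferred.
    """
    if not scan:
        raise ValueError("empty factor scan")
    for row in scan:
        if row.r_c >= r_threshold and row.r_v >= r_threshold:
            return row.k
    best = max(scan, key=lambda r: min(r.r_c, r.r_v))
    raise ModelSelectionError(
        f"no factor count reaches r >= {r_threshold}; best was k={best.k} "
        f"with r_c={best.r_c:.5f}, r_v={best.r_v:.5f}"
    )


# ---------------------------------------------------------------------------
# calibration model


@dataclasses.dataclass
class CalibrationModel:
    """Frozen preprocessing + PLS regression + diagnostics for the chosen k."""

    preprocess: PreprocessParams
    pls: PLS1Fit
    n_factors: int
    regression_vector: np.ndarray
    diagnostics: FactorScanRow
    factor_scan: list[FactorScanRow]
    seed: int

    @property
    def rmsec(self) -> float:
        return self.diagnostics.rmsec

    @property
    def rmsev(self) -> float:
        return self.diagnostics.rmsev


def calibrate(
    scansets: Sequence[ScanSet],
    r_true: Mapping[str, float],
    plan: SplitPlan | None = None,
    params: PreprocessParams | None = None,
    k_max: int = 10,
    r_threshold: float = 0.998,
    n_factors: int | None = None,
    working_level: float = 50.0,
) -> CalibrationModel:
    """Fit the full calibration: preprocess, split, factor scan, select, fit.

    ``n_factors`` overrides the automatic selection rule when given.  The
    final regression is fitted on the calibration part of the split only;
    the validation part serves exclusively for the scan diagnostics.
    """
    plan = plan or SplitPlan()
    params = params or PreprocessParams()
    frozen, X_cal, y_cal, _, _ = _prepare_xy(scansets, r_true, plan, params)
    rows = factor_scan(scansets, r_true, plan, k_max, params, working_level)
    k = int(n_factors) if n_factors is not None else select_factors(rows, r_threshold)
    if not 1 <= k <= rows[-1].k:
        raise ValueError(f"n_factors={k} outside the scanned range 1..{rows[-1].k}")
    fit = nipals_pls1(X_cal, y_cal, rows[-1].k)
    return CalibrationModel(
        preprocess=frozen,
        pls=fit,
        n_factors=k,
        regression_vector=fit.coef(k),
        diagnostics=rows[k - 1],
        factor_scan=rows,
        seed=plan.seed,
    )


def predict_r(model: CalibrationModel, s: Spectrum) -> float:
    """Predict the R value (%) of one scan through the frozen pipeline."""
    x = preprocess_pipeline(s, model.preprocess)
    if len(x) != model.pls.x_mean.size:
        raise WindowMismatchError(
            f"preprocessed spectrum has {len(x)} points, "
            f"model expects {model.pls.x_mean.size}"
        )
    value = model.pls.y_mean + float(
        (x.absorbance - model.pls.x_mean) @ model.regression_vector
    )
    if not np.isfinite(value):
        raise WindowMismatchError("non-finite prediction")
    return value


# ---------------------------------------------------------------------------
# persistence


def save_model(model: CalibrationModel, path: str | Path) -> None:
    """Write the model as versioned, human-diffable JSON."""
    ref = model.preprocess.msc_reference
    doc = {
        "schema": MODEL_SCHEMA,
        "preprocess": {
            "window_lo": model.preprocess.window_lo,
            "window_hi": model.preprocess.window_hi,
            "norm_wavenumber": model.preprocess.norm_wavenumber,
            "msc_reference_wavenumbers": ref.wavenumbers.tolist() if ref else None,
            "msc_reference_absorbance": ref.absorbance.tolist() if ref else None,
        },
        "pls": {
            "x_mean": model.pls.x_mean.tolist(),
            "y_mean": model.pls.y_mean,
            "weights": model.pls.weights.tolist(),
            "x_loadings": model.pls.x_loadings.tolist(),
            "y_loadings": model.pls.y_loadings.tolist(),
            "n_factors_fitted": model.pls.n_factors,
        },
        "n_factors": model.n_factors,
        "regression_vector": model.regression_vector.tolist(),
        "diagnostics": model.diagnostics.as_dict(),
        "factor_scan": [r.as_dict() for r in model.factor_scan],
        "seed": model.seed,
    }
    Path(path).write_text(json.dumps(doc, indent=1), encoding="utf-8")


def load_model(path: str | Path) -> CalibrationModel:
    """Read a model file written by :func:`save_model`."""
    try:
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise ModelSchemaError(f"{path}: not a valid model file ({exc})") from None
    if not isinstance(doc, dict) or doc.get("schema") != MODEL_SCHEMA:
        raise ModelSchemaError(
            f"{path}: schema {doc.get('schema') if isinstance(doc, dict) else None!r} "
            f"!= {MODEL_SCHEMA!r}"
        )
    pp = doc["preprocess"]
    ref = None
    if pp["msc_reference_wavenumbers"] is not None:
        ref = Spectrum(
            np.array(pp["msc_reference_wavenumbers"]),
            np.array(pp["msc_reference_absorbance"]),
            "msc_reference",
        )
    params = PreprocessParams(pp["window_lo"], pp["window_hi"], pp["norm_wavenumber"], ref)
    pls = PLS1Fit(
        x_mean=np.array(doc["pls"]["x_mean"]),
        y_mean=float(doc["pls"]["y_mean"]),
        weights=np.array(doc["pls"]["weights"]),
        x_loadings=np.array(doc["pls"]["x_loadings"]),
        y_loadings=np.array(doc["pls"]["y_loadings"]),
        n_factors=int(doc["pls"]["n_factors_fitted"]),
    )
    rows = [FactorScanRow(**r) for r in doc["factor_scan"]]
    return CalibrationModel(
        preprocess=params,
        pls=pls,
        n_factors=int(doc["n_factors"]),
        regression_vector=np.array(doc["regression_vector"]),
        diagnostics=FactorScanRow(**doc["diagnostics"]),
        factor_scan=rows,
        seed=int(doc["seed"]),
    )
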