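"""ICH M10 / EMA bioanalytical method validation engine.

Calibration is ordinary least squares of the analyte/IS peak-area ratio
on nominal concentration (an optional 1/x^2 weighting is available but
not the default). Acceptance gates follow ICH M10: at least 75% of
calibrators back-calculating within +/-15% of nominal and the LLOQ
within +/-20%; precision and accuracy within +/-15% (20% at the LLOQ);
IS-normalized matrix factor within 0.8-1.2 with CV <= 15%.

LOD and LOQ come from the calibration-curve approach across independent
assays: LOD = 3.3 sigma / S and LOQ = 10 sigma / S, with sigma the
standard deviation of the fitted intercepts and S the mean slope, so
LOQ/LOD = 10/3.3 by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CalibrationFit",
    "CalibrationSummary",
    "GateRecord",
    "QCBatch",
    "RecoveryResult",
    "MatrixEffectResult",
    "QuantResult",
    "fit_calibration",
    "calibration_acceptance",
    "lod_loq",
    "precision_accuracy",
    "recovery",
    "matrix_effect",
    "quantify",
    "homogenate_to_tissue",
    "tissue_to_homogenate",
]


@dataclass(frozen=True)
class GateRecord:
    name: str
    observed: float
    limit: float
    passed: bool
    detail: str = ""


@dataclass(frozen=True)
class CalibrationFit:
    slope: float
    intercept: float
    r_squared: float
    calibrators: pd.DataFrame = field(compare=False)  # nominal, ratio, back_calc, pct_dev
    assay_id: str = ""
    weighted: bool = False


def fit_calibration(
    calibrators: Sequence[tuple[float, float]] | pd.DataFrame,
    assay_id: str = "",
    weighting: str | None = None,
) -> CalibrationFit:
    """Fit area ratio vs nominal concentration over >=6 non-zero levels.

    ``weighting='1/x2'`` performs weighted least squares with weights
    1/nominal^2; default is unweighted OLS. Back-calculated
    concentrations (ratio - intercept)/slope and percent deviations are
    attached per calibrator.
    """
    if isinstance(calibrators, pd.DataFrame):
        x = calibrators["nominal"].to_numpy(dtype=float)
        y = calibrators["area_ratio"].to_numpy(dtype=float)
    else:
        arr = np.asarray(calibrators, dtype=float)
        x, y = arr[:, 0], arr[:, 1]
    if len(set(np.round(x, 12))) < 6:
        raise ValueError("need >=6 distinct non-zero calibrator levels")
    if np.any(x <= 0):
        raise ValueError("calibrator concentrations must be > 0")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in concentrations")

    if weighting == "1/x2":
        w = 1.0 / x**2
        W = np.sum(w)
        xm = np.sum(w * x) / W
        ym = np.sum(w * y) / W
        slope = np.sum(w * (x - xm) * (y - ym)) / np.sum(w * (x - xm) ** 2)
        intercept = ym - slope * xm
        yhat = intercept + slope * x
        ss_res = np.sum(w * (y - yhat) ** 2)
        ss_tot = np.sum(w * (y - ym) ** 2)
        r2 = 1 - ss_res / ss_tot
        weighted = True
    elif weighting is None:
        res = stats.linregress(x, y)
        slope, intercept, r2 = float(res.slope), float(res.intercept), float(res.rvalue**2)
        weighted = False
    else:
        raise ValueError(f"unknown weighting {weighting!r}")

    back = (y - intercept) / slope
    table = pd.DataFrame({
        "nominal": x,
        "area_ratio": y,
        "back_calc": back,
        "pct_dev": 100.0 * (back - x) / x,
    })
    return CalibrationFit(
        slope=float(slope), intercept=float(intercept), r_squared=float(r2),
        calibrators=table, assay_id=assay_id, weighted=weighted,
    )


def calibration_acceptance(
    fit: CalibrationFit,
    lloq_level: float | None = None,
    pct_limit: float = 15.0,
    lloq_pct_limit: float = 20.0,
    min_fraction: float = 0.75,
) -> GateRecord:
    """ICH calibration gate: >=75% of calibrators within +/-15% of
    nominal and the LLOQ within +/-20%."""
    tab = fit.calibrators
    if lloq_level is None:
        lloq_level = float(tab["nominal"].min())
    within = (tab["pct_dev"].abs() <= pct_limit)
    frac = float(within.mean())
    lloq_rows = tab[np.isclose(tab["nominal"], lloq_level)]
    lloq_ok = bool((lloq_rows["pct_dev"].abs() <= lloq_pct_limit).all())
    passed = frac >= min_fraction and lloq_ok
    return GateRecord(
        name="calibration_acceptance",
        observed=frac,
        limit=min_fraction,
        passed=passed,
        detail=(f"{within.sum()}/{len(tab)} calibrators within +/-{pct_limit:g}%; "
                f"LLOQ within +/-{lloq_pct_limit:g}%: {lloq_ok}"),
    )


@dataclass(frozen=True)
class CalibrationSummary:
    mean_slope: float
    sd_intercept: float
    lod: float            # ug/mL, 3.3 sigma / S
    loq: float            # ug/mL, 10 sigma / S
    n_assays: int


def lod_loq(fits: Sequence[CalibrationFit]) -> CalibrationSummary:
    """Detection and quantification limits from >=3 independent assays.

    sigma is the SD of the fitted intercepts (the background response),
    S the mean slope; LOD = 3.3 sigma/S and LOQ = 10 sigma/S, reported
    at full precision (render to 2 decimals for tables).
    """
    if len(fits) < 3:
        raise ValueError("need >=3 independent calibration fits")
    slopes = np.array([f.slope for f in fits])
    intercepts = np.array([f.intercept for f in fits])
    s = float(slopes.mean())
    sigma = float(intercepts.std(ddof=1))
    return CalibrationSummary(
        mean_slope=s,
        sd_intercept=sigma,
        lod=3.3 * sigma / s,
        loq=10.0 * sigma / s,
        n_assays=len(fits),
    )


@dataclass(frozen=True)
class QCBatch:
    """Replicate measured concentrations for one QC level, grouped by day."""

    level_name: str          # LQC / MQC / HQC
    nominal: float           # ug/mL
    measured_by_day: dict[int, tuple[float, ...]]

    def __post_init__(self) -> None:
        if self.nominal <= 0:
            raise ValueError("nominal must be > 0")


def precision_accuracy(
    batches: Sequence[QCBatch],
    is_lloq: dict[str, bool] | None = None,
) -> pd.DataFrame:
    """Intra/inter-day precision (CV%) and accuracy per QC level.

    Intra-day CV% is the within-day CV pooled across days by averaging;
    inter-day CV% is computed over the day means (ICH convention; the
    pooled-all-replicates CV is also reported). Accuracy% is
    100*grand_mean/nominal. Gates: +/-15% (CV and accuracy deviation),
    +/-20% where the level is the LLOQ. Levels with a single replicate
    in a day are excluded from that day's intra-day CV with a warning
    column rather than an error.
    """
    rows = []
    for b in batches:
        day_cvs, day_means, all_vals = [], [], []
        for day in sorted(b.measured_by_day):
            vals = np.asarray(b.measured_by_day[day], dtype=float)
            all_vals.extend(vals.tolist())
            day_means.append(vals.mean())
            if vals.size >= 2:
                day_cvs.append(100.0 * vals.std(ddof=1) / vals.mean())
        if not all_vals:
            continue
        all_arr = np.asarray(all_vals)
        grand = all_arr.mean()
        day_means_arr = np.asarray(day_means)
        intra = float(np.mean(day_cvs)) if day_cvs else float("nan")
        inter = (100.0 * day_means_arr.std(ddof=1) / day_means_arr.mean()
                 if day_means_arr.size >= 2 else float("nan"))
        pooled = (100.0 * all_arr.std(ddof=1) / grand
                  if all_arr.size >= 2 else float("nan"))
        accuracy = 100.0 * grand / b.nominal
        limit = 20.0 if (is_lloq or {}).get(b.level_name, False) else 15.0
        rows.append({
            "level": b.level_name,
            "nominal": b.nominal,
            "grand_mean": grand,
            "intra_day_cv_pct": intra,
            "inter_day_cv_pct": float(inter),
            "pooled_cv_pct": float(pooled),
            "accuracy_pct": accuracy,
            "gate_limit_pct": limit,
            "precision_pass": bool(
                (math.isnan(intra) or intra <= limit)
                and (math.isnan(float(inter)) or inter <= limit)
            ),
            "accuracy_pass": bool(abs(accuracy - 100.0) <= limit),
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RecoveryResult:
    level: float
    recovery_pct: float
    cv_pct: float
    n: int


def recovery(
    pre_spiked_ratios: Sequence[float],
    post_spiked_ratios: Sequence[float],
    level: float,
) -> RecoveryResult:
    """Extraction recovery: 100 * mean(pre-extraction spiked ratios) /
    mean(post-extraction spiked ratios), with the CV of the
    per-replicate recoveries."""
    pre = np.asarray(pre_spiked_ratios, dtype=float)
    post = np.asarray(post_spiked_ratios, dtype=float)
    if pre.size < 3 or post.size < 3:
        raise ValueError("need >=3 replicates on each side")
    if post.mean() <= 0:
        raise ValueError("post-extraction mean ratio must be > 0")
    per_rep = 100.0 * pre / post.mean()
    return RecoveryResult(
        level=level,
        recovery_pct=float(per_rep.mean()),
        cv_pct=float(100.0 * per_rep.std(ddof=1) / per_rep.mean()),
        n=int(pre.size),
    )


@dataclass(frozen=True)
class MatrixEffectResult:
    level: float
    mf_analyte: float
    mf_is: float
    is_normalized_mf: float
    cv_pct: float
    gate: GateRecord


def matrix_effect(
    matrix_analyte_areas: Sequence[float],
    solvent_analyte_areas: Sequence[float],
    matrix_is_areas: Sequence[float],
    solvent_is_areas: Sequence[float],
    level: float = float("nan"),
    mf_range: tuple[float, float] = (0.8, 1.2),
    cv_limit_pct: float = 15.0,
) -> MatrixEffectResult:
    """Matrix factor and IS-normalized matrix factor with EMA-style gate.

    MF = mean matrix-spiked area / mean solvent-spiked area, per channel;
    IS-normalized MF = MF_analyte / MF_IS. The CV% is computed over the
    per-replicate IS-normalized factors. Gate: IS-normalized MF within
    0.8-1.2 and CV <= 15%. Values below 1 indicate ion suppression.
    """
    ma = np.asarray(matrix_analyte_areas, dtype=float)
    sa = np.asarray(solvent_analyte_areas, dtype=float)
    mi = np.asarray(matrix_is_areas, dtype=float)
    si = np.asarray(solvent_is_areas, dtype=float)
    if min(ma.size, sa.size, mi.size, si.size) < 3:
        raise ValueError("need >=3 replicates on each side")
    if sa.mean() <= 0 or si.mean() <= 0:
        raise ValueError("solvent-side mean areas must be > 0")
    mf_a = float(ma.mean() / sa.mean())
    mf_i = float(mi.mean() / si.mean())
    norm = mf_a / mf_i
    per_rep = (ma / mi) / (sa.mean() / si.mean())
    cv = float(100.0 * per_rep.std(ddof=1) / per_rep.mean())
    lo, hi = mf_range
    ok = lo <= norm <= hi and cv <= cv_limit_pct
    gate = GateRecord(
        name="is_normalized_mf",
        observed=norm,
        limit=hi,
        passed=bool(ok),
        detail=(f"IS-normalized MF {norm:.3f} in [{lo}, {hi}]: {lo <= norm <= hi}; "
                f"CV {cv:.2f}% <= {cv_limit_pct:g}%: {cv <= cv_limit_pct}"
                + ("; suppression" if norm < 1 else "; enhancement" if norm > 1 else "")),
    )
    return MatrixEffectResult(
        level=level, mf_analyte=mf_a, mf_is=mf_i,
        is_normalized_mf=norm, cv_pct=cv, gate=gate,
    )


@dataclass(frozen=True)
class QuantResult:
    conc: float              # ug/mL homogenate
    flag: str | None = None  # None | "BLQ" | "ALQ"

    @property
    def reportable(self) -> bool:
        return self.flag is None


def quantify(
    area_ratio: float,
    fit: CalibrationFit,
    loq: float | None = None,
    upper_limit: float = 20.0,
) -> QuantResult:
    """Back-calculate concentration; flag BLQ below LOQ, ALQ above range.

    Flagged values are carried (never silently dropped) but are excluded
    from group means by default downstream.
    """
    if fit.slope == 0:
        raise ValueError("zero slope")
    conc = (area_ratio - fit.intercept) / fit.slope
    flag = None
    if loq is not None and conc < loq:
        flag = "BLQ"
    elif conc < 0:
        flag = "BLQ"
    elif conc > upper_limit:
        flag = "ALQ"
    return QuantResult(conc=float(conc), flag=flag)


def homogenate_to_tissue(
    conc_ug_per_ml: float, buffer_volume_per_mass: float = 0.01
) -> float:
    """Convert homogenate concentration (ug/mL) to tissue burden (ug/mg).

    Default 0.01 mL buffer per mg tissue (1 mL per 100 mg brain).
    """
    if buffer_volume_per_mass <= 0:
        raise ValueError("buffer_volume_per_mass must be > 0")
    return conc_ug_per_ml * buffer_volume_per_mass


def tissue_to_homogenate(
    burden_ug_per_mg: float, buffer_volume_per_mass: float = 0.01
) -> float:
    """Exact inverse of :func:`homogenate_to_tissue`."""
    if buffer_volume_per_mass <= 0:
        raise ValueError("buffer_volume_per_mass must be > 0")
    return burden_ug_per_mg / buffer_volume_per_mass
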