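"""Non-compartmental pharmacokinetic analysis for destructive sampling.

Brain concentration-time data from destructively sampled animals (one
observation per animal, n animals per nominal time) are pooled into a
composite mean profile, from which the standard NCA parameter set is
derived: Tmax, Cmax, terminal rate constant lambda_z (log-linear OLS on
an adjusted-R2-selected terminal point set), T1/2 = ln2/lambda_z,
trapezoidal AUC0-t and AUMC0-t, extrapolated AUC0-inf, MRT, and apparent
clearance and volume (Cl/F = dose/AUC0-inf, Vz/F = Cl_F/lambda_z).

Units: concentrations in ug per mg tissue, times in h, dose in ug/kg.
Cl/F then falls out in mg/(kg*h) and Vz/F in mg/kg, i.e. the familiar
dose-normalized scales (the ug->mg factor of 10^3 is implicit in the
unit algebra, not applied numerically).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConcTimeTable",
    "PKParameters",
    "mean_profile",
    "cmax_tmax",
    "fit_lambda_z",
    "auc",
    "aumc",
    "extrapolate",
    "clearance_volume",
    "nca",
]


@dataclass
class ConcTimeTable:
    """Destructive-sampling concentration-time records.

    ``data`` columns: animal, time_h, conc (ug/mg tissue), optional group.
    Each animal appears exactly once (one terminal sample per animal).
    """

    data: pd.DataFrame
    dose_ug_per_kg: float = 20_000.0  # 20 mg/kg ip
    truth: dict[str, Any] | None = None

    def __post_init__(self) -> None:
        required = {"animal", "time_h", "conc"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        if (self.data["time_h"] < 0).any():
            raise ValueError("times must be >= 0")
        if self.data["animal"].duplicated().any():
            raise ValueError("destructive design: each animal appears once")


def mean_profile(table: ConcTimeTable) -> pd.DataFrame:
    """Naive pooled per-time (mean, sd, n) composite profile."""
    g = table.data.groupby("time_h")["conc"]
    prof = pd.DataFrame(
        {"mean": g.mean(), "sd": g.std(ddof=1).fillna(0.0), "n": g.size()}
    ).reset_index()
    return prof.sort_values("time_h").reset_index(drop=True)


def cmax_tmax(profile: pd.DataFrame) -> tuple[float, float]:
    """Maximum of the mean profile and its time; ties -> earliest time."""
    if not (profile["mean"] > 0).any():
        raise ValueError("all-zero profile")
    i = int(np.argmax(profile["mean"].to_numpy()))  # argmax tie -> earliest
    return float(profile["mean"].iloc[i]), float(profile["time_h"].iloc[i])


def fit_lambda_z(
    profile: pd.DataFrame,
    min_points: int = 3,
    policy: str = "best_adj_r2",
) -> tuple[float, float, int]:
    """Terminal elimination rate constant by log-linear OLS.

    Candidate point sets are suffixes of the post-Tmax profile (Cmax
    itself excluded) of length >= ``min_points`` with positive means;
    the fit with the highest adjusted R2 wins (``policy='last'`` forces
    the minimal suffix of the last ``min_points`` points). Returns
    (lambda_z, adjusted R2, number of points used).
    """
    _, tmax = cmax_tmax(profile)
    term = profile[(profile["time_h"] > tmax) & (profile["mean"] > 0)]
    t = term["time_h"].to_numpy(dtype=float)
    c = term["mean"].to_numpy(dtype=float)
    if t.size < min_points:
        raise ValueError("insufficient terminal data: need >=3 post-Tmax points")

    def fit(ts: np.ndarray, cs: np.ndarray) -> tuple[float, float]:
        res = stats.linregress(ts, np.log(cs))
        n = ts.size
        r2 = res.rvalue**2
        r2_adj = 1 - (1 - r2) * (n - 1) / (n - 2) if n > 2 else r2
        return float(-res.slope), float(r2_adj)

    if policy == "last":
        lam, r2 = fit(t[-min_points:], c[-min_points:])
        return lam, r2, min_points

    best: tuple[float, float, int] | None = None
    for k in range(min_points, t.size + 1):
        lam, r2 = fit(t[-k:], c[-k:])
        if lam <= 0:
            continue
        if best is None or r2 > best[1] + 1e-12:
            best = (lam, r2, k)
    if best is None:
        raise ValueError("no candidate terminal fit with positive lambda_z")
    return best


def auc(profile: pd.DataFrame, method: str = "linear") -> float:
    """AUC0-t by trapezoids (``linear``) or lin-up/log-down."""
    t = profile["time_h"].to_numpy(dtype=float)
    c = profile["mean"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError("need >=2 points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be sorted strictly increasing")
    if method == "linear":
        return float(np.trapezoid(c, t))
    if method == "linuplogdown":
        total = 0.0
        for i in range(t.size - 1):
            dt = t[i + 1] - t[i]
            c0, c1 = c[i], c[i + 1]
            if c1 < c0 and c0 > 0 and c1 > 0:
                total += dt * (c0 - c1) / math.log(c0 / c1)
            else:
                total += dt * (c0 + c1) / 2
        return total
    raise ValueError(f"unknown AUC method {method!r}")


def aumc(profile: pd.DataFrame) -> float:
    """AUMC0-t: trapezoids on t*C(t)."""
    t = profile["time_h"].to_numpy(dtype=float)
    c = profile["mean"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be sorted strictly increasing")
    return float(np.trapezoid(t * c, t))


def extrapolate(
    auc_0_t: float, c_last: float, lambda_z: float
) -> tuple[float, float]:
    """AUC0-inf = AUC0-t + C_last/lambda_z and the observed fraction.

    An observed fraction below 0.8 means >20% of the exposure estimate
    rests on extrapolation; callers should surface that as a warning.
    """
    if lambda_z <= 0:
        raise ValueError("lambda_z must be > 0")
    if c_last < 0:
        raise ValueError("C_last must be >= 0")
    auc_inf = auc_0_t + c_last / lambda_z
    return auc_inf, auc_0_t / auc_inf


def clearance_volume(
    dose_ug_per_kg: float, auc_0_inf: float, lambda_z: float
) -> tuple[float, float]:
    """(Cl/F, Vz/F) in mg/(kg*h) and mg/kg.

    Cl/F = dose / AUC0-inf with dose in ug/kg and AUC in ug*h/mg, which
    is dimensionally mg/(kg*h); Vz/F = Cl_F / lambda_z.
    """
    if auc_0_inf <= 0:
        raise ValueError("AUC0-inf must be > 0")
    cl_f = dose_ug_per_kg / auc_0_inf
    return cl_f, cl_f / lambda_z


@dataclass(frozen=True)
class PKParameters:
    tmax_h: float
    cmax: float                  # ug/mg
    lambda_z: float              # 1/h
    t_half_h: float
    auc_0_t: float               # ug*h/mg
    auc_0_inf: float
    frac_auc: float              # AUC0-t / AUC0-inf
    aumc_0_t: float
    mrt_0_t_h: float
    cl_f: float                  # mg/(kg*h)
    vz_f: float                  # mg/kg
    lambda_z_points: int
    lambda_z_r2_adj: float
    warnings: tuple[str, ...] = ()
    provenance: dict[str, Any] = field(default_factory=dict, compare=False)

    def as_dict(self) -> dict[str, Any]:
        d = {
            "Tmax_h": self.tmax_h,
            "Cmax_ug_per_mg": self.cmax,
            "lambda_z_per_h": self.lambda_z,
            "T_half_h": self.t_half_h,
            "AUC_0_t": self.auc_0_t,
            "AUC_0_inf": self.auc_0_inf,
            "frac_AUC": self.frac_auc,
            "AUMC_0_t": self.aumc_0_t,
            "MRT_0_t_h": self.mrt_0_t_h,
            "Cl_F_mg_per_kg_h": self.cl_f,
            "Vz_F_mg_per_kg": self.vz_f,
            "lambda_z_points": self.lambda_z_points,
            "lambda_z_r2_adj": self.lambda_z_r2_adj,
            "warnings": list(self.warnings),
        }
        return d


def nca(
    table: ConcTimeTable,
    dose_ug_per_kg: float | None = None,
    auc_method: str = "linear",
    lambda_z_policy: str = "best_adj_r2",
) -> PKParameters:
    """Full non-compartmental analysis of a composite profile."""
    dose = table.dose_ug_per_kg if dose_ug_per_kg is None else dose_ug_per_kg
    prof = mean_profile(table)
    cmax, tmax = cmax_tmax(prof)
    warnings: list[str] = []
    try:
        lam, r2_adj, npts = fit_lambda_z(prof, policy=lambda_z_policy)
    except ValueError:
        # sparse grid with a late observed Tmax: fall back to the last
        # three points even though that set touches Cmax
        tail = prof[prof["mean"] > 0].tail(3)
        if len(tail) < 3:
            raise
        res = stats.linregress(tail["time_h"], np.log(tail["mean"]))
        lam, r2_adj, npts = float(-res.slope), float(res.rvalue**2), 3
        if lam <= 0:
            raise ValueError("terminal phase not decreasing; cannot fit lambda_z")
        warnings.append("terminal fit fell back to the last 3 points incl. Cmax")
    auc_t = auc(prof, method=auc_method)
    aumc_t = aumc(prof)
    c_last = float(prof["mean"].iloc[-1])
    auc_inf, frac = extrapolate(auc_t, c_last, lam)
    cl_f, vz_f = clearance_volume(dose, auc_inf, lam)
    if frac < 0.8:
        warnings.append(
            f"high extrapolation: AUC0-t covers only {frac:.0%} of AUC0-inf"
        )
    return PKParameters(
        tmax_h=tmax,
        cmax=cmax,
        lambda_z=lam,
        t_half_h=math.log(2) / lam,
        auc_0_t=auc_t,
        auc_0_inf=auc_inf,
        frac_auc=frac,
        aumc_0_t=aumc_t,
        mrt_0_t_h=aumc_t / auc_t if auc_t > 0 else float("nan"),
        cl_f=cl_f,
        vz_f=vz_f,
        lambda_z_points=npts,
        lambda_z_r2_adj=r2_adj,
        warnings=tuple(warnings),
        provenance={
            "auc_method": auc_method,
            "lambda_z_policy": lambda_z_policy,
            "dose_ug_per_kg": dose,
            "times_h": prof["time_h"].tolist(),
        },
    )
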