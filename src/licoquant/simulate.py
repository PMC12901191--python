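"""Synthetic-data generators with stored ground truth.

Emulates every input the quantification workbench consumes, under the
assay's study conditions: six-point matrix calibration (0.5-20 ug/mL,
internal standard at 0.5 ug/mL) with intra-day and day-to-day
proportional noise, extraction recovery near two-thirds, mild matrix
suppression, MRM chromatogram traces, composite brain concentration-time
datasets from a one-compartment first-order-absorption model sampled
destructively at {0, 2, 4, 6, 8, 24} h with five animals per time, and
behavioral event logs with group-level memory effects.

Noise model: multiplicative mean-one lognormal on response ratios
(chromatographic noise scales with signal) plus a shared per-day
lognormal factor, so inter-day variability exceeds intra-day; blanks
carry additive baseline noise only. All generators are deterministic
given (config, design, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .behavior import ArmEntrySequence, NORSession, ARMS
from .nca import ConcTimeTable
from .peaks import Chromatogram

__all__ = [
    "SimConfig",
    "BehaviorDataset",
    "ROLES",
    "generate_injection_table",
    "generate_chromatogram",
    "generate_pk_dataset",
    "generate_behavior_dataset",
]

ROLES = (
    "blank", "zero", "calibrator", "QC", "pre-spike", "post-spike",
    "solvent", "unknown",
)

# Roles whose analyte response passes through extraction (recovery applies)
_EXTRACTED = {"calibrator", "QC", "pre-spike", "unknown"}
# Roles measured in matrix (matrix factor applies)
_MATRIX = {"calibrator", "QC", "pre-spike", "post-spike", "unknown"}


def _default_behavior_params() -> dict[str, dict[str, float]]:
    return {
        "control": {"dr_mean": 0.65, "total_exploration_s": 40.0,
                    "n_bouts": 8, "alternation_p": 0.70, "mean_entries": 22.0},
        "LPS": {"dr_mean": 0.50, "total_exploration_s": 32.0,
                "n_bouts": 8, "alternation_p": 0.55, "mean_entries": 18.0},
        "LPS+LCA": {"dr_mean": 0.62, "total_exploration_s": 38.0,
                    "n_bouts": 8, "alternation_p": 0.68, "mean_entries": 21.0},
        "LCA": {"dr_mean": 0.66, "total_exploration_s": 40.0,
                "n_bouts": 8, "alternation_p": 0.71, "mean_entries": 22.0},
    }


@dataclass
class SimConfig:
    """Ground-truth parameters for all synthetic inputs.

    Calibration response: area ratio = slope_true*C + intercept_true,
    scaled by recovery_true for extracted (pre-extraction-spiked) samples
    and by the matrix factors for matrix-based samples. PK: C(t) =
    scale*(exp(-lambda_z t) - exp(-ka t)), one observation per animal.
    """

    seed: int = 0
    # calibration / validation truth
    slope_true: float = 8.5133          # area-ratio per (ug/mL)
    intercept_true: float = 1.7962      # area-ratio
    recovery_true: float = 0.68         # extraction recovery fraction
    matrix_factor_true: float = 0.88    # analyte-channel matrix factor
    matrix_factor_is_true: float = 1.0  # IS-channel matrix factor
    cv_intra: float = 0.04              # proportional noise on ratios
    cv_inter_day: float = 0.08          # shared per-day factor
    cv_is: float = 0.02                 # IS-area instrument noise
    cv_ion_ratio: float = 0.05          # qualifier/quantifier ratio noise
    is_conc: float = 0.5                # ug/mL, constant in every sample
    base_is_area: float = 20_000.0      # counts, nominal IS response
    baseline_area_sd: float = 50.0      # counts, blank-channel noise
    analyte_rt: float = 11.22           # min (E-isomer derivative peak)
    is_rt: float = 10.04                # min
    rt_jitter_sd: float = 0.02          # min
    qualifier_ra: tuple[float, float] = (73.0, 44.0)  # % of quantifier
    emit_minor_isomer: bool = False     # optional early Z-isomer peak
    minor_isomer_rt: float = 10.61
    minor_isomer_fraction: float = 0.05
    # pharmacokinetics truth
    pk_ka: float = 0.8                  # 1/h absorption
    pk_lambda_z: float = 0.0405         # 1/h elimination
    pk_scale: float = 95.0              # ug/mg profile scale
    pk_bsv_cv: float = 0.15             # between-animal CV on scale
    sampling_times: tuple[float, ...] = (0.0, 2.0, 4.0, 6.0, 8.0, 24.0)
    n_per_time: int = 5
    # behavior truth
    behavior_group_params: dict[str, dict[str, float]] = field(
        default_factory=_default_behavior_params
    )

    def __post_init__(self) -> None:
        for name in ("cv_intra", "cv_inter_day", "cv_is", "cv_ion_ratio",
                     "pk_bsv_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (self.pk_ka > self.pk_lambda_z > 0):
            raise ValueError("require pk_ka > pk_lambda_z > 0 (no flip-flop)")
        ts = self.sampling_times
        if ts[0] != 0 or any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("sampling_times must start at 0 and strictly increase")
        for name in ("recovery_true", "matrix_factor_true", "matrix_factor_is_true"):
            v = getattr(self, name)
            if not 0 < v <= 1.5:
                raise ValueError(f"{name} must lie in (0, 1.5]")

    def truth_dict(self) -> dict[str, Any]:
        return asdict(self)


def _lognormal_mean_one(rng: np.random.Generator, cv: float, size=None):
    """Multiplicative noise factor with mean exactly 1 and the given CV."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma = math.sqrt(math.log(1 + cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def generate_injection_table(
    design: Sequence[Mapping[str, Any]] | pd.DataFrame,
    config: SimConfig,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate one injection per design row.

    Design rows need ``role`` (one of :data:`ROLES`) and, for non-blank
    roles, ``nominal`` (ug/mL); optional ``day`` (default 1) and
    ``sample_id``. Returns a table with per-transition areas
    (quantifier, two qualifiers, IS), retention times, and the analyte/IS
    area ratio. Blanks carry baseline noise only in both channels.
    """
    if isinstance(design, pd.DataFrame):
        rows = design.to_dict("records")
    else:
        rows = [dict(r) for r in design]
    if not rows:
        raise ValueError("design is empty")
    for r in rows:
        role = r.get("role")
        if role not in ROLES:
            raise ValueError(f"invalid role {role!r}; expected one of {ROLES}")
        nominal = float(r.get("nominal", 0.0) or 0.0)
        if nominal < 0:
            raise ValueError("negative nominal concentration")
        r["nominal"] = nominal
        r.setdefault("day", 1)

    rng = np.random.default_rng(config.seed if seed is None else seed)
    days = sorted({int(r["day"]) for r in rows})
    day_factor = {
        d: float(_lognormal_mean_one(rng, config.cv_inter_day)) for d in days
    }

    ra1, ra2 = config.qualifier_ra
    out = []
    for i, r in enumerate(rows):
        role, nominal, day = r["role"], r["nominal"], int(r["day"])
        rec = {
            "sample_id": r.get("sample_id", f"inj{i:03d}"),
            "role": role,
            "day": day,
            "nominal": nominal,
        }
        if role == "blank":
            rec.update(
                rt_analyte=np.nan,
                rt_is=np.nan,
                area_quant=abs(rng.normal(0, config.baseline_area_sd)),
                area_qual1=abs(rng.normal(0, config.baseline_area_sd)),
                area_qual2=abs(rng.normal(0, config.baseline_area_sd)),
                area_is=abs(rng.normal(0, config.baseline_area_sd)),
                area_ratio=np.nan,
            )
            out.append(rec)
            continue

        mf_is = config.matrix_factor_is_true if role in _MATRIX else 1.0
        is_area = (
            config.base_is_area * mf_is * _lognormal_mean_one(rng, config.cv_is)
        )
        if role == "zero" or nominal == 0:
            quant = abs(rng.normal(0, config.baseline_area_sd))
            ratio = quant / is_area
            qual1 = abs(rng.normal(0, config.baseline_area_sd))
            qual2 = abs(rng.normal(0, config.baseline_area_sd))
        else:
            mean_ratio = config.slope_true * nominal + config.intercept_true
            if role in _EXTRACTED:
                mean_ratio *= config.recovery_true
            if role in _MATRIX:
                mean_ratio *= config.matrix_factor_true / config.matrix_factor_is_true
            ratio = (
                mean_ratio
                * _lognormal_mean_one(rng, config.cv_intra)
                * day_factor[day]
            )
            quant = ratio * is_area
            qual1 = quant * ra1 / 100.0 * _lognormal_mean_one(rng, config.cv_ion_ratio)
            qual2 = quant * ra2 / 100.0 * _lognormal_mean_one(rng, config.cv_ion_ratio)
        rec.update(
            rt_analyte=config.analyte_rt + rng.normal(0, config.rt_jitter_sd),
            rt_is=config.is_rt + rng.normal(0, config.rt_jitter_sd),
            area_quant=float(quant),
            area_qual1=float(qual1),
            area_qual2=float(qual2),
            area_is=float(is_area),
            area_ratio=float(ratio),
        )
        out.append(rec)
    return pd.DataFrame(out)


def generate_chromatogram(
    peaks: Sequence[tuple[float, float, float, str]],
    noise_sd: float,
    gradient_length: float,
    seed: int = 0,
    points_per_sigma: int = 12,
    baseline_level: float = 0.0,
) -> dict[str, Chromatogram]:
    """Render Gaussian peaks on a flat noisy baseline, per transition.

    ``peaks`` rows are (RT min, height counts, width s, transition id)
    where width is the Gaussian sigma in seconds. The uniform sampling
    grid guarantees at least ``points_per_sigma`` samples per narrowest
    peak width. White noise of sd ``noise_sd`` is added independently
    per transition trace.
    """
    rng = np.random.default_rng(seed)
    for rt, height, width, _ in peaks:
        if not 0 <= rt <= gradient_length:
            raise ValueError(f"peak RT {rt} outside [0, {gradient_length}]")
        if height <= 0 or width <= 0:
            raise ValueError("peak height and width must be > 0")
    if peaks:
        min_sigma_min = min(w for _, _, w, _ in peaks) / 60.0
        dt = min_sigma_min / points_per_sigma
    else:
        dt = gradient_length / 2000.0
    n = int(math.floor(gradient_length / dt)) + 1
    t = np.arange(n) * dt

    transitions = sorted({tr for *_, tr in peaks}) or ["trace"]
    out: dict[str, Chromatogram] = {}
    for tr in transitions:
        y = np.full(n, baseline_level, dtype=float)
        for rt, height, width, tr_i in peaks:
            if tr_i != tr:
                continue
            sigma = width / 60.0
            y += height * np.exp(-0.5 * ((t - rt) / sigma) ** 2)
        if noise_sd > 0:
            y = y + rng.normal(0, noise_sd, size=n)
        out[tr] = Chromatogram(transition=tr, time=t, intensity=y)
    return out


def generate_pk_dataset(
    config: SimConfig,
    dose_ug_per_kg: float = 20_000.0,
    seed: int | None = None,
) -> ConcTimeTable:
    """Destructive-sampling brain concentration-time dataset.

    Each animal is sampled at exactly one nominal time; its concentration
    is scale_i * (exp(-lambda_z t) - exp(-ka t)) with scale_i mean-one
    lognormal across animals (CV ``pk_bsv_cv``). The generating truth is
    attached to the returned table.
    """
    if config.n_per_time < 1:
        raise ValueError("n_per_time must be >= 1")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    lam, ka = config.pk_lambda_z, config.pk_ka
    rows = []
    aid = 0
    for t in config.sampling_times:
        for _ in range(config.n_per_time):
            scale = config.pk_scale * float(_lognormal_mean_one(rng, config.pk_bsv_cv))
            conc = scale * (math.exp(-lam * t) - math.exp(-ka * t))
            rows.append(
                {"animal": f"m{aid:03d}", "time_h": float(t),
                 "conc": conc, "group": "LCA"}
            )
            aid += 1
    truth = {
        "lambda_z": lam,
        "ka": ka,
        "scale": config.pk_scale,
        "bsv_cv": config.pk_bsv_cv,
        "tmax_continuous_h": math.log(ka / lam) / (ka - lam),
        "dose_ug_per_kg": dose_ug_per_kg,
    }
    return ConcTimeTable(
        data=pd.DataFrame(rows), dose_ug_per_kg=dose_ug_per_kg, truth=truth
    )


@dataclass
class BehaviorDataset:
    nor_sessions: list[NORSession]
    ymaze_sequences: list[ArmEntrySequence]
    truth: dict[str, dict[str, float]]


def _ymaze_sequence(rng: np.random.Generator, n_entries: int, p_alt: float
                    ) -> tuple[str, ...]:
    """First-order arm-entry process with alternation propensity p_alt.

    After the first two (distinct) entries, the next arm completes an
    alternation triplet with probability p_alt; otherwise the animal
    returns to the arm visited two entries ago. Consecutive repeats
    never occur (re-entry is not an entry). p_alt=1 yields perfect
    alternation.
    """
    first = ARMS[rng.integers(3)]
    second = rng.choice([a for a in ARMS if a != first])
    seq = [first, str(second)]
    while len(seq) < n_entries:
        third_options = [a for a in ARMS if a not in seq[-2:]]
        if rng.random() < p_alt:
            seq.append(third_options[0])
        else:
            seq.append(seq[-2])
    return tuple(seq[:n_entries])


def generate_behavior_dataset(
    config: SimConfig,
    n_per_group: int,
    seed: int | None = None,
) -> BehaviorDataset:
    """NOR bout logs and Y-maze entry sequences per treatment group.

    NOR bout durations are exponential with group-specific novel/familiar
    means chosen so the expected discrimination ratio matches the
    configured group mean; Y-maze sequences come from a first-order
    alternation process. Ground-truth group parameters ride along.
    """
    if n_per_group < 0:
        raise ValueError("n_per_group must be >= 0")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    nor: list[NORSession] = []
    ymaze: list[ArmEntrySequence] = []
    for group, p in config.behavior_group_params.items():
        n_bouts = int(p["n_bouts"])
        mean_bout = p["total_exploration_s"] / (2 * n_bouts)
        for i in range(n_per_group):
            animal = f"{group}-{i:02d}"
            # training: two identical objects
            train = tuple(
                ("familiar", float(rng.exponential(mean_bout)))
                for _ in range(2 * n_bouts)
            )
            nor.append(NORSession(animal, group, "training", train))
            # test: novel/familiar with DR-matched mean durations
            mean_nov = 2 * mean_bout * p["dr_mean"]
            mean_fam = 2 * mean_bout * (1 - p["dr_mean"])
            test = tuple(
                ("novel", float(rng.exponential(mean_nov))) for _ in range(n_bouts)
            ) + tuple(
                ("familiar", float(rng.exponential(mean_fam))) for _ in range(n_bouts)
            )
            nor.append(NORSession(animal, group, "test", test))
            n_entries = max(3, int(rng.poisson(p["mean_entries"])))
            ymaze.append(
                ArmEntrySequence(
                    animal, group,
                    _ymaze_sequence(rng, n_entries, p["alternation_p"]),
                )
            )
    return BehaviorDataset(
        nor_sessions=nor,
        ymaze_sequences=ymaze,
        truth={g: dict(p) for g, p in config.behavior_group_params.items()},
    )
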