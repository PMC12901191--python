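"""Qualitative identity confirmation for targeted MRM assays.

Implements the FDA-style first-identification checklist: retention time
within +/-1% of the same-batch reference standard, MRM qualifier ion
ratios within +/-20% (relative) of the reference relative abundance,
blank true-negative screening (analyte-region area < 20% of the LLOQ
calibrator area and < 5% of the mean IS area), and a carry-over check on
the blank injected after a spiked sample. Every criterion yields an
auditable record; the sample is confirmed only if all pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

__all__ = [
    "ConfirmationCriteria",
    "CriterionRecord",
    "ConfirmationResult",
    "check_rt",
    "check_ion_ratios",
    "check_blank",
    "confirm_identity",
]


@dataclass(frozen=True)
class ConfirmationCriteria:
    rt_tolerance_pct: float = 1.0
    ion_ratio_tolerance_pct: float = 20.0
    blank_analyte_max_pct_of_lloq: float = 20.0
    blank_is_max_pct: float = 5.0

    def __post_init__(self) -> None:
        for name in ("rt_tolerance_pct", "ion_ratio_tolerance_pct",
                     "blank_analyte_max_pct_of_lloq", "blank_is_max_pct"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class CriterionRecord:
    name: str
    observed: float
    limit: float
    passed: bool
    detail: str = ""


@dataclass(frozen=True)
class ConfirmationResult:
    criteria: tuple[CriterionRecord, ...]
    confirmed: bool
    diagnostics: str = ""

    def __post_init__(self) -> None:
        # overall decision is exactly the conjunction of the criteria
        if self.confirmed != all(c.passed for c in self.criteria):
            raise ValueError("confirmed flag inconsistent with criteria")

    def failing(self) -> list[str]:
        return [c.name for c in self.criteria if not c.passed]


def check_rt(
    sample_rt: float,
    reference_rt: float,
    criteria: ConfirmationCriteria = ConfirmationCriteria(),
) -> CriterionRecord:
    """Retention-time agreement: 100*|RT_s - RT_ref|/RT_ref <= tolerance.

    The denominator is always the reference standard's RT (documented
    asymmetry of the rule).
    """
    if reference_rt <= 0:
        raise ValueError("reference RT must be > 0")
    dev = 100.0 * abs(sample_rt - reference_rt) / reference_rt
    return CriterionRecord(
        name="retention_time",
        observed=dev,
        limit=criteria.rt_tolerance_pct,
        passed=dev <= criteria.rt_tolerance_pct,
        detail=f"sample {sample_rt:.3f} vs reference {reference_rt:.3f} min",
    )


def check_ion_ratios(
    sample_areas: Mapping[str, float],
    reference_ra: Mapping[str, float],
    criteria: ConfirmationCriteria = ConfirmationCriteria(),
    quantifier: str = "quant",
) -> list[CriterionRecord]:
    """Qualifier/quantifier ratio agreement, one record per qualifier.

    The sample relative abundance is 100*qualifier/quantifier; it passes
    if its relative deviation from the reference RA is within the
    tolerance (|RA_s - RA_ref| / RA_ref <= 20% by default, a relative
    window, not absolute percentage points). A missing or zero qualifier
    fails automatically.
    """
    q_area = sample_areas.get(quantifier, 0.0)
    if q_area <= 0:
        raise ValueError("quantifier area must be > 0 in the sample")
    out = []
    tol = criteria.ion_ratio_tolerance_pct / 100.0
    for qual, ra_ref in reference_ra.items():
        if ra_ref <= 0:
            raise ValueError(f"reference RA for {qual} must be > 0")
        area = sample_areas.get(qual)
        if area is None or area <= 0:
            out.append(CriterionRecord(
                name=f"ion_ratio[{qual}]", observed=float("nan"),
                limit=criteria.ion_ratio_tolerance_pct, passed=False,
                detail="qualifier absent",
            ))
            continue
        ra_s = 100.0 * area / q_area
        dev = abs(ra_s - ra_ref) / ra_ref * 100.0
        out.append(CriterionRecord(
            name=f"ion_ratio[{qual}]", observed=dev,
            limit=criteria.ion_ratio_tolerance_pct, passed=dev <= criteria.ion_ratio_tolerance_pct,
            detail=f"sample RA {ra_s:.1f} vs reference {ra_ref:.1f}",
        ))
    return out


def check_blank(
    blank_analyte_area: float,
    blank_is_area: float,
    lloq_analyte_area: float,
    mean_is_area: float,
    criteria: ConfirmationCriteria = ConfirmationCriteria(),
    label: str = "blank",
) -> CriterionRecord:
    """Blank interference: analyte region < 20% of LLOQ and IS region < 5% of mean IS."""
    if lloq_analyte_area <= 0 or mean_is_area <= 0:
        raise ValueError("LLOQ and mean IS areas must be > 0")
    pct_analyte = 100.0 * blank_analyte_area / lloq_analyte_area
    pct_is = 100.0 * blank_is_area / mean_is_area
    ok = (pct_analyte < criteria.blank_analyte_max_pct_of_lloq
          and pct_is < criteria.blank_is_max_pct)
    return CriterionRecord(
        name=label,
        observed=max(
            pct_analyte / criteria.blank_analyte_max_pct_of_lloq,
            pct_is / criteria.blank_is_max_pct,
        ),
        limit=1.0,
        passed=ok,
        detail=(f"analyte {pct_analyte:.1f}% of LLOQ "
                f"(limit {criteria.blank_analyte_max_pct_of_lloq:g}%); "
                f"IS {pct_is:.1f}% of mean IS (limit {criteria.blank_is_max_pct:g}%)"),
    )


def confirm_identity(
    sample: Mapping[str, Any],
    reference: Mapping[str, Any] | None,
    pre_run_blank: Mapping[str, Any] | None = None,
    post_run_blank: Mapping[str, Any] | None = None,
    lloq_analyte_area: float | None = None,
    mean_is_area: float | None = None,
    criteria: ConfirmationCriteria = ConfirmationCriteria(),
) -> ConfirmationResult:
    """Aggregate all identification criteria into one auditable decision.

    ``sample`` and ``reference`` are injection records with keys
    ``rt_analyte``, ``area_quant``, ``area_qual1``, ``area_qual2`` (the
    reference must come from the same batch). Blanks, when given, are
    screened against the LLOQ calibrator and mean IS areas; the
    post-run blank is the carry-over check and reuses the same limits.
    """
    if reference is None:
        raise ValueError("no same-batch reference standard")
    records: list[CriterionRecord] = [
        check_rt(float(sample["rt_analyte"]), float(reference["rt_analyte"]),
                 criteria)
    ]
    ref_ra = {
        "area_qual1": 100.0 * reference["area_qual1"] / reference["area_quant"],
        "area_qual2": 100.0 * reference["area_qual2"] / reference["area_quant"],
    }
    sample_areas = {
        "quant": float(sample["area_quant"]),
        "area_qual1": float(sample.get("area_qual1", 0.0)),
        "area_qual2": float(sample.get("area_qual2", 0.0)),
    }
    records.extend(check_ion_ratios(sample_areas, ref_ra, criteria))
    for blank, label in ((pre_run_blank, "blank"), (post_run_blank, "carry_over")):
        if blank is not None:
            if lloq_analyte_area is None or mean_is_area is None:
                raise ValueError("blank checks need LLOQ and mean IS areas")
            records.append(check_blank(
                float(blank["area_quant"]), float(blank["area_is"]),
                lloq_analyte_area, mean_is_area, criteria, label=label,
            ))
    ok = all(r.passed for r in records)
    failing = [r.name for r in records if not r.passed]
    return ConfirmationResult(
        criteria=tuple(records),
        confirmed=ok,
        diagnostics="confirmed" if ok else "failed: " + ", ".join(failing),
    )
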