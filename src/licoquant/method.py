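"""GC-MS/MS method design arithmetic.

Everything needed to design a targeted GC-MS/MS assay on paper before
touching an instrument: elemental-formula bookkeeping for trimethylsilyl
(TMS) derivatives, nominal and monoisotopic mass calculation, electron-
ionization fragment annotation by neutral loss, oven temperature-program
timing, Kovats retention indices against an n-alkane ladder, selection of
quantifier/qualifier MRM transitions from product-ion scans, and assembly
of a time-segmented MRM acquisition schedule.

Masses are computed from embedded IUPAC atomic constants; fragment m/z
values use nominal (integer) masses, matching unit-resolution quadrupole
readout.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

__all__ = [
    "ElementalFormula",
    "OvenProgram",
    "AlkaneLadder",
    "MRMTransition",
    "MethodSchedule",
    "NEUTRAL_LOSSES",
    "nominal_mass",
    "monoisotopic_mass",
    "tms_derivatize",
    "annotate_fragments",
    "program_duration",
    "temperature_at",
    "kovats_index",
    "ladder_from_index_pairs",
    "select_transitions",
    "build_schedule",
]

# Most-abundant-isotope integer masses (unit-resolution quadrupole scale).
_NOMINAL_MASS: dict[str, int] = {
    "H": 1, "C": 12, "N": 14, "O": 16, "Si": 28, "S": 32, "P": 31,
}

# IUPAC monoisotopic masses of the most abundant isotope, Da.
_MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "Si": 27.9769265327,
    "S": 31.97207069,
    "P": 30.97376151,
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementalFormula:
    """Immutable element -> count mapping, e.g. C21H22O4."""

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        clean: dict[str, int] = {}
        for el, n in self.counts.items():
            if el not in _NOMINAL_MASS:
                raise ValueError(f"unsupported element {el!r}")
            if not isinstance(n, int) or n < 0:
                raise ValueError(f"count for {el} must be a non-negative integer")
            if n > 0:
                clean[el] = n
        object.__setattr__(self, "counts", dict(sorted(clean.items())))

    @classmethod
    def parse(cls, text: str) -> "ElementalFormula":
        """Parse a Hill-style formula string such as ``'C27H38O4Si2'``."""
        counts: dict[str, int] = {}
        pos = 0
        for m in _FORMULA_TOKEN.finditer(text):
            if not m.group(0):
                continue
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {text!r} at position {pos}")
            pos = m.end()
            el = m.group(1)
            counts[el] = counts.get(el, 0) + (int(m.group(2)) if m.group(2) else 1)
        if pos != len(text):
            raise ValueError(f"cannot parse formula {text!r}")
        return cls(counts)

    def __getitem__(self, el: str) -> int:
        return self.counts.get(el, 0)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) + n
        return ElementalFormula(merged)

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            left = merged.get(el, 0) - n
            if left < 0:
                raise ValueError(
                    f"{other} is not a sub-formula of {self} (element {el})"
                )
            merged[el] = left
        return ElementalFormula(merged)

    def contains(self, other: "ElementalFormula") -> bool:
        return all(self[el] >= n for el, n in other.counts.items())

    def __str__(self) -> str:
        return "".join(
            f"{el}{n if n != 1 else ''}" for el, n in self.counts.items()
        ) or "(empty)"


def nominal_mass(f: ElementalFormula) -> int:
    """Integer mass from most-abundant-isotope masses."""
    return sum(n * _NOMINAL_MASS[el] for el, n in f.counts.items())


def monoisotopic_mass(f: ElementalFormula) -> float:
    """Exact monoisotopic mass in Da (full precision; display rounds)."""
    return sum(n * _MONOISOTOPIC_MASS[el] for el, n in f.counts.items())


# One TMS substitution replaces an active hydrogen with Si(CH3)3:
# net composition change +C3H8Si (= +SiC3H9 - H).
_TMS_NET = ElementalFormula({"C": 3, "H": 8, "Si": 1})


def tms_derivatize(parent: ElementalFormula, n_tms: int) -> ElementalFormula:
    """Formula of the n-TMS derivative of ``parent``.

    Each trimethylsilyl group replaces one active (hydroxyl) hydrogen,
    a net gain of C3H8Si. Requires the parent to carry at least
    ``n_tms`` hydrogens.
    """
    if n_tms < 0:
        raise ValueError("n_tms must be >= 0")
    if parent["H"] < n_tms:
        raise ValueError(
            f"parent has {parent['H']} H but {n_tms} TMS substitutions requested"
        )
    out = parent
    for _ in range(n_tms):
        out = out + _TMS_NET
    return out


NEUTRAL_LOSSES: dict[str, ElementalFormula] = {
    "Me": ElementalFormula({"C": 1, "H": 3}),
    "OMe": ElementalFormula({"C": 1, "H": 3, "O": 1}),
}


def annotate_fragments(
    derivative: ElementalFormula,
    losses: Sequence[str | ElementalFormula] = (),
    named_fragments: Sequence[tuple[str, ElementalFormula]] = (),
) -> list[tuple[str, int]]:
    """Nominal m/z of neutral-loss fragments and directly named fragments.

    ``losses`` entries are either keys of :data:`NEUTRAL_LOSSES` or
    explicit formulas; each must be a sub-formula of the derivative.
    Returned labels are ``[M-X]+`` for losses and the given label for
    named fragments.
    """
    out: list[tuple[str, int]] = []
    for loss in losses:
        if isinstance(loss, str):
            label, loss_f = loss, NEUTRAL_LOSSES[loss]
        else:
            label, loss_f = str(loss), loss
        if not derivative.contains(loss_f):
            raise ValueError(f"loss {label} exceeds derivative composition")
        out.append((f"[M-{label}]+", nominal_mass(derivative) - nominal_mass(loss_f)))
    for label, frag in named_fragments:
        out.append((label, nominal_mass(frag)))
    return out


# ---------------------------------------------------------------------------
# Oven temperature program


@dataclass(frozen=True)
class OvenProgram:
    """GC oven gradient: initial hold then heating ramps with holds.

    ``segments`` is an ordered list of (ramp_rate degC/min, target degC,
    hold min). Targets must be non-decreasing (no cooling ramps).
    """

    initial_temp: float
    initial_hold: float
    segments: tuple[tuple[float, float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.initial_hold < 0:
            raise ValueError("initial hold must be >= 0")
        prev = self.initial_temp
        for rate, target, hold in self.segments:
            if rate <= 0:
                raise ValueError("ramp rate must be > 0")
            if target < prev:
                raise ValueError("cooling ramps unsupported: target below previous temperature")
            if hold < 0:
                raise ValueError("hold must be >= 0")
            prev = target


def program_duration(program: OvenProgram) -> float:
    """Total runtime in minutes, exact rational arithmetic before float."""
    total = Fraction(program.initial_hold).limit_denominator(10**9)
    prev = Fraction(program.initial_temp).limit_denominator(10**9)
    for rate, target, hold in program.segments:
        r = Fraction(rate).limit_denominator(10**9)
        t = Fraction(target).limit_denominator(10**9)
        total += (t - prev) / r + Fraction(hold).limit_denominator(10**9)
        prev = t
    return float(total)


def temperature_at(program: OvenProgram, t: float) -> float:
    """Oven temperature (degC) at time ``t`` minutes into the run."""
    dur = program_duration(program)
    if not 0 <= t <= dur + 1e-12:
        raise ValueError(f"t={t} outside program duration [0, {dur}]")
    clock = program.initial_hold
    temp = program.initial_temp
    if t <= clock:
        return temp
    for rate, target, hold in program.segments:
        ramp_time = (target - temp) / rate
        if t <= clock + ramp_time:
            return temp + rate * (t - clock)
        clock += ramp_time
        temp = target
        if t <= clock + hold:
            return temp
        clock += hold
    return temp


# ---------------------------------------------------------------------------
# Kovats retention index


@dataclass(frozen=True)
class AlkaneLadder:
    """n-alkane reference ladder: (carbon number, retention time min)."""

    rungs: tuple[tuple[int, float], ...]

    def __post_init__(self) -> None:
        ns = [n for n, _ in self.rungs]
        ts = [t for _, t in self.rungs]
        if len(self.rungs) < 2:
            raise ValueError("ladder needs at least two alkanes")
        if any(b <= a for a, b in zip(ns, ns[1:])):
            raise ValueError("carbon numbers must be strictly increasing")
        if any(b <= a for a, b in zip(ts, ts[1:])) or ts[0] <= 0:
            raise ValueError("retention times must be positive and strictly increasing")

    def bracket(self, t_x: float) -> tuple[int, float, float]:
        """(n, t_n, t_{n+1}) of the consecutive pair with t_n <= t_x < t_{n+1}."""
        for (n_lo, t_lo), (n_hi, t_hi) in zip(self.rungs, self.rungs[1:]):
            if t_lo <= t_x < t_hi:
                if n_hi != n_lo + 1:
                    raise ValueError(
                        f"bracketing alkanes C{n_lo}/C{n_hi} are not consecutive"
                    )
                return n_lo, t_lo, t_hi
        raise ValueError(f"unbracketed retention time: {t_x}")


def kovats_index(t_x: float, ladder: AlkaneLadder) -> float:
    """Kovats retention index from bracketing n-alkanes.

    I = 100 * [n + (log t_x - log t_n) / (log t_{n+1} - log t_n)]

    with base-10 logarithms of the raw retention times; returns 100 n at
    t_x = t_n. (A linear temperature-programmed index variant is not the
    default here; the logarithmic form is used throughout.)
    """
    n, t_n, t_next = ladder.bracket(t_x)
    return 100.0 * (
        n
        + (math.log10(t_x) - math.log10(t_n))
        / (math.log10(t_next) - math.log10(t_n))
    )


def ladder_from_index_pairs(
    n: int,
    pair_a: tuple[float, float],
    pair_b: tuple[float, float],
) -> tuple[float, float]:
    """Solve for the bracketing alkane RTs (t_n, t_{n+1}) from two
    (retention time, index) observations that share the same bracket.

    Inverts the two-point Kovats system; useful to reconstruct a ladder
    consistent with published (RT, index) pairs.
    """
    (tx_a, idx_a), (tx_b, idx_b) = pair_a, pair_b
    f_a = (idx_a - 100.0 * n) / 100.0
    f_b = (idx_b - 100.0 * n) / 100.0
    if not (0 <= f_a < 1 and 0 <= f_b < 1):
        raise ValueError("indices do not lie within the stated bracket")
    if f_a == f_b:
        raise ValueError("degenerate pair: identical index fractions")
    d = (math.log10(tx_a) - math.log10(tx_b)) / (f_a - f_b)
    log_tn = math.log10(tx_a) - f_a * d
    return 10.0 ** log_tn, 10.0 ** (log_tn + d)


# ---------------------------------------------------------------------------
# MRM transitions and acquisition schedule


@dataclass(frozen=True)
class MRMTransition:
    """One precursor -> product transition with its acquisition settings."""

    analyte: str
    precursor: float
    product: float
    collision_energy: float
    role: str  # "quantifier" | "qualifier"
    dwell_ms: float = 20.0
    expected_relative_abundance: float = 100.0  # % of quantifier response

    CE_MIN = 3.0
    CE_MAX = 42.0

    def __post_init__(self) -> None:
        if self.product >= self.precursor:
            raise ValueError("product m/z must be below precursor m/z")
        if not self.CE_MIN <= self.collision_energy <= self.CE_MAX:
            raise ValueError(
                f"collision energy {self.collision_energy} outside scanned grid "
                f"{self.CE_MIN}-{self.CE_MAX} V"
            )
        if self.role not in ("quantifier", "qualifier"):
            raise ValueError(f"unknown role {self.role!r}")

    @property
    def ratio_label(self) -> str:
        """Relative-abundance label in 100/x convention, e.g. '100/73'."""
        return f"100/{self.expected_relative_abundance:.0f}"


def select_transitions(
    analyte: str,
    precursor: float,
    product_scans: Iterable[tuple[float, float, float]],
) -> list[MRMTransition]:
    """Pick quantifier + two qualifiers from product-ion scan results.

    ``product_scans`` yields (product m/z, collision energy V, abundance).
    For each distinct product the best collision energy (highest
    abundance) is retained; the most abundant product becomes the
    quantifier and the next two become qualifiers, with expected
    relative abundance 100*(qualifier/quantifier). Ties in abundance are
    broken toward the lower product m/z.
    """
    best: dict[float, tuple[float, float]] = {}  # product -> (abundance, CE)
    for product, ce, abundance in product_scans:
        if product not in best or abundance > best[product][0]:
            best[product] = (abundance, ce)
    if len(best) < 3:
        raise ValueError(
            f"need >=3 distinct product ions for {analyte}, got {len(best)}"
        )
    ranked = sorted(best.items(), key=lambda kv: (-kv[1][0], kv[0]))
    (q_mz, (q_ab, q_ce)) = ranked[0]
    out = [
        MRMTransition(analyte, precursor, q_mz, q_ce, "quantifier",
                      expected_relative_abundance=100.0)
    ]
    for mz, (ab, ce) in ranked[1:3]:
        out.append(
            MRMTransition(analyte, precursor, mz, ce, "qualifier",
                          expected_relative_abundance=100.0 * ab / q_ab)
        )
    return out


@dataclass(frozen=True)
class MethodSchedule:
    """Time-segmented MRM schedule: (start min, end min, transitions).

    Segments are half-open [start, end): a retention time on a boundary
    belongs to the later segment. Segments are non-overlapping and
    ordered.
    """

    segments: tuple[tuple[float, float, tuple[MRMTransition, ...]], ...]

    def __post_init__(self) -> None:
        prev_end = None
        for start, end, _ in self.segments:
            if end <= start:
                raise ValueError("segment end must exceed start")
            if prev_end is not None and start < prev_end - 1e-12:
                raise ValueError("segments overlap")
            prev_end = end

    def active_at(self, t: float) -> tuple[MRMTransition, ...]:
        for start, end, trans in self.segments:
            if start <= t < end:
                return trans
        return ()


def build_schedule(
    analyte_rts: Mapping[str, float],
    transitions: Mapping[str, Sequence[MRMTransition]],
    runtime: float,
    solvent_delay: float = 0.0,
    boundaries: Sequence[float] | None = None,
    fill_analyte: str | None = None,
) -> MethodSchedule:
    """Assemble a time-segmented MRM schedule.

    Each analyte's transitions are active in the segment containing its
    retention time (half-open [start, end) segments). Interior segment
    ``boundaries`` default to midpoints between the sorted distinct
    analyte RTs. Segments containing no expected RT monitor
    ``fill_analyte`` (default: the latest-eluting analyte, i.e. the
    quantification target is watched outside other analytes' windows).
    """
    if not analyte_rts:
        raise ValueError("no analytes given")
    for name, rt in analyte_rts.items():
        if not solvent_delay <= rt <= runtime:
            raise ValueError(
                f"retention time {rt} of {name} outside [{solvent_delay}, {runtime}]"
            )
    if boundaries is None:
        rts = sorted(set(analyte_rts.values()))
        boundaries = [(a + b) / 2 for a, b in zip(rts, rts[1:])]
    edges = [solvent_delay, *sorted(boundaries), runtime]
    if any(b <= solvent_delay or b >= runtime for b in boundaries):
        raise ValueError("boundaries must lie strictly inside (solvent_delay, runtime)")
    if fill_analyte is None:
        fill_analyte = max(analyte_rts, key=lambda a: analyte_rts[a])

    segs = []
    for start, end in zip(edges, edges[1:]):
        active = [
            name for name, rt in analyte_rts.items()
            if start <= rt < end or (rt == runtime and end == runtime)
        ]
        if not active:
            active = [fill_analyte]
        trans: list[MRMTransition] = []
        for name in sorted(active):
            trans.extend(transitions.get(name, ()))
        segs.append((start, end, tuple(trans)))
    return MethodSchedule(tuple(segs))
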