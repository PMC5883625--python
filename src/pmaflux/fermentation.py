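"""Quantitation arithmetic for polymalic acid (PMA) fermentations.

PMA is a polyester of l-malic acid (MA, C4H6O5); each ester bond releases
one water on acid hydrolysis, so a gram of polymer corresponds to more than
a gram of free monomer.  The module provides the residue/monomer mass
conversion, titer / yield / productivity arithmetic, percent changes, and
the 2^(−ΔΔCt) relative-expression formula used for qPCR — all deterministic,
with rounding kept explicit (round-half-up at a chosen precision) and raw
values carried at full precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd

__all__ = [
    "ATOMIC_MASS",
    "MW_MALIC_ACID",
    "MW_WATER",
    "residue_mass_ratio",
    "round_half_up",
    "pma_from_ma",
    "ma_from_pma",
    "productivity",
    "yield_g_g",
    "percent_change",
    "ddct_fold_change",
    "FermentationRecord",
    "QuantSummary",
    "read_timecourse",
    "summarize_run",
]

#: standard atomic masses (g/mol), CIAAW conventional values
ATOMIC_MASS = {"C": 12.011, "H": 1.008, "O": 15.999}

MW_MALIC_ACID = 4 * ATOMIC_MASS["C"] + 6 * ATOMIC_MASS["H"] + 5 * ATOMIC_MASS["O"]
MW_WATER = 2 * ATOMIC_MASS["H"] + ATOMIC_MASS["O"]


def residue_mass_ratio() -> float:
    """Mass of a malyl residue per mass of free malic acid:
    (MW(C4H6O5) − MW(H2O)) / MW(C4H6O5) ≈ 0.8657, commonly rounded to 0.87."""
    return (MW_MALIC_ACID - MW_WATER) / MW_MALIC_ACID


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round half away from zero at ``ndigits`` decimals (the convention used
    when comparing against printed values; banker's rounding is not)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def _check_factor(factor: float) -> None:
    if not 0 < factor < 1:
        raise ValueError(f"conversion factor must lie in (0, 1), got {factor}")


def pma_from_ma(ma_g_l: float, factor: float | None = None) -> float:
    """Polymer concentration equivalent to ``ma_g_l`` of free malic acid."""
    factor = residue_mass_ratio() if factor is None else factor
    _check_factor(factor)
    if ma_g_l < 0:
        raise ValueError("concentration must be non-negative")
    return ma_g_l * factor


def ma_from_pma(pma_g_l: float, factor: float | None = None) -> float:
    """Free malic acid released by full hydrolysis of ``pma_g_l`` of polymer."""
    factor = residue_mass_ratio() if factor is None else factor
    _check_factor(factor)
    if pma_g_l < 0:
        raise ValueError("concentration must be non-negative")
    return pma_g_l / factor


def productivity(titer_g_l: float, elapsed_h: float) -> float:
    """Volumetric productivity, g/L/h."""
    if elapsed_h <= 0:
        raise ValueError("elapsed time must be positive")
    return titer_g_l / elapsed_h


def yield_g_g(product_g_l: float, substrate_consumed_g_l: float) -> float:
    """Product formed per substrate consumed, g/g."""
    if substrate_consumed_g_l <= 0:
        raise ValueError("substrate consumed must be positive")
    return product_g_l / substrate_consumed_g_l


def percent_change(new_value: float, reference_value: float) -> float:
    """(new − reference) / reference × 100.  Asymmetric by construction:
    percent_change(a, b) does not negate percent_change(b, a)."""
    if reference_value <= 0:
        raise ValueError("reference value must be positive")
    return (new_value - reference_value) / reference_value * 100.0


def ddct_fold_change(
    ct_target_treated: float,
    ct_reference_treated: float,
    ct_target_control: float,
    ct_reference_control: float,
) -> float:
    """Relative expression 2^(−ΔΔCt) with
    ΔΔCt = (Ct_target − Ct_ref)_treated − (Ct_target − Ct_ref)_control."""
    for ct in (ct_target_treated, ct_reference_treated,
               ct_target_control, ct_reference_control):
        if not math.isfinite(ct):
            raise ValueError("all Ct values must be finite")
    ddct = (ct_target_treated - ct_reference_treated) - (
        ct_target_control - ct_reference_control
    )
    return 2.0 ** (-ddct)


# ---------------------------------------------------------------------------
# time-course records

SUGAR_COLUMNS = ("sucrose_g_L", "glucose_g_L", "fructose_g_L")


@dataclass(frozen=True)
class FermentationRecord:
    """One broth sample: time, biomass, product and residual sugars (g/L)."""

    time_h: float
    biomass_g_L: float
    pma_g_L: float
    ma_g_L: float
    sugars_g_L: dict[str, float]

    def __post_init__(self) -> None:
        for label, value in (
            ("time_h", self.time_h),
            ("biomass_g_L", self.biomass_g_L),
            ("pma_g_L", self.pma_g_L),
            ("ma_g_L", self.ma_g_L),
            *((k, v) for k, v in self.sugars_g_L.items()),
        ):
            if value < 0:
                raise ValueError(f"{label} must be non-negative, got {value}")

    @property
    def total_sugar_g_L(self) -> float:
        return sum(self.sugars_g_L.values())


@dataclass(frozen=True)
class QuantSummary:
    """Endpoint quantities of one run.  ``final_titer_g_L`` is the PMA titer;
    ``final_ma_g_L`` the malic-acid equivalent after hydrolysis; yield and
    productivity follow the malic-acid accounting convention."""

    final_titer_g_L: float
    final_ma_g_L: float
    elapsed_h: float
    productivity_g_L_h: float
    yield_g_g: float | None
    conversion_factor: float


def read_timecourse(path: str | Path) -> list[FermentationRecord]:
    """Read a CSV time course (columns time_h, biomass_g_L, pma_g_L, ma_g_L,
    sucrose_g_L, glucose_g_L, fructose_g_L) into records; times must be
    non-decreasing."""
    df = pd.read_csv(path, comment="#")
    required = {"time_h", "biomass_g_L", "pma_g_L", "ma_g_L"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        sugars = {c: float(row[c]) for c in SUGAR_COLUMNS if c in df.columns}
        records.append(
            FermentationRecord(
                time_h=float(row["time_h"]),
                biomass_g_L=float(row["biomass_g_L"]),
                pma_g_L=float(row["pma_g_L"]),
                ma_g_L=float(row["ma_g_L"]),
                sugars_g_L=sugars,
            )
        )
    times = [r.time_h for r in records]
    if any(t1 > t2 for t1, t2 in zip(times, times[1:])):
        raise ValueError(f"{path}: time_h must be non-decreasing")
    return records


def summarize_run(
    records: list[FermentationRecord], factor: float | None = None
) -> QuantSummary:
    """Endpoint titer, malic-acid equivalent, productivity and yield of a run.

    The conversion factor is an explicit argument (default: the exact residue
    mass ratio) and is never inferred from the data.  Yield is malic acid
    formed per total sugar consumed (initial − final), ``None`` when no sugar
    consumption is recorded.
    """
    if not records:
        raise ValueError("empty time course")
    factor = residue_mass_ratio() if factor is None else factor
    _check_factor(factor)
    first, last = records[0], records[-1]
    elapsed = last.time_h - first.time_h
    if elapsed <= 0:
        raise ValueError("time course must span positive time")
    pma = last.pma_g_L if last.pma_g_L > 0 else pma_from_ma(last.ma_g_L, factor)
    ma = last.ma_g_L if last.ma_g_L > 0 else ma_from_pma(pma, factor)
    consumed = first.total_sugar_g_L - last.total_sugar_g_L
    return QuantSummary(
        final_titer_g_L=pma,
        final_ma_g_L=ma,
        elapsed_h=elapsed,
        productivity_g_L_h=productivity(ma, elapsed),
        yield_g_g=yield_g_g(ma, consumed) if consumed > 0 else None,
        conversion_factor=factor,
    )
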