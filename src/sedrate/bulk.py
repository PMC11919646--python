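"""Bulk extrapolation: per-cell rates -> volumetric rates, units, dilutions.

A mean per-cell rate R (fmol cell^-1 h^-1), a capability fraction f (the
share of sorted cells whose genomes encode the pathway) and a cell
concentration C (cells per cm^3 of sediment or per ml of slurry) combine to a
volumetric rate

    nmol h^-1 cm^-3  =  R * f * C / 1e6        (fmol -> nmol)

All unit conversions are exact rationals (day = 24 h, 10^3 between mole
prefixes, 1 ml = 1 cm^3, 1 L = 1000 ml); display rounding is a separate,
explicit step so reported figures can match published precision without
contaminating arithmetic.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from fractions import Fraction

from .errors import ConfigError, UnitError

logger = logging.getLogger(__name__)

# --- unit lattice -----------------------------------------------------------

#: moles per unit, as exact rationals
_AMOUNT = {
    "fmol": Fraction(1, 10**15),
    "pmol": Fraction(1, 10**12),
    "nmol": Fraction(1, 10**9),
}
#: hours per unit
_TIME = {"h": Fraction(1), "day": Fraction(24)}
#: millilitres per unit; "cell" is a count basis, not interconvertible
_BASIS = {"cell": None, "ml": Fraction(1), "cm3": Fraction(1),
          "L": Fraction(1000)}

_ALIASES = {
    "hr": "h", "hour": "h", "hours": "h", "d": "day", "days": "day",
    "l": "L", "liter": "L", "litre": "L", "cc": "cm3", "cm^3": "cm3",
    "cm³": "cm3", "mL": "ml",
    # exponent stripping reduces both "cm-3" and bare "cm3" to "cm"
    "cm": "cm3",
}


def _parse_unit(unit: str) -> tuple[str, str, str]:
    """Parse e.g. 'nmol h-1 cm-3', 'fmol/cell/h' or 'nmol day^-1 L^-1'
    into (amount, time, basis)."""
    tokens = re.split(r"[\s/·*]+", unit.strip())
    tokens = [re.sub(r"(\^?-?\d+|⁻[¹²³])$", "", t) for t in tokens if t]
    tokens = [_ALIASES.get(t, _ALIASES.get(t.lower(), t)) for t in tokens]
    amount = time = basis = None
    for t in tokens:
        if t in _AMOUNT:
            amount = t
        elif t in _TIME:
            time = t
        elif t in _BASIS:
            basis = t
        else:
            raise UnitError(
                f"unsupported unit token {t!r} in {unit!r}; supported lattice: "
                f"{sorted(_AMOUNT)} x {sorted(_BASIS)} x {sorted(_TIME)}")
    if amount is None or time is None or basis is None:
        raise UnitError(
            f"unit {unit!r} must name an amount, a time and a per-cell/volume "
            f"basis, e.g. 'nmol h-1 cm-3'")
    return amount, time, basis


def convert_rate(value: float, from_unit: str, to_unit: str,
                 decimals: int | None = None) -> float:
    """Exact rational conversion within {fmol,pmol,nmol} x {cell,ml,cm3,L}
    x {h,day}.

    ``decimals``, if given, applies display rounding to the result;
    conversion itself is never rounded.

    >>> convert_rate(4670, "nmol day-1 cm-3", "nmol h-1 cm-3", decimals=0)
    195.0
    """
    fa, ft, fb = _parse_unit(from_unit)
    ta, tt, tb = _parse_unit(to_unit)
    if (fb == "cell") != (tb == "cell"):
        raise UnitError(
            f"cannot convert between per-cell and per-volume bases "
            f"({from_unit!r} -> {to_unit!r})")
    factor = _AMOUNT[fa] / _AMOUNT[ta]
    factor *= _TIME[tt] / _TIME[ft]          # per-from-time -> per-to-time
    if fb != "cell":
        factor *= _BASIS[tb] / _BASIS[fb]    # per-from-vol -> per-to-vol
    out = float(Fraction(value) * factor)
    if decimals is not None:
        out = round(out, decimals)
    return out


def paper_decimals(value: float) -> int:
    """Display-precision heuristic: whole numbers at >=10, one decimal below."""
    return 0 if abs(value) >= 10 else 1


# --- volumetric extrapolation -----------------------------------------------


@dataclass(frozen=True)
class BulkRateInput:
    """Inputs to the per-cell -> volumetric extrapolation."""

    mean_rate_fmol_per_cell_h: float
    capability_fraction: float
    cells_per_cm3: float
    dilution_chain: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.mean_rate_fmol_per_cell_h < 0:
            raise ConfigError("mean per-cell rate must be >= 0")
        if not 0.0 <= self.capability_fraction <= 1.0:
            raise ConfigError("capability fraction must be in [0, 1]")
        if self.cells_per_cm3 < 0:
            raise ConfigError("cell concentration must be >= 0")
        for f in self.dilution_chain:
            if not f > 0:
                raise ConfigError(f"dilution fold must be > 0, got {f}")


@dataclass(frozen=True)
class BulkRateResult:
    """Volumetric rate with the full unit trail for auditability."""

    volumetric_rate_nmol_per_h_cm3: float
    inputs: BulkRateInput
    unit_trail: tuple[str, ...]

    def as_dict(self) -> dict:
        return {
            "volumetric_rate_nmol_per_h_cm3": self.volumetric_rate_nmol_per_h_cm3,
            "mean_rate_fmol_per_cell_h": self.inputs.mean_rate_fmol_per_cell_h,
            "capability_fraction": self.inputs.capability_fraction,
            "cells_per_cm3": self.inputs.cells_per_cm3,
            "dilution_chain": list(self.inputs.dilution_chain),
            "unit_trail": list(self.unit_trail),
        }


def volumetric_rate(inp: BulkRateInput) -> BulkRateResult:
    """Scale a mean per-cell rate to a bulk volumetric rate.

    The capability fraction normalizes the cell concentration to the share
    of cells genomically able to reduce sulfate; the 1e-6 factor converts
    fmol to nmol.
    """
    rate = (inp.mean_rate_fmol_per_cell_h * inp.capability_fraction
            * inp.cells_per_cm3 / 1e6)
    trail = (
        f"{inp.mean_rate_fmol_per_cell_h} fmol cell-1 h-1",
        f"x capability fraction {inp.capability_fraction}",
        f"x {inp.cells_per_cm3} cells cm-3",
        "x 1e-6 (fmol -> nmol)",
        f"= {rate} nmol h-1 cm-3",
    )
    return BulkRateResult(volumetric_rate_nmol_per_h_cm3=rate,
                          inputs=inp, unit_trail=trail)


def dilution_factor(chain) -> float:
    """Overall fold of a serial-dilution chain (product of per-step folds).

    A 1:10 slurry carried through a second 1:10 step is ``[10, 10] -> 100``.
    An empty chain is the identity (fold 1), logged as such.
    """
    chain = list(chain)
    if not chain:
        logger.info("dilution_factor: empty chain, treating as identity (1x)")
        return 1.0
    fold = 1.0
    for f in chain:
        if not f > 0:
            raise ConfigError(f"dilution fold must be > 0, got {f}")
        fold *= f
    return fold


def cells_per_cm3_from_counts(gated_count: int, analyzed_volume_ml: float,
                              dilution_chain=()) -> float:
    """Back-calculate active cells per cm^3 of source sediment from a gated
    event count: count / analyzed volume x overall dilution fold
    (1 ml = 1 cm^3)."""
    if not analyzed_volume_ml > 0:
        raise ConfigError("analyzed volume must be > 0 ml")
    return gated_count / analyzed_volume_ml * dilution_factor(dilution_chain)


def expected_bulk_accumulation(rate_nmol_per_h_ml: float, duration_h: float,
                               detection_limit_uM: float = 0.1
                               ) -> tuple[float, bool]:
    """Concentration change a volumetric rate would produce, and whether a
    bulk assay could see it.

    nmol ml^-1 is numerically uM (umol L^-1), so the accumulated change is
    simply rate x duration.  A change exactly at the detection limit counts
    as detectable (>= convention: nominally measurable).
    """
    if rate_nmol_per_h_ml < 0 or duration_h < 0 or detection_limit_uM < 0:
        raise ConfigError("rate, duration and detection limit must be >= 0")
    delta_uM = rate_nmol_per_h_ml * duration_h
    return delta_uM, delta_uM >= detection_limit_uM
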