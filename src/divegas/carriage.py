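"""Gas carriage: tension <-> content conversions for O2, CO2 and N2.

Blood O2 is carried bound to hemoglobin (Hill saturation curve) plus a
physically dissolved fraction; muscle O2 bound to myoglobin (hyperbolic,
Hill n = 1) plus dissolved; CO2 by an effective linear capacitance (the
slope of the whole-blood/tissue CO2 dissociation relation, bicarbonate
included); N2 and the dissolved fractions by Henry/Ostwald solubility with
a distinct, much larger solubility in fat than in aqueous media.

All content functions are continuous, non-negative and strictly monotone
in tension, so each has a well-defined inverse; the nonlinear blood-O2
inverse is evaluated from a dense precomputed table, the rest in closed
form. Temperature is fixed at 37 degC and there are no pH (Bohr/Haldane)
effects.

Contents are returned in ml STPD per liter of medium (matching the
conventional literature units); the kinetics engine divides by 1000 where
liters are needed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Mapping

import numpy as np

from .config import load_packaged, merge

GASES = ("n2", "o2", "co2")
MEDIA = ("blood", "lean", "fat")


@dataclass(frozen=True)
class CarriageConstants:
    """Solubility / dissociation constants (tensions kPa, contents ml/l)."""

    hb_o2_capacity: float            # ml O2 per g Hb
    hb_p50: float                    # kPa
    hb_hill_n: float
    mb_o2_capacity: float            # ml O2 per g Mb
    mb_p50: float                    # kPa
    co2_capacitance: dict[str, float]   # ml CO2 / (l kPa) per medium
    ostwald_n2: dict[str, float]        # ml N2 / (l kPa) per medium
    ostwald_o2: dict[str, float]
    ostwald_co2: dict[str, float]

    def __post_init__(self) -> None:
        for name in ("hb_o2_capacity", "hb_p50", "hb_hill_n", "mb_o2_capacity", "mb_p50"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for table_name in ("co2_capacitance", "ostwald_n2", "ostwald_o2", "ostwald_co2"):
            table = getattr(self, table_name)
            for medium in MEDIA:
                if table.get(medium, 0) <= 0:
                    raise ValueError(f"{table_name}[{medium}] must be positive")
        if self.ostwald_n2["fat"] <= self.ostwald_n2["lean"]:
            raise ValueError("fat N2 solubility must exceed aqueous N2 solubility")

    @classmethod
    def load(cls, overrides: Mapping[str, Any] | None = None) -> "CarriageConstants":
        raw = merge(load_packaged("gas_constants"), overrides)
        return cls(
            hb_o2_capacity=raw["hb_o2_capacity_ml_per_g"],
            hb_p50=raw["hb_p50_kpa"],
            hb_hill_n=raw["hb_hill_n"],
            mb_o2_capacity=raw["mb_o2_capacity_ml_per_g"],
            mb_p50=raw["mb_p50_kpa"],
            co2_capacitance=dict(raw["co2_capacitance_ml_per_l_kpa"]),
            ostwald_n2=dict(raw["ostwald_n2_ml_per_l_kpa"]),
            ostwald_o2=dict(raw["ostwald_o2_ml_per_l_kpa"]),
            ostwald_co2=dict(raw["ostwald_co2_ml_per_l_kpa"]),
        )


DEFAULT_CONSTANTS = CarriageConstants.load()


def _check_tension(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError("gas tension must be non-negative")
    return p


def hb_capacity(hb: float, constants: CarriageConstants = DEFAULT_CONSTANTS) -> float:
    """Hb-bound O2 capacity, ml O2 per liter of blood, from [Hb] in g/100 g."""
    return hb * 10.0 * constants.hb_o2_capacity  # g/100g -> g/l (density ~1), x ml/g


def o2_saturation_blood(po2, constants: CarriageConstants = DEFAULT_CONSTANTS):
    """Hemoglobin O2 saturation in [0, 1] (Hill curve)."""
    p = _check_tension(po2)
    pn = p ** constants.hb_hill_n
    return pn / (pn + constants.hb_p50 ** constants.hb_hill_n)


def o2_content_blood(po2, hb: float, constants: CarriageConstants = DEFAULT_CONSTANTS):
    """Blood O2 content (ml O2 / l): Hill-saturated Hb-bound plus dissolved."""
    p = _check_tension(po2)
    return hb_capacity(hb, constants) * o2_saturation_blood(p, constants) + constants.ostwald_o2["blood"] * p


def o2_content_muscle(po2, mb_per_liter: float, constants: CarriageConstants = DEFAULT_CONSTANTS):
    """Muscle O2 content (ml O2 / l): hyperbolic Mb-bound plus dissolved.

    ``mb_per_liter`` is the myoglobin concentration in g per liter of the
    compartment (a compartment-average when only part of the muscle mass
    carries myoglobin).
    """
    p = _check_tension(po2)
    cap = mb_per_liter * constants.mb_o2_capacity
    return cap * p / (p + constants.mb_p50) + constants.ostwald_o2["lean"] * p


def co2_content(pco2, medium: str, constants: CarriageConstants = DEFAULT_CONSTANTS):
    """CO2 content (ml/l) under the linear effective-capacitance model."""
    p = _check_tension(pco2)
    return constants.co2_capacitance[medium] * p


def inert_content(pn2, medium: str, constants: CarriageConstants = DEFAULT_CONSTANTS):
    """Dissolved N2 content (ml/l); fat uses the lipid solubility."""
    p = _check_tension(pn2)
    return constants.ostwald_n2[medium] * p


# ---------------------------------------------------------------------------
# inversions (content -> tension)

def o2_tension_muscle(content, mb_per_liter: float, constants: CarriageConstants = DEFAULT_CONSTANTS):
    """Invert :func:`o2_content_muscle` in closed form (quadratic)."""
    c = np.asarray(content, dtype=float)
    cap = mb_per_liter * constants.mb_o2_capacity
    sol = constants.ostwald_o2["lean"]
    b = cap + sol * constants.mb_p50 - c
    return (-b + np.sqrt(b * b + 4.0 * sol * c * constants.mb_p50)) / (2.0 * sol)


class BloodO2Table:
    """Dense tension grid for fast, vector-friendly blood O2 inversion."""

    def __init__(self, hb: float, constants: CarriageConstants = DEFAULT_CONSTANTS) -> None:
        self.hb = hb
        self.constants = constants
        # fine near the steep part of the Hill curve, coarser above
        grid = np.concatenate([np.linspace(0.0, 60.0, 24001), np.geomspace(60.01, 6000.0, 4000)])
        self._p = grid
        self._c = np.asarray(o2_content_blood(grid, hb, constants))

    def tension(self, content):
        return np.interp(content, self._c, self._p)

    def content(self, po2):
        return np.interp(po2, self._p, self._c)
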