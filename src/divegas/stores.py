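"""Compartmental O2 stores and calculated aerobic dive limits (cADL).

The cADL is the total usable O2 store divided by the rate of O2
consumption. The total store is split into three compartments:

* lung — alveolar O2 at dive start (volume convention configurable);
* blood — Hb-bound O2, arterial fraction at its initial saturation and
  venous fraction at a lower saturation (Kooyman-style convention);
* tissue — Mb-bound O2 in the locomotor muscle (plus an optional
  dissolved term).

Two store paths coexist: the *formula* path computed from a
:class:`~divegas.physio.PhysioParams` set, and the *published* path that
carries the per-compartment values printed for the 200 kg reference animal
of each ecotype (they differ by a few percent because the exact saturation
and lung-volume conventions behind the printed values are not stated).
"""

from __future__ import annotations

from dataclasses import dataclass

from .carriage import CarriageConstants, DEFAULT_CONSTANTS, hb_capacity
from .physio import PhysioParams
from .respiratory import total_lung_capacity
from .units import WATER_VAPOR_ATA

#: Default Kooyman-style blood saturation convention.
ARTERIAL_FRACTION = 1.0 / 3.0
ARTERIAL_SATURATION = 0.95
VENOUS_SATURATION_DEFICIT = 0.05  # saturation points below arterial
VENOUS_CONTENT_DEFICIT_ML_L = 50.0  # alternative: 5 vol% below arterial


@dataclass(frozen=True)
class O2StoreBreakdown:
    """Per-compartment O2 stores, liters, plus derived totals."""

    lung: float
    tissue: float
    blood: float
    body_mass: float

    @property
    def total(self) -> float:
        return self.lung + self.tissue + self.blood

    @property
    def mass_specific(self) -> float:
        """ml O2 per kg body mass."""
        return 1000.0 * self.total / self.body_mass


def lung_o2_store(
    body_mass: float,
    surface_alveolar: dict[str, float] | None = None,
    diving_lung_volume_fraction: float = 1.0,
    convention: str = "tlc_dry",
) -> float:
    """Alveolar O2 amount at dive start, liters.

    Conventions for the gas volume the surface O2 fraction applies to:
    ``tlc_dry`` (total lung capacity corrected for water vapor; default),
    ``tlc`` (uncorrected TLC), ``alveolar`` (93% of TLC).
    """
    if body_mass <= 0:
        raise ValueError("body mass must be positive")
    o2_frac = (surface_alveolar or {"o2": 0.133})["o2"]
    tlc, va_max, _ = total_lung_capacity(body_mass)
    volume = {
        "tlc_dry": tlc * (1.0 - WATER_VAPOR_ATA),
        "tlc": tlc,
        "alveolar": va_max,
    }[convention]
    return volume * diving_lung_volume_fraction * o2_frac


def blood_o2_store(
    params: PhysioParams,
    constants: CarriageConstants = DEFAULT_CONSTANTS,
    arterial_fraction: float = ARTERIAL_FRACTION,
    arterial_saturation: float = ARTERIAL_SATURATION,
    venous_deficit_mode: str = "saturation_points",
) -> float:
    """Usable blood O2 store, liters.

    The arterial fraction of the blood volume starts at
    ``arterial_saturation``; the venous fraction either 5 saturation points
    lower (``saturation_points``, default) or 5 vol% (50 ml O2/l) lower in
    content (``vol_percent``).
    """
    cap = hb_capacity(params.hb, constants) / 1000.0  # l O2 per l blood
    vb = params.blood_volume
    va = vb * arterial_fraction
    vv = vb - va
    arterial_content = cap * arterial_saturation
    if venous_deficit_mode == "saturation_points":
        venous_content = cap * (arterial_saturation - VENOUS_SATURATION_DEFICIT)
    elif venous_deficit_mode == "vol_percent":
        venous_content = arterial_content - VENOUS_CONTENT_DEFICIT_ML_L / 1000.0
    else:
        raise ValueError(f"unknown venous_deficit_mode {venous_deficit_mode!r}")
    return va * arterial_content + vv * max(venous_content, 0.0)


def tissue_o2_store(
    params: PhysioParams,
    constants: CarriageConstants = DEFAULT_CONSTANTS,
    include_dissolved: bool = False,
    dissolved_po2_kpa: float = 5.0,
) -> float:
    """Myoglobin-bound O2 in the locomotor muscle, liters.

    ``locomotor muscle mass x [Mb] x binding capacity``; optionally adds
    the O2 physically dissolved in the non-blood tissues at a nominal
    tissue PO2.
    """
    locomotor_kg = params.muscle_locomotor_fraction * params.body_mass
    mb_g_per_kg = params.mb * 10.0
    bound = locomotor_kg * mb_g_per_kg * constants.mb_o2_capacity / 1000.0
    if include_dissolved:
        tissue_l = sum(c.mass_fraction for c in params.compartments) * params.body_mass
        bound += tissue_l * constants.ostwald_o2["lean"] * dissolved_po2_kpa / 1000.0
    return bound


def compute_o2_stores(params: PhysioParams, diving_lung_volume_fraction: float = 1.0) -> O2StoreBreakdown:
    """Formula-path store breakdown from a physiology parameter set."""
    return O2StoreBreakdown(
        lung=lung_o2_store(params.body_mass, params.surface_alveolar, diving_lung_volume_fraction),
        tissue=tissue_o2_store(params),
        blood=blood_o2_store(params),
        body_mass=params.body_mass,
    )


def reference_o2_stores(params: PhysioParams) -> O2StoreBreakdown:
    """Published per-compartment stores for the 200 kg reference animal."""
    ref = params.reference_o2_stores
    if not ref:
        raise ValueError(f"no published store values carried for ecotype {params.ecotype!r}")
    return O2StoreBreakdown(lung=ref["lung"], tissue=ref["tissue"], blood=ref["blood"], body_mass=200.0)


def cadl(total_store: float, metabolic_rate: float) -> float:
    """Calculated aerobic dive limit, minutes: store (l) / rate (l O2 min^-1)."""
    if metabolic_rate <= 0:
        raise ValueError("metabolic rate must be positive")
    if total_store < 0:
        raise ValueError("total store must be non-negative")
    return total_store / metabolic_rate


def required_store(dive_duration: float, metabolic_rate: float, body_mass: float) -> float:
    """O2 store (ml O2 per kg) needed to keep a dive of this length aerobic."""
    if min(dive_duration, metabolic_rate, body_mass) <= 0:
        raise ValueError("all arguments must be positive")
    return dive_duration * metabolic_rate * 1000.0 / body_mass


#: Field metabolic rate used for cADL reporting, as a multiple of resting.
FIELD_METABOLIC_MULTIPLIER = 2.0

#: Field metabolic-rate range measured in coastal dolphins, ml O2 min^-1 kg^-1.
FIELD_RATE_RANGE_ML_MIN_KG = (11.7, 23.4)


def cadl_table(params: PhysioParams, breakdown: O2StoreBreakdown | None = None) -> dict[str, float]:
    """Store totals and cADLs at resting, field (2x resting) and the
    measured field-rate range, for one ecotype."""
    bd = breakdown if breakdown is not None else reference_o2_stores(params)
    vo2 = params.vo2_rest_total
    lo, hi = FIELD_RATE_RANGE_ML_MIN_KG
    return {
        "lung_l": bd.lung,
        "tissue_l": bd.tissue,
        "blood_l": bd.blood,
        "total_l": bd.total,
        "mass_specific_ml_kg": bd.mass_specific,
        "cadl_rest_min": cadl(bd.total, vo2),
        "cadl_field_min": cadl(bd.total, FIELD_METABOLIC_MULTIPLIER * vo2),
        "cadl_field_range_low_min": bd.mass_specific / hi,
        "cadl_field_range_high_min": bd.mass_specific / lo,
    }
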