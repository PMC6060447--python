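"""Unit conventions and pressure/depth conversions.

Internal conventions used throughout the package:

* tensions (partial pressures) in kPa; 1 ATA = 98.07 kPa
* gas amounts in liters STPD; gas contents in l STPD per l of medium
* volumes in liters, flows in l s^-1, metabolic rates in l O2 min^-1
* depth in meters of seawater; ambient pressure in ATA (1 + depth/10)
"""

from __future__ import annotations

#: kPa per atmosphere absolute.
ATA_KPA = 98.07

#: Water vapor partial pressure in the saturated respiratory tract at 37 degC, ATA.
WATER_VAPOR_ATA = 0.062

#: Meters of seawater per additional ATA.
MSW_PER_ATA = 10.0


def pressure_at_depth(depth_m: float) -> float:
    """Ambient pressure in ATA at a depth in meters of seawater.

    1 ATA at the surface, +1 ATA per 10 m (2 ATA at 10 m).
    """
    if depth_m < 0:
        raise ValueError(f"depth must be non-negative, got {depth_m}")
    return 1.0 + depth_m / MSW_PER_ATA


def depth_at_pressure(pressure_ata: float) -> float:
    """Inverse of :func:`pressure_at_depth`."""
    if pressure_ata < 1.0:
        raise ValueError(f"ambient pressure must be >= 1 ATA, got {pressure_ata}")
    return (pressure_ata - 1.0) * MSW_PER_ATA


def kpa(ata: float) -> float:
    """Convert a pressure from ATA to kPa."""
    return ata * ATA_KPA
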