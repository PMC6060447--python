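"""Ecotype-specific physiological parameter sets.

Two parameter sets ship with the package, for the coastal (Sarasota Bay,
shallow-diving) and offshore (Bermuda, deep-diving) bottlenose dolphin
ecotypes. Each set fixes the compartmental body composition (brain, fat,
central circulation, muscle + one blood compartment), O2-storage variables
([Hb], [Mb], hematocrit), per-compartment resting metabolic rates for a
200 kg reference animal, and the cardiac-output / blood-flow-distribution
schedule at the surface and during the dive response.

Metabolic rates and cardiac output are defined for the 200 kg reference
animal and rescaled to the requested body mass with a standard metabolic
allometry: mass-specific rates scale as ``(M/200)^(-0.25)`` (whole-animal
rates as ``M^0.75``), exponent configurable. At 200 kg the rescaling is the
identity, so all reference values are recovered exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Mapping

from .config import load_packaged, merge
from .respiratory import ComplianceParams

ECOTYPES = ("sarasota", "bermuda")
COMPARTMENTS = ("brain", "fat", "central_circulation", "muscle")

#: Reference body mass (kg) at which the shipped rates are defined.
REFERENCE_MASS = 200.0

#: Default allometric exponent for *mass-specific* rates.
ALLOMETRIC_EXPONENT = -0.25


@dataclass(frozen=True)
class CompartmentSpec:
    """One body compartment: size, metabolism, and perfusion shares."""

    name: str
    mass_fraction: float          # fraction of body mass
    vo2_rest: float               # resting O2 consumption, l O2 min^-1 (at PhysioParams.body_mass)
    perfusion_surface: float      # fraction of cardiac output at the surface
    perfusion_dive: float         # fraction of cardiac output during the dive response


@dataclass(frozen=True)
class PhysioParams:
    """Full physiological parameter set for one ecotype at one body mass."""

    ecotype: str
    body_mass: float                       # kg
    compartments: tuple[CompartmentSpec, ...]
    blood_fraction: float                  # blood mass fraction of body
    muscle_locomotor_fraction: float       # myoglobin-bearing muscle, fraction of body mass
    hb: float                              # g Hb per 100 g blood
    mb: float                              # g Mb per 100 g locomotor muscle
    hct: float                             # hematocrit, %
    q_rest: float                          # resting cardiac output, l min^-1 (at body_mass)
    surface_q_multiplier: float            # x resting while at the surface
    dive_q_multiplier: float               # x resting during the dive response
    dive_response_depth: float             # m; dive schedule engages below this depth
    vo2_rest_total: float                  # printed whole-animal resting VO2, l O2 min^-1
    compliance: ComplianceParams
    surface_alveolar: dict[str, float]     # partial pressures at the surface, ATA
    reference_o2_stores: dict[str, float] = field(default_factory=dict)  # printed, liters @200 kg

    def compartment(self, name: str) -> CompartmentSpec:
        for c in self.compartments:
            if c.name == name:
                return c
        raise KeyError(name)

    @property
    def blood_volume(self) -> float:
        """Blood volume in liters (1 kg of blood taken as 1 l)."""
        return self.blood_fraction * self.body_mass


def _allometric_factor(body_mass: float, exponent: float) -> float:
    # whole-animal rate factor: M * (M/Mref)^exponent / Mref = (M/Mref)^(1+exponent)
    return (body_mass / REFERENCE_MASS) ** (1.0 + exponent)


def load_ecotype(
    name: str,
    body_mass: float = REFERENCE_MASS,
    overrides: Mapping[str, Any] | None = None,
    compliance_variant: str = "updated_dolphin",
    allometric_exponent: float = ALLOMETRIC_EXPONENT,
) -> PhysioParams:
    """Load the shipped parameter set for an ecotype, rescaled to ``body_mass``.

    ``overrides`` (same mapping layout as the packaged YAML) are merged on
    top of the shipped defaults before rescaling.
    """
    if name not in ECOTYPES:
        raise ValueError(f"unknown ecotype {name!r}; expected one of {ECOTYPES}")
    if body_mass <= 0:
        raise ValueError(f"body mass must be positive, got {body_mass}")
    raw = merge(load_packaged(name), overrides)
    factor = _allometric_factor(body_mass, allometric_exponent)

    comps = tuple(
        CompartmentSpec(
            name=cname,
            mass_fraction=float(cfg["mass_fraction"]),
            vo2_rest=float(cfg["vo2_rest_l_per_min"]) * factor,
            perfusion_surface=float(cfg["perfusion_surface"]),
            perfusion_dive=float(cfg["perfusion_dive"]),
        )
        for cname, cfg in ((c, raw["compartments"][c]) for c in COMPARTMENTS)
    )
    return PhysioParams(
        ecotype=raw["ecotype"],
        body_mass=body_mass,
        compartments=comps,
        blood_fraction=float(raw["blood_fraction"]),
        muscle_locomotor_fraction=float(raw["muscle_locomotor_fraction"]),
        hb=float(raw["hb_g_per_100g"]),
        mb=float(raw["mb_g_per_100g_muscle"]),
        hct=float(raw["hct_percent"]),
        q_rest=float(raw["q_rest_l_per_min"]) * factor,
        surface_q_multiplier=float(raw["surface_q_multiplier"]),
        dive_q_multiplier=float(raw["dive_q_multiplier"]),
        dive_response_depth=float(raw["dive_response_depth_m"]),
        vo2_rest_total=float(raw["vo2_rest_total_l_per_min"]) * factor,
        compliance=ComplianceParams.load(compliance_variant),
        surface_alveolar={k: float(v) for k, v in raw["surface_alveolar_ata"].items()},
        reference_o2_stores={k: float(v) for k, v in raw.get("reference_o2_stores_l", {}).items()},
    )


def with_compliance(params: PhysioParams, variant: str) -> PhysioParams:
    """Return a copy of ``params`` using a different compliance variant."""
    return replace(params, compliance=ComplianceParams.load(variant))


def validate(params: PhysioParams) -> list[str]:
    """Check all parameter-set invariants; return a list of violations.

    An empty list means the set is valid. Each violation names the field
    and the rule it breaks. Mass fractions are *not* normalized (a small
    documented residual against 1 is allowed); perfusion fractions must sum
    to 1 in each circulatory state.
    """
    v: list[str] = []
    if params.ecotype not in ECOTYPES:
        v.append(f"ecotype: unknown label {params.ecotype!r}")
    if params.body_mass <= 0:
        v.append("body_mass: must be positive")
    names = [c.name for c in params.compartments]
    if sorted(names) != sorted(COMPARTMENTS):
        v.append(f"compartments: expected {set(COMPARTMENTS)}, got {set(names)}")

    for c in params.compartments:
        if not (0.0 < c.mass_fraction < 1.0):
            v.append(f"{c.name}.mass_fraction: must be in (0,1), got {c.mass_fraction}")
        if c.vo2_rest < 0:
            v.append(f"{c.name}.vo2_rest: must be >= 0, got {c.vo2_rest}")
        for state in ("surface", "dive"):
            frac = getattr(c, f"perfusion_{state}")
            if not (0.0 <= frac <= 1.0):
                v.append(f"{c.name}.perfusion_{state}: must be in [0,1], got {frac}")

    mass_sum = sum(c.mass_fraction for c in params.compartments) + params.blood_fraction
    if abs(mass_sum - 1.0) > 0.02:
        v.append(f"mass fractions + blood_fraction: sum {mass_sum:.4f} differs from 1 by > 0.02")
    for state in ("surface", "dive"):
        s = sum(getattr(c, f"perfusion_{state}") for c in params.compartments)
        if abs(s - 1.0) > 1e-9:
            v.append(f"perfusion_{state}: fractions sum to {s:.4f}, expected 1")

    alv_sum = sum(params.surface_alveolar.values())
    if abs(alv_sum - 1.0) > 0.01:
        v.append(f"surface_alveolar: components sum to {alv_sum:.4f} ATA, expected ~1")

    for fname in ("hb", "mb", "hct", "q_rest", "vo2_rest_total", "blood_fraction"):
        if getattr(params, fname) <= 0:
            v.append(f"{fname}: must be positive, got {getattr(params, fname)}")
    if not (0.0 < params.muscle_locomotor_fraction < 1.0):
        v.append("muscle_locomotor_fraction: must be in (0,1)")
    if params.dive_response_depth < 0:
        v.append("dive_response_depth: must be >= 0")

    comp_sum = sum(c.vo2_rest for c in params.compartments)
    if params.vo2_rest_total > 0 and abs(comp_sum - params.vo2_rest_total) > 0.011 * params.vo2_rest_total:
        v.append(
            f"vo2_rest_total: compartment rates sum to {comp_sum:.4f}, "
            f"inconsistent with whole-animal total {params.vo2_rest_total:.4f} (>1.1% apart)"
        )
    return v
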