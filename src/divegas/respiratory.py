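"""Pressure-dependent respiratory mechanics and pulmonary shunt.

Hydrostatic pressure compresses the respiratory system during a breath-hold
dive. Total lung gas obeys Boyle's law, and the compressed volume is
partitioned between the alveolar space and the conducting airways (dead
space) according to two structural volume-pressure relations. As the
alveolar space compresses, an increasing fraction of pulmonary blood flow
bypasses gas exchange (pulmonary shunt); at full alveolar collapse
(atelectasis) gas exchange stops entirely until the alveoli are recruited
again on ascent. The model is memoryless in pressure, so collapse and
recruitment occur at the same ambient pressure on descent and ascent.

Functional forms
----------------
The structural relations are expressed as normalized volumes (fraction of
the fully inflated volume) against structural (collapsing) pressure ``p``
in ATA:

* alveolar space: ``vA(p) = (1 + a*p/b)^(-c)`` — a survival-type curve whose
  shape parameters ``(a, b, c)`` come from respiratory compliance fits;
* dead space (collapsible tube): ``vD(p) = exp(-(p/|Kp|)^n)``.

Both are monotone non-increasing, equal 1 at zero structural pressure and
decay to 0. The exact published forms from the compliance literature can be
substituted behind :class:`RespiratoryModel` without touching the rest of
the package; all downstream behavior is asserted property-wise (limits,
monotonicity, updated-vs-legacy orderings), never on the form itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .config import load_packaged
from .units import pressure_at_depth  # noqa: F401  (re-exported: part of this module's surface)

#: Dead space (trachea + bronchi) as a fraction of total lung capacity.
DEAD_SPACE_FRACTION = 0.07

#: Normalized alveolar volume below which the lung is considered collapsed
#: (atelectasis): gas exchange stops and the shunt is forced to 1.
COLLAPSE_THRESHOLD = 1e-3

#: Default shunt power-law exponent. The convex default (< 1) keeps the
#: shunt near zero under moderate Boyle compression and lets it rise
#: steeply as the alveoli approach collapse, reproducing the observed
#: pattern (no shunt on shallow dives; descent arterial hyperoxia before
#: atelectasis on deep dives). gamma = 1 gives a shunt linear in relative
#: alveolar volume.
DEFAULT_SHUNT_GAMMA = 0.1


@dataclass(frozen=True)
class ComplianceParams:
    """Shape parameters of the structural volume-pressure relations.

    ``a, b, c`` describe the alveolar space, ``kp, n`` the conducting
    airways. Two variants ship with the package: ``updated_dolphin``
    (dolphin-specific compliance: stiffer trachea, more compliant alveoli)
    and ``legacy`` (earlier multi-species estimates).
    """

    a: float
    b: float
    c: float
    kp: float
    n: float
    variant: str = "custom"

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "kp", "n"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"compliance parameter {name} must be finite")
        if self.b <= 0 or self.kp == 0:
            raise ValueError("b must be > 0 and kp nonzero")

    @classmethod
    def load(cls, variant: str = "updated_dolphin") -> "ComplianceParams":
        table = load_packaged("compliance")
        if variant not in table:
            raise KeyError(f"unknown compliance variant {variant!r}; have {sorted(table)}")
        row = table[variant]
        return cls(a=row["a"], b=row["b"], c=row["c"], kp=row["kp"], n=row["n"], variant=variant)

    # -- normalized structural curves ------------------------------------

    def alveolar_fraction(self, p_struct):
        """Normalized alveolar volume at structural pressure ``p_struct`` (ATA)."""
        p = np.asarray(p_struct, dtype=float)
        return (1.0 + self.a * p / self.b) ** (-self.c)

    def dead_space_fraction(self, p_struct):
        """Normalized dead-space volume at structural pressure ``p_struct`` (ATA)."""
        p = np.asarray(p_struct, dtype=float)
        return np.exp(-((p / abs(self.kp)) ** self.n))


@dataclass(frozen=True)
class RespiratoryState:
    """Respiratory geometry at one ambient pressure."""

    pressure: float  # ATA
    v_alv: float     # alveolar gas volume, liters
    v_dead: float    # dead-space gas volume, liters
    shunt: float     # pulmonary shunt fraction [0, 1]
    collapsed: bool  # True when the alveolar space has collapsed

    def __post_init__(self) -> None:
        if not (0.0 <= self.shunt <= 1.0):
            raise ValueError(f"shunt must be in [0,1], got {self.shunt}")
        if self.v_alv < -1e-12 or self.v_dead < -1e-12:
            raise ValueError("volumes must be non-negative")
        if self.collapsed and self.shunt != 1.0:
            raise ValueError("a collapsed lung implies shunt = 1")


def total_lung_capacity(body_mass: float) -> tuple[float, float, float]:
    """Estimated total lung capacity and its partition, liters.

    TLC scales allometrically as ``0.135 * M^0.92`` (M in kg); the dead
    space is 7% of TLC and the maximum alveolar volume the remaining 93%.

    Returns ``(tlc, v_alv_max, v_dead_max)``.
    """
    if body_mass <= 0:
        raise ValueError(f"body mass must be positive, got {body_mass}")
    tlc = 0.135 * body_mass ** 0.92
    v_dead_max = DEAD_SPACE_FRACTION * tlc
    return tlc, tlc - v_dead_max, v_dead_max


def shunt_fraction(v_alv: float, v_alv_max: float, gamma: float = DEFAULT_SHUNT_GAMMA) -> float:
    """Pulmonary shunt as a function of relative alveolar inflation.

    ``shunt = clamp(1 - (v_alv/v_alv_max)^gamma, 0, 1)``: zero at full
    inflation, one at collapse, monotone non-increasing in ``v_alv``. The
    exponent ``gamma`` reshapes the power-law rise of the shunt with
    compression; ``gamma = 1`` is linear in relative volume, the convex
    default keeps the shunt small until the alveoli are strongly compressed
    (see :data:`DEFAULT_SHUNT_GAMMA`).
    """
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    if v_alv < -1e-12 or v_alv > v_alv_max * (1 + 1e-9):
        raise ValueError(f"v_alv={v_alv} outside [0, {v_alv_max}]")
    r = min(max(v_alv / v_alv_max, 0.0), 1.0)
    return float(min(max(1.0 - r ** gamma, 0.0), 1.0))


class RespiratoryModel:
    """Partition of Boyle-compressed lung gas between alveoli and dead space.

    Given a total (1-ATA equivalent) gas amount, the gas volume at ambient
    pressure follows Boyle's law; a single structural pressure is found such
    that the two structural curves jointly account for that volume. A dense
    precomputed grid makes per-step lookups cheap inside the ODE engine; the
    exact solved path (:meth:`state_at`, absolute tolerance 1e-9 l) is used
    where precision matters.
    """

    #: structural-pressure grid upper bound, ATA (far beyond full collapse)
    P_STRUCT_MAX = 2000.0

    def __init__(
        self,
        compliance: ComplianceParams,
        v_alv_start: float,
        v_dead_start: float,
        gamma: float = DEFAULT_SHUNT_GAMMA,
        collapse_threshold: float = COLLAPSE_THRESHOLD,
        grid_size: int = 6000,
    ) -> None:
        if v_alv_start <= 0 or v_dead_start < 0:
            raise ValueError("non-physical start volumes")
        self.compliance = compliance
        self.v_alv_start = float(v_alv_start)
        self.v_dead_start = float(v_dead_start)
        self.gamma = float(gamma)
        self.collapse_threshold = float(collapse_threshold)

        ps = np.concatenate([[0.0], np.geomspace(1e-5, self.P_STRUCT_MAX, grid_size)])
        va = self.v_alv_start * compliance.alveolar_fraction(ps)
        vd = self.v_dead_start * compliance.dead_space_fraction(ps)
        vol = va + vd
        # np.interp needs ascending x: store volume-ascending views
        self._vol_grid = vol[::-1].copy()
        self._va_grid = va[::-1].copy()
        self._vd_grid = vd[::-1].copy()
        self._ps_grid = ps[::-1].copy()

    # -- fast path (grid interpolation) ----------------------------------

    def volumes_for(self, total_volume: float) -> tuple[float, float]:
        """Alveolar and dead-space volumes holding ``total_volume`` liters of gas."""
        v = min(max(total_volume, float(self._vol_grid[0])), float(self._vol_grid[-1]))
        v_alv = float(np.interp(v, self._vol_grid, self._va_grid))
        v_dead = float(np.interp(v, self._vol_grid, self._vd_grid))
        return v_alv, v_dead

    def lookup(self, pressure: float, gas_amount_1ata: float) -> tuple[float, float, float, bool]:
        """Fast per-step geometry: ``(v_alv, v_dead, shunt, collapsed)``.

        ``gas_amount_1ata`` is the current total lung gas expressed as the
        volume it would occupy at 1 ATA.
        """
        v_target = gas_amount_1ata / pressure
        v_alv, v_dead = self.volumes_for(v_target)
        collapsed = v_alv < self.collapse_threshold * self.v_alv_start
        s = 1.0 if collapsed else shunt_fraction(v_alv, self.v_alv_start, self.gamma)
        return v_alv, v_dead, s, collapsed

    # -- exact path (root finding) ----------------------------------------

    def state_at(self, pressure: float, dive_start_volume: float | None = None) -> RespiratoryState:
        """Exact respiratory state at an ambient pressure (ATA).

        ``dive_start_volume`` is the total lung gas volume at the surface
        (defaults to the model's start volumes). The structural pressure is
        solved by 1-D root finding to an absolute volume tolerance of 1e-9 l.
        """
        if pressure < 1.0:
            raise ValueError(f"ambient pressure must be >= 1 ATA, got {pressure}")
        v0 = self.v_alv_start + self.v_dead_start if dive_start_volume is None else dive_start_volume
        if not (0 < v0 <= self.v_alv_start + self.v_dead_start + 1e-9):
            raise ValueError("dive_start_volume must be in (0, start volume]")
        scale = v0 / (self.v_alv_start + self.v_dead_start)
        va0 = self.v_alv_start * scale
        vd0 = self.v_dead_start * scale
        v_target = v0 / pressure

        def residual(p_struct: float) -> float:
            return (
                va0 * float(self.compliance.alveolar_fraction(p_struct))
                + vd0 * float(self.compliance.dead_space_fraction(p_struct))
                - v_target
            )

        if residual(0.0) <= 0.0:  # no compression needed (surface)
            v_alv, v_dead = va0, vd0
        elif residual(self.P_STRUCT_MAX) > 0.0:
            raise RuntimeError(f"volume solver failed to bracket at {pressure} ATA")
        else:
            p_struct = brentq(residual, 0.0, self.P_STRUCT_MAX, xtol=1e-12, rtol=1e-15)
            v_alv = va0 * float(self.compliance.alveolar_fraction(p_struct))
            v_dead = vd0 * float(self.compliance.dead_space_fraction(p_struct))
            if abs(v_alv + v_dead - v_target) > 1e-9:
                raise RuntimeError(f"volume solver did not converge at {pressure} ATA")
        collapsed = v_alv < self.collapse_threshold * self.v_alv_start
        s = 1.0 if collapsed else shunt_fraction(v_alv, self.v_alv_start, self.gamma)
        return RespiratoryState(pressure=pressure, v_alv=v_alv, v_dead=v_dead, shunt=s, collapsed=collapsed)


def compartment_volumes(
    pressure: float,
    params: ComplianceParams,
    dive_start_volume: float,
    body_mass: float | None = None,
    gamma: float = DEFAULT_SHUNT_GAMMA,
) -> RespiratoryState:
    """Respiratory state at an ambient pressure for a given dive-start volume.

    The dive-start volume is split 93%/7% between alveolar space and dead
    space (or according to the TLC of ``body_mass`` when given), then
    compressed per Boyle's law and partitioned along the structural curves.
    """
    if dive_start_volume <= 0:
        raise ValueError("dive_start_volume must be positive")
    if body_mass is not None:
        tlc, va_max, vd_max = total_lung_capacity(body_mass)
        if dive_start_volume > tlc + 1e-9:
            raise ValueError("dive_start_volume exceeds total lung capacity")
        frac = dive_start_volume / tlc
        model = RespiratoryModel(params, va_max * frac, vd_max * frac, gamma=gamma)
    else:
        model = RespiratoryModel(
            params,
            dive_start_volume * (1 - DEAD_SPACE_FRACTION),
            dive_start_volume * DEAD_SPACE_FRACTION,
            gamma=gamma,
        )
    return model.state_at(pressure)
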