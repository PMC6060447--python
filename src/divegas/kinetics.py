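"""Coupled lung-blood-tissue gas exchange over a depth time series.

The body is partitioned into four perfused tissue compartments (brain,
fat, central circulation, muscle) plus arterial and mixed-venous blood
pools and a homogeneous lung gas store. At each instant:

1. respiratory mechanics give the alveolar volume and pulmonary shunt at
   the current ambient pressure (Boyle compression partitioned along the
   structural curves);
2. the non-shunted fraction of cardiac output equilibrates with alveolar
   gas (no diffusion limitation at the alveolus), so lung-blood flux is
   ``q (1-s) (C_blood(P_A) - C_venous)`` per gas, zero at collapse;
3. each tissue exchanges with arterial blood in proportion to its share
   of cardiac output (perfusion-limited exchange) and consumes O2 /
   produces CO2 at its metabolic rate;
4. venous return is the perfusion-weighted mixture of tissue outflows;
5. at the surface, alveolar composition is reset to the fixed surface
   values and arterial blood equals alveolar (no surface diffusion
   resistance; breathing is treated as an instantaneous alveolar reset);
6. the diving perfusion schedule (reduced cardiac output, redistributed
   flow) engages only below the ecotype's dive-response depth.

State is integrated with fixed-step classical RK4 (default dt = 0.1 s)
over the linearly interpolated depth profile. A tissue whose O2 store is
exhausted stops consuming (its deficit is implicitly anaerobic) and the
dive is flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .carriage import CarriageConstants, DEFAULT_CONSTANTS, hb_capacity, o2_content_blood
from .physio import COMPARTMENTS, PhysioParams
from .records import DepthSeries, DiveRecord
from .respiratory import DEFAULT_SHUNT_GAMMA, RespiratoryModel, shunt_fraction, total_lung_capacity
from .units import ATA_KPA, WATER_VAPOR_ATA

GAS_NAMES = ("n2", "o2", "co2")
_N2, _O2, _CO2 = 0, 1, 2
_MUSCLE = COMPARTMENTS.index("muscle")

#: Tissue O2 tension (kPa) below which a compartment counts as exhausted.
EXHAUSTION_PO2_KPA = 0.05


@dataclass(frozen=True)
class SolverConfig:
    """Numerical and model options for :func:`simulate`."""

    dt: float = 0.1                      # s, RK4 step
    output_dt: float | None = None       # s, recording interval (None = dt)
    respiratory_quotient: float = 0.9    # CO2 produced per O2 consumed
    metabolic_multiplier: float = 2.0    # x resting (field rate) during simulation
    surface_threshold: float = 0.1       # m, at/above counts as surfaced
    diving_lung_volume_fraction: float = 1.0  # fraction of TLC at dive start
    shunt_gamma: float = DEFAULT_SHUNT_GAMMA  # shunt power-law exponent
    arterial_volume_fraction: float = 1.0 / 3.0
    dive_response_ramp_m: float = 0.0    # 0 = instantaneous schedule switch
    metabolism_enabled: bool = True
    shunt_override: float | None = None  # force a fixed shunt fraction (diagnostics)


@dataclass(frozen=True)
class GasState:
    """Full gas state at one instant (tensions in kPa, volumes in liters)."""

    time: float
    depth: float
    alveolar: dict[str, float]   # pa_n2, pa_o2, pa_co2, volume
    arterial: dict[str, float]
    venous: dict[str, float]
    tissues: dict[str, dict[str, float]]
    q_tot: float                 # l s^-1
    perfusion: dict[str, float]
    shunt: float
    collapsed: bool


@dataclass
class TensionTrajectory:
    """Time-indexed gas states at solver output resolution."""

    time: np.ndarray          # (n,)
    depth: np.ndarray         # (n,)
    pressure: np.ndarray      # (n,) ATA
    v_alv: np.ndarray         # (n,) liters
    v_dead: np.ndarray        # (n,)
    shunt: np.ndarray         # (n,)
    collapsed: np.ndarray     # (n,) bool
    alveolar: np.ndarray      # (n, 3) kPa
    arterial: np.ndarray      # (n, 3) kPa
    venous: np.ndarray        # (n, 3) kPa
    tissues: np.ndarray       # (n, 4, 3) kPa
    q_tot: np.ndarray         # (n,) l/s
    perfusion: np.ndarray     # (n, 4)
    cum_o2_uptake: np.ndarray     # (n,) liters, lung -> blood
    cum_o2_consumed: np.ndarray   # (n,) liters, metabolized
    raw_states: np.ndarray    # (n, 23) solver state snapshots
    params: PhysioParams = field(repr=False, default=None)
    solver: SolverConfig = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("trajectory times must be strictly increasing")

    def state(self, i: int) -> GasState:
        """Materialize one sample as a :class:`GasState`."""
        tissues = {
            name: {f"p{g}": float(self.tissues[i, c, k]) for k, g in enumerate(GAS_NAMES)}
            for c, name in enumerate(COMPARTMENTS)
        }
        return GasState(
            time=float(self.time[i]),
            depth=float(self.depth[i]),
            alveolar={
                **{f"pa_{g}": float(self.alveolar[i, k]) for k, g in enumerate(GAS_NAMES)},
                "volume": float(self.v_alv[i]),
            },
            arterial={f"pa_{g}": float(self.arterial[i, k]) for k, g in enumerate(GAS_NAMES)},
            venous={f"pv_{g}": float(self.venous[i, k]) for k, g in enumerate(GAS_NAMES)},
            tissues=tissues,
            q_tot=float(self.q_tot[i]),
            perfusion={name: float(self.perfusion[i, c]) for c, name in enumerate(COMPARTMENTS)},
            shunt=float(self.shunt[i]),
            collapsed=bool(self.collapsed[i]),
        )

    def to_dataframe(self) -> pd.DataFrame:
        cols: dict[str, np.ndarray] = {
            "time_s": self.time,
            "depth_m": self.depth,
            "pressure_ata": self.pressure,
            "v_alv_l": self.v_alv,
            "v_dead_l": self.v_dead,
            "shunt": self.shunt,
            "collapsed": self.collapsed.astype(int),
            "q_tot_l_s": self.q_tot,
        }
        for k, g in enumerate(GAS_NAMES):
            cols[f"pa_alv_{g}_kpa"] = self.alveolar[:, k]
            cols[f"pa_art_{g}_kpa"] = self.arterial[:, k]
            cols[f"pv_ven_{g}_kpa"] = self.venous[:, k]
        for c, name in enumerate(COMPARTMENTS):
            for k, g in enumerate(GAS_NAMES):
                cols[f"pt_{name}_{g}_kpa"] = self.tissues[:, c, k]
        cols["cum_o2_uptake_l"] = self.cum_o2_uptake
        cols["cum_o2_consumed_l"] = self.cum_o2_consumed
        return pd.DataFrame(cols)


class _EngineContext:
    """Precomputed constants and fast conversions for one simulation."""

    def __init__(self, params: PhysioParams, solver: SolverConfig, constants: CarriageConstants):
        self.params = params
        self.solver = solver
        self.constants = constants

        # compartment geometry (1 kg ~ 1 l for soft tissue and blood)
        self.v_tissue = np.array([params.compartment(c).mass_fraction for c in COMPARTMENTS]) * params.body_mass
        blood_volume = params.blood_volume
        self.v_art = blood_volume * solver.arterial_volume_fraction
        self.v_ven = blood_volume - self.v_art

        # metabolic rates, l O2 s^-1, at the simulated (field) multiplier
        mult = solver.metabolic_multiplier if solver.metabolism_enabled else 0.0
        self.vo2 = np.array([params.compartment(c).vo2_rest for c in COMPARTMENTS]) * mult / 60.0
        self.rq = solver.respiratory_quotient

        # perfusion schedules
        self.frac_surface = np.array([params.compartment(c).perfusion_surface for c in COMPARTMENTS])
        self.frac_dive = np.array([params.compartment(c).perfusion_dive for c in COMPARTMENTS])
        q_rest_ls = params.q_rest / 60.0
        self.q_surface = q_rest_ls * params.surface_q_multiplier
        self.q_dive = q_rest_ls * params.dive_q_multiplier
        self.dive_engage_depth = max(params.dive_response_depth, solver.surface_threshold)
        self.ramp_m = solver.dive_response_ramp_m

        # gas capacitances, l STPD / (l kPa)
        med = ["lean", "fat", "lean", "lean"]  # brain, fat, cc, muscle media
        self.beta_t_n2 = np.array([constants.ostwald_n2[m] for m in med]) / 1000.0
        self.beta_t_co2 = np.array([constants.co2_capacitance[m] for m in med]) / 1000.0
        self.sol_t_o2 = np.array([constants.ostwald_o2[m if m != "fat" else "lean"] for m in med]) / 1000.0
        self.beta_bl_n2 = constants.ostwald_n2["blood"] / 1000.0
        self.beta_bl_co2 = constants.co2_capacitance["blood"] / 1000.0

        # blood O2 curve (l/l) on a dense grid for both directions
        grid = np.concatenate([np.linspace(0.0, 60.0, 24001), np.geomspace(60.01, 6000.0, 4000)])
        self.bl_o2_p = grid
        self.bl_o2_c = np.asarray(o2_content_blood(grid, params.hb, constants)) / 1000.0
        self.hb_cap = hb_capacity(params.hb, constants) / 1000.0

        # muscle myoglobin, compartment-average g/l
        locomotor_kg = params.muscle_locomotor_fraction * params.body_mass
        self.mb_per_l = params.mb * 10.0 * locomotor_kg / self.v_tissue[_MUSCLE]
        self.mb_cap = self.mb_per_l * constants.mb_o2_capacity / 1000.0  # l/l
        self.mb_p50 = constants.mb_p50

        # lung: dive-start volumes and respiratory model
        tlc, va_max, vd_max = total_lung_capacity(params.body_mass)
        f = solver.diving_lung_volume_fraction
        self.v0 = tlc * f
        self.resp = RespiratoryModel(
            params.compliance, va_max * f, vd_max * f, gamma=solver.shunt_gamma
        )
        alv = params.surface_alveolar
        self.surface_frac = np.array([alv["n2"], alv["o2"], alv["co2"]])
        self.lung_surface = self.v0 * self.surface_frac  # l STPD, dry gases
        self.pa_surface = self.surface_frac * ATA_KPA    # surface alveolar tensions, kPa
        self.ca_surface = self._blood_content(self.pa_surface)

    # -- conversions -----------------------------------------------------

    def _blood_content(self, tensions: np.ndarray) -> np.ndarray:
        """Blood contents (l/l) for a tension triple (kPa)."""
        return np.array([
            self.beta_bl_n2 * tensions[_N2],
            float(np.interp(tensions[_O2], self.bl_o2_p, self.bl_o2_c)),
            self.beta_bl_co2 * tensions[_CO2],
        ])

    def blood_o2_tension(self, content):
        return np.interp(content, self.bl_o2_c, self.bl_o2_p)

    def tissue_tensions(self, amounts: np.ndarray) -> np.ndarray:
        """Tensions (4, 3) kPa from tissue gas amounts (4, 3) liters."""
        conc = amounts / self.v_tissue[:, None]
        pt = np.empty((4, 3))
        pt[:, _N2] = conc[:, _N2] / self.beta_t_n2
        pt[:, _CO2] = conc[:, _CO2] / self.beta_t_co2
        # dissolved-only compartments
        pt[:, _O2] = conc[:, _O2] / self.sol_t_o2
        # muscle: Mb-bound + dissolved, closed-form quadratic inverse
        c = conc[_MUSCLE, _O2]
        sol = self.sol_t_o2[_MUSCLE]
        b = self.mb_cap + sol * self.mb_p50 - c
        pt[_MUSCLE, _O2] = (-b + np.sqrt(b * b + 4.0 * sol * c * self.mb_p50)) / (2.0 * sol)
        return np.clip(pt, 0.0, None)

    def tissue_o2_content(self, po2: np.ndarray) -> np.ndarray:
        """Tissue O2 contents (l/l) from tensions (4,) kPa."""
        c = self.sol_t_o2 * po2
        c[_MUSCLE] += self.mb_cap * po2[_MUSCLE] / (po2[_MUSCLE] + self.mb_p50)
        return c

    def schedule(self, depth: float) -> tuple[float, np.ndarray]:
        """Cardiac output (l/s) and perfusion fractions at a depth."""
        if self.ramp_m > 0.0:
            w = min(max((depth - self.dive_engage_depth) / self.ramp_m, 0.0), 1.0)
        else:
            w = 1.0 if depth > self.dive_engage_depth else 0.0
        q = (1.0 - w) * self.q_surface + w * self.q_dive
        frac = (1.0 - w) * self.frac_surface + w * self.frac_dive
        return q, frac

    # -- state vector layout ----------------------------------------------
    # y[0:3] lung gas, l STPD | y[3:6] arterial content l/l | y[6:9] venous
    # y[9:21] tissue amounts, l, (4 tissues x 3 gases) | y[21] cum uptake
    # y[22] cum consumed

    def initial_state(self) -> np.ndarray:
        """Surface steady state under the surface perfusion schedule."""
        y = np.zeros(23)
        y[0:3] = self.lung_surface
        ca = self.ca_surface
        y[3:6] = ca
        q, frac = self.q_surface, self.frac_surface
        pt = np.empty((4, 3))
        pt[:, _N2] = self.pa_surface[_N2]
        # O2: perfusion-limited steady state -> venous-side content deficit
        cb_out = np.maximum(ca[_O2] - self.vo2 / (frac * q), 1e-9)
        pt[:, _O2] = self.blood_o2_tension(cb_out)
        pt[:, _CO2] = (ca[_CO2] + self.rq * self.vo2 / (frac * q)) / self.beta_bl_co2
        amounts = np.empty((4, 3))
        amounts[:, _N2] = self.v_tissue * self.beta_t_n2 * pt[:, _N2]
        amounts[:, _CO2] = self.v_tissue * self.beta_t_co2 * pt[:, _CO2]
        amounts[:, _O2] = self.v_tissue * self.tissue_o2_content(pt[:, _O2])
        y[9:21] = amounts.ravel()
        cv = np.zeros(3)
        cv[_N2] = self.beta_bl_n2 * np.dot(frac, pt[:, _N2])
        cv[_O2] = np.dot(frac, np.interp(pt[:, _O2], self.bl_o2_p, self.bl_o2_c))
        cv[_CO2] = self.beta_bl_co2 * np.dot(frac, pt[:, _CO2])
        y[6:9] = cv
        return y

    def apply_surface_reset(self, y: np.ndarray) -> None:
        # re-arterialization of the pinned arterial pool is O2 taken up from
        # the (freshly ventilated) lung: count it so the O2 audit closes
        y[21] += (self.ca_surface[_O2] - y[4]) * self.v_art
        y[0:3] = self.lung_surface
        y[3:6] = self.ca_surface

    def respiratory_at(self, pressure: float, n_dry: float) -> tuple[float, float, float, bool]:
        """(v_alv, v_dead, shunt, collapsed) for a dry lung gas amount (l STPD)."""
        v_target = n_dry / (pressure - WATER_VAPOR_ATA)
        v_alv, v_dead = self.resp.volumes_for(v_target)
        collapsed = v_alv < self.resp.collapse_threshold * self.resp.v_alv_start
        if self.solver.shunt_override is not None:
            s = self.solver.shunt_override
            collapsed = s >= 1.0
        elif collapsed:
            s = 1.0
        else:
            s = shunt_fraction(v_alv, self.resp.v_alv_start, self.solver.shunt_gamma)
        return v_alv, v_dead, s, collapsed

    def rhs(self, depth: float, y: np.ndarray) -> np.ndarray:
        """Time derivative of the state vector at a given depth."""
        dy = np.zeros_like(y)
        pressure = 1.0 + depth / 10.0
        at_surface = depth <= self.solver.surface_threshold
        q, frac = self.schedule(depth)
        ca = y[3:6]
        cv = y[6:9]
        amounts = y[9:21].reshape(4, 3)

        pt = self.tissue_tensions(amounts)
        # blood contents in equilibrium with each tissue (outflowing blood)
        cb_t = np.empty((4, 3))
        cb_t[:, _N2] = self.beta_bl_n2 * pt[:, _N2]
        cb_t[:, _O2] = np.interp(pt[:, _O2], self.bl_o2_p, self.bl_o2_c)
        cb_t[:, _CO2] = self.beta_bl_co2 * pt[:, _CO2]

        # tissue exchange + metabolism
        flow = frac * q
        d_amounts = flow[:, None] * (ca[None, :] - cb_t)
        o2_in = flow * ca[_O2]
        consumption = np.where(
            amounts[:, _O2] > 1e-12, self.vo2, np.minimum(self.vo2, np.maximum(o2_in, 0.0))
        )
        d_amounts[:, _O2] -= consumption
        d_amounts[:, _CO2] += self.rq * consumption
        dy[9:21] = d_amounts.ravel()

        # venous mixing
        dy[6:9] = q * (frac @ cb_t - cv) / self.v_ven

        if at_surface:
            # lung and arterial pinned to surface composition; uptake is the
            # flux carried away by fully arterialized blood
            dy[21] = q * (self.ca_surface[_O2] - cv[_O2])
        else:
            n_dry = y[0] + y[1] + y[2]
            _, _, s, _ = self.respiratory_at(pressure, n_dry)
            pa = (y[0:3] / n_dry) * (pressure - WATER_VAPOR_ATA) * ATA_KPA
            c_pulm = self._blood_content(pa)
            j = q * (1.0 - s) * (c_pulm - cv)
            dy[0:3] = -j
            c_in = (1.0 - s) * c_pulm + s * cv
            dy[3:6] = q * (c_in - ca) / self.v_art
            dy[21] = j[_O2]
        dy[22] = consumption.sum()
        return dy


def simulate(
    profile: DepthSeries,
    params: PhysioParams,
    solver: SolverConfig | None = None,
    constants: CarriageConstants = DEFAULT_CONSTANTS,
) -> TensionTrajectory:
    """Integrate the gas-exchange dynamics over a depth profile.

    The profile must start and end at the surface. Returns the recorded
    trajectory at ``solver.output_dt`` resolution (default: every step).
    """
    solver = solver or SolverConfig()
    ctx = _EngineContext(params, solver, constants)
    if profile.depth[0] > solver.surface_threshold or profile.depth[-1] > solver.surface_threshold:
        raise ValueError("profile must start and end at the surface")

    dt = solver.dt
    n_steps = int(round(profile.span / dt))
    if n_steps < 1:
        raise ValueError("profile shorter than one solver step")
    out_every = max(1, int(round((solver.output_dt or dt) / dt)))

    # depth at half-step resolution for RK4 stages
    t_half = profile.time[0] + np.arange(2 * n_steps + 1) * (dt / 2.0)
    d_half = np.interp(t_half, profile.time, profile.depth)

    y = ctx.initial_state()
    rec_idx: list[int] = []
    rec_y: list[np.ndarray] = []

    def record(k: int) -> None:
        rec_idx.append(k)
        rec_y.append(y.copy())

    record(0)
    rhs = ctx.rhs
    for k in range(n_steps):
        d0 = d_half[2 * k]
        dm = d_half[2 * k + 1]
        d1 = d_half[2 * k + 2]
        k1 = rhs(d0, y)
        k2 = rhs(dm, y + 0.5 * dt * k1)
        k3 = rhs(dm, y + 0.5 * dt * k2)
        k4 = rhs(d1, y + dt * k3)
        y = y + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if not np.all(np.isfinite(y)):
            t_bad = profile.time[0] + (k + 1) * dt
            raise RuntimeError(f"solver instability: non-finite state at t={t_bad:.1f}s, depth={d1:.1f}m")
        # physical floors: gas amounts cannot go negative
        np.clip(y[0:3], 0.0, None, out=y[0:3])
        amounts = y[9:21].reshape(4, 3)
        np.clip(amounts[:, _O2], 0.0, None, out=amounts[:, _O2])
        if d1 <= solver.surface_threshold:
            ctx.apply_surface_reset(y)
        if (k + 1) % out_every == 0 or k == n_steps - 1:
            record(k + 1)

    return _assemble(profile, ctx, np.array(rec_idx), np.array(rec_y), dt)


def _assemble(
    profile: DepthSeries, ctx: _EngineContext, rec_idx: np.ndarray, ys: np.ndarray, dt: float
) -> TensionTrajectory:
    times = profile.time[0] + rec_idx * dt
    depths = np.interp(times, profile.time, profile.depth)
    pressures = 1.0 + depths / 10.0
    n = len(times)

    v_alv = np.empty(n)
    v_dead = np.empty(n)
    shunt = np.empty(n)
    collapsed = np.zeros(n, dtype=bool)
    alveolar = np.empty((n, 3))
    arterial = np.empty((n, 3))
    venous = np.empty((n, 3))
    tissues = np.empty((n, 4, 3))
    q_tot = np.empty(n)
    perf = np.empty((n, 4))

    for i in range(n):
        y = ys[i]
        n_dry = y[0] + y[1] + y[2]
        va, vd, s, col = ctx.respiratory_at(pressures[i], n_dry)
        v_alv[i], v_dead[i], shunt[i], collapsed[i] = va, vd, s, col
        alveolar[i] = (y[0:3] / n_dry) * (pressures[i] - WATER_VAPOR_ATA) * ATA_KPA
        arterial[i] = [
            y[3] / ctx.beta_bl_n2,
            ctx.blood_o2_tension(y[4]),
            y[5] / ctx.beta_bl_co2,
        ]
        venous[i] = [
            y[6] / ctx.beta_bl_n2,
            ctx.blood_o2_tension(y[7]),
            y[8] / ctx.beta_bl_co2,
        ]
        tissues[i] = ctx.tissue_tensions(y[9:21].reshape(4, 3))
        q_tot[i], perf[i] = ctx.schedule(depths[i])

    return TensionTrajectory(
        time=times,
        depth=depths,
        pressure=pressures,
        v_alv=v_alv,
        v_dead=v_dead,
        shunt=shunt,
        collapsed=collapsed,
        alveolar=alveolar,
        arterial=arterial,
        venous=venous,
        tissues=tissues,
        q_tot=q_tot,
        perfusion=perf,
        cum_o2_uptake=ys[:, 21],
        cum_o2_consumed=ys[:, 22],
        raw_states=ys,
        params=ctx.params,
        solver=ctx.solver,
    )


def end_dive_summary(traj: TensionTrajectory, dives: DiveRecord) -> pd.DataFrame:
    """One row per segmented dive: duration, depth, and end-dive tensions.

    A dive is flagged ``anaerobic`` when any tissue O2 tension fell to
    (effectively) zero at any recorded instant within the dive.
    """
    if dives.n_dives and (
        dives.dives[0].start_time < traj.time[0] - 1e-6 or dives.dives[-1].end_time > traj.time[-1] + 1e-6
    ):
        raise ValueError("dive record extends outside the simulated trajectory")
    rows = []
    for dv in dives.dives:
        i_end = int(np.searchsorted(traj.time, dv.end_time, side="right") - 1)
        i_start = int(np.searchsorted(traj.time, dv.start_time, side="left"))
        window_o2 = traj.tissues[i_start : i_end + 1, :, _O2]
        row: dict[str, float | bool] = {
            "duration_s": dv.duration_s,
            "max_depth_m": dv.max_depth_m,
            "anaerobic": bool(np.any(window_o2 < EXHAUSTION_PO2_KPA)),
        }
        for k, g in enumerate(GAS_NAMES):
            row[f"end_venous_{g}_kpa"] = float(traj.venous[i_end, k])
            for c, name in enumerate(COMPARTMENTS):
                row[f"end_{name}_{g}_kpa"] = float(traj.tissues[i_end, c, k])
        rows.append(row)
    return pd.DataFrame(rows)


def gas_totals(traj: TensionTrajectory) -> np.ndarray:
    """Whole-body gas amounts (n, 3) in liters STPD at each recorded time.

    Lung store + arterial and venous blood + all tissue compartments; used
    for conservation audits (total is invariant while submerged when
    metabolism is disabled).
    """
    ctx = _EngineContext(traj.params, traj.solver, DEFAULT_CONSTANTS)
    ys = traj.raw_states
    lung = ys[:, 0:3]
    blood = ys[:, 3:6] * ctx.v_art + ys[:, 6:9] * ctx.v_ven
    tissue = ys[:, 9:21].reshape(-1, 4, 3).sum(axis=1)
    return lung + blood + tissue


def o2_balance_audit(traj: TensionTrajectory, i0: int = 0, i1: int | None = None) -> dict[str, float]:
    """Audit O2 mass balance between two recorded samples.

    Net O2 taken up from the lung must equal metabolized O2 plus the change
    in blood + tissue O2 stores. Returns the components and the residual as
    a fraction of consumption.
    """
    i1 = len(traj.time) - 1 if i1 is None else i1
    ctx = _EngineContext(traj.params, traj.solver, DEFAULT_CONSTANTS)
    ys = traj.raw_states
    store = ys[:, 4] * ctx.v_art + ys[:, 7] * ctx.v_ven + ys[:, 9:21].reshape(-1, 4, 3)[:, :, _O2].sum(axis=1)
    uptake = float(traj.cum_o2_uptake[i1] - traj.cum_o2_uptake[i0])
    consumed = float(traj.cum_o2_consumed[i1] - traj.cum_o2_consumed[i0])
    delta_store = float(store[i1] - store[i0])
    residual = uptake - consumed - delta_store
    return {
        "uptake_l": uptake,
        "consumed_l": consumed,
        "delta_store_l": delta_store,
        "residual_l": residual,
        "relative_residual": residual / consumed if consumed else 0.0,
    }
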