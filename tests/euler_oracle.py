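"""Independent fine-step explicit-Euler integration of the gas-exchange model.

This is a from-scratch scalar reimplementation of the lung-blood-tissue
model used to cross-check the package's RK4 engine. It shares only the
*inputs* with the engine (the packaged parameter YAML files and the model
description); all numerics are independent: explicit Euler stepping,
closed-form carriage curves (no interpolation tables), and exact
root-finding (scipy brentq) for both the respiratory volume partition and
the blood O2 inversion.
"""

from __future__ import annotations

import math

import numpy as np
import yaml
from importlib import resources
from scipy.optimize import brentq

ATA_KPA = 98.07
PH2O = 0.062
COMPS = ("brain", "fat", "central_circulation", "muscle")
MEDIA = ("lean", "fat", "lean", "lean")


def _data(name: str) -> dict:
    return yaml.safe_load(resources.files("divegas.data").joinpath(f"{name}.yaml").read_text())


class EulerOracle:
    """Explicit-Euler reference trajectory for one ecotype at 200 kg."""

    def __init__(self, ecotype: str, compliance_variant: str = "updated_dolphin",
                 gamma: float = 0.1, metabolic_multiplier: float = 2.0, rq: float = 0.9):
        p = _data(ecotype)
        g = _data("gas_constants")
        comp = _data("compliance")[compliance_variant]
        mass = 200.0

        self.v_tis = [p["compartments"][c]["mass_fraction"] * mass for c in COMPS]
        vb = p["blood_fraction"] * mass
        self.v_art = vb / 3.0
        self.v_ven = vb - self.v_art
        self.vo2 = [p["compartments"][c]["vo2_rest_l_per_min"] * metabolic_multiplier / 60.0 for c in COMPS]
        self.rq = rq
        self.f_surf = [p["compartments"][c]["perfusion_surface"] for c in COMPS]
        self.f_dive = [p["compartments"][c]["perfusion_dive"] for c in COMPS]
        q_rest = p["q_rest_l_per_min"] / 60.0
        self.q_surf = q_rest * p["surface_q_multiplier"]
        self.q_dive = q_rest * p["dive_q_multiplier"]
        self.engage_depth = max(p["dive_response_depth_m"], 0.1)

        # carriage (l/l and l/(l kPa))
        self.hb_cap = p["hb_g_per_100g"] * 10.0 * g["hb_o2_capacity_ml_per_g"] / 1000.0
        self.p50 = g["hb_p50_kpa"]
        self.hill = g["hb_hill_n"]
        self.sol_o2_bl = g["ostwald_o2_ml_per_l_kpa"]["blood"] / 1000.0
        self.b_n2_bl = g["ostwald_n2_ml_per_l_kpa"]["blood"] / 1000.0
        self.b_co2_bl = g["co2_capacitance_ml_per_l_kpa"]["blood"] / 1000.0
        self.b_n2_t = [g["ostwald_n2_ml_per_l_kpa"][m] / 1000.0 for m in MEDIA]
        self.b_co2_t = [g["co2_capacitance_ml_per_l_kpa"][m] / 1000.0 for m in MEDIA]
        self.sol_o2_t = [g["ostwald_o2_ml_per_l_kpa"]["lean"] / 1000.0] * 4
        loco = p["muscle_locomotor_fraction"] * mass
        self.mb_cap = p["mb_g_per_100g_muscle"] * 10.0 * loco / self.v_tis[3] * g["mb_o2_capacity_ml_per_g"] / 1000.0
        self.mb_p50 = g["mb_p50_kpa"]

        # respiratory structure
        tlc = 0.135 * mass ** 0.92
        self.va0 = 0.93 * tlc
        self.vd0 = 0.07 * tlc
        self.ca_comp = comp
        self.gamma = gamma
        self.collapse_frac = 1e-3
        self.v0 = tlc
        alv = p["surface_alveolar_ata"]
        self.x_surf = [alv["n2"], alv["o2"], alv["co2"]]
        self.pa_surf = [x * ATA_KPA for x in self.x_surf]
        self._last_ps = 0.0

    # -- carriage ---------------------------------------------------------

    def cb_o2(self, po2: float) -> float:
        pn = po2 ** self.hill
        return self.hb_cap * pn / (pn + self.p50 ** self.hill) + self.sol_o2_bl * po2

    def po2_blood(self, content: float) -> float:
        if content <= 0:
            return 0.0
        return brentq(lambda p: self.cb_o2(p) - content, 0.0, 10000.0, xtol=1e-12)

    def ct_o2(self, c: int, po2: float) -> float:
        out = self.sol_o2_t[c] * po2
        if c == 3:
            out += self.mb_cap * po2 / (po2 + self.mb_p50)
        return out

    def pt_o2(self, c: int, content: float) -> float:
        if content <= 0:
            return 0.0
        if c != 3:
            return content / self.sol_o2_t[c]
        return brentq(lambda p: self.ct_o2(3, p) - content, 0.0, 10000.0, xtol=1e-12)

    # -- respiratory -------------------------------------------------------

    def _fa(self, ps: float) -> float:
        return (1.0 + self.ca_comp["a"] * ps / self.ca_comp["b"]) ** (-self.ca_comp["c"])

    def _fd(self, ps: float) -> float:
        return math.exp(-((ps / abs(self.ca_comp["kp"])) ** self.ca_comp["n"]))

    def respiratory(self, pressure: float, n_dry: float) -> tuple[float, float]:
        """(v_alv, shunt) by exact root finding with a warm-started bracket."""
        v_target = n_dry / (pressure - PH2O)
        def res(ps):
            return self.va0 * self._fa(ps) + self.vd0 * self._fd(ps) - v_target
        if res(0.0) <= 0.0:
            v_alv = self.va0
        else:
            lo, hi = 0.0, max(4.0 * self._last_ps + 1.0, 2.0)
            while res(hi) > 0.0:
                hi *= 2.0
                if hi > 1e7:
                    raise RuntimeError("bracket failure")
            ps = brentq(res, lo, hi, xtol=1e-12)
            self._last_ps = ps
            v_alv = self.va0 * self._fa(ps)
        r = v_alv / self.va0
        if r < self.collapse_frac:
            return v_alv, 1.0
        return v_alv, min(max(1.0 - r ** self.gamma, 0.0), 1.0)

    # -- integration --------------------------------------------------------

    def initial_state(self):
        lung = [self.v0 * x for x in self.x_surf]
        ca = [self.b_n2_bl * self.pa_surf[0], self.cb_o2(self.pa_surf[1]), self.b_co2_bl * self.pa_surf[2]]
        q, f = self.q_surf, self.f_surf
        pt = [[0.0] * 3 for _ in range(4)]
        A = [[0.0] * 3 for _ in range(4)]
        for c in range(4):
            pt[c][0] = self.pa_surf[0]
            pt[c][1] = self.po2_blood(max(ca[1] - self.vo2[c] / (f[c] * q), 1e-9))
            pt[c][2] = (ca[2] + self.rq * self.vo2[c] / (f[c] * q)) / self.b_co2_bl
            A[c][0] = self.v_tis[c] * self.b_n2_t[c] * pt[c][0]
            A[c][1] = self.v_tis[c] * self.ct_o2(c, pt[c][1])
            A[c][2] = self.v_tis[c] * self.b_co2_t[c] * pt[c][2]
        cv = [
            sum(f[c] * self.b_n2_bl * pt[c][0] for c in range(4)),
            sum(f[c] * self.cb_o2(pt[c][1]) for c in range(4)),
            sum(f[c] * self.b_co2_bl * pt[c][2] for c in range(4)),
        ]
        return lung, ca, cv, A

    def run(self, times: np.ndarray, depths: np.ndarray, dt: float, record_every: float):
        """Integrate over a (1-Hz) profile; return records at ``record_every`` s.

        Records are dicts of tensions (kPa) keyed like the engine trajectory.
        """
        lung, ca, cv, A = self.initial_state()
        t0, t1 = float(times[0]), float(times[-1])
        n_steps = int(round((t1 - t0) / dt))
        rec_stride = int(round(record_every / dt))
        records = []

        def snapshot():
            n_dry = sum(lung)
            pres = 1.0 + depth / 10.0
            pa = [lung[k] / n_dry * (pres - PH2O) * ATA_KPA for k in range(3)]
            rec = {
                "alv": pa,
                "art": [ca[0] / self.b_n2_bl, self.po2_blood(ca[1]), ca[2] / self.b_co2_bl],
                "ven": [cv[0] / self.b_n2_bl, self.po2_blood(cv[1]), cv[2] / self.b_co2_bl],
                "tis": [
                    [A[c][0] / self.v_tis[c] / self.b_n2_t[c],
                     self.pt_o2(c, A[c][1] / self.v_tis[c]),
                     A[c][2] / self.v_tis[c] / self.b_co2_t[c]]
                    for c in range(4)
                ],
            }
            records.append(rec)

        depth = float(np.interp(t0, times, depths))
        snapshot()
        for k in range(n_steps):
            t = t0 + k * dt
            depth = float(np.interp(t, times, depths))
            at_surface = depth <= 0.1
            if at_surface:
                lung = [self.v0 * x for x in self.x_surf]
                ca = [self.b_n2_bl * self.pa_surf[0], self.cb_o2(self.pa_surf[1]), self.b_co2_bl * self.pa_surf[2]]
            dive = depth > self.engage_depth
            q = self.q_dive if dive else self.q_surf
            f = self.f_dive if dive else self.f_surf

            pt = [[A[c][0] / self.v_tis[c] / self.b_n2_t[c],
                   self.pt_o2(c, A[c][1] / self.v_tis[c]),
                   A[c][2] / self.v_tis[c] / self.b_co2_t[c]] for c in range(4)]
            cb_t = [[self.b_n2_bl * pt[c][0], self.cb_o2(pt[c][1]), self.b_co2_bl * pt[c][2]] for c in range(4)]

            dA = [[0.0] * 3 for _ in range(4)]
            for c in range(4):
                flow = f[c] * q
                cons = self.vo2[c] if A[c][1] > 1e-12 else min(self.vo2[c], max(flow * ca[1], 0.0))
                for k3 in range(3):
                    dA[c][k3] = flow * (ca[k3] - cb_t[c][k3])
                dA[c][1] -= cons
                dA[c][2] += self.rq * cons
            dcv = [q * (sum(f[c] * cb_t[c][k3] for c in range(4)) - cv[k3]) / self.v_ven for k3 in range(3)]

            if at_surface:
                dlung = [0.0, 0.0, 0.0]
                dca = [0.0, 0.0, 0.0]
            else:
                pres = 1.0 + depth / 10.0
                n_dry = lung[0] + lung[1] + lung[2]
                _, s = self.respiratory(pres, n_dry)
                pa = [lung[k3] / n_dry * (pres - PH2O) * ATA_KPA for k3 in range(3)]
                c_pulm = [self.b_n2_bl * pa[0], self.cb_o2(pa[1]), self.b_co2_bl * pa[2]]
                j = [q * (1.0 - s) * (c_pulm[k3] - cv[k3]) for k3 in range(3)]
                dlung = [-j[k3] for k3 in range(3)]
                dca = [q * ((1.0 - s) * c_pulm[k3] + s * cv[k3] - ca[k3]) / self.v_art for k3 in range(3)]

            for k3 in range(3):
                lung[k3] = max(lung[k3] + dt * dlung[k3], 0.0)
                ca[k3] += dt * dca[k3]
                cv[k3] += dt * dcv[k3]
            for c in range(4):
                for k3 in range(3):
                    A[c][k3] += dt * dA[c][k3]
                A[c][1] = max(A[c][1], 0.0)

            depth = float(np.interp(t + dt, times, depths))
            if depth <= 0.1:
                lung = [self.v0 * x for x in self.x_surf]
                ca = [self.b_n2_bl * self.pa_surf[0], self.cb_o2(self.pa_surf[1]), self.b_co2_bl * self.pa_surf[2]]
            if (k + 1) % rec_stride == 0:
                snapshot()
        return records
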