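import numpy as np
import pytest

from divegas.kinetics import SolverConfig, end_dive_summary, gas_totals, o2_balance_audit, simulate
from divegas.records import DepthSeries, segment_dives
from divegas.synthetic import generate_worked_dive

CFG = SolverConfig(dt=0.1, output_dt=1.0)


def flat_profile(seconds):
    t = np.arange(seconds + 1.0)
    return DepthSeries(time=t, depth=np.zeros_like(t), sample_rate=1.0)


def repeated_dives(depth, duration, gap, n, pad=60.0):
    points = [(0.0, 0.0)]
    t = pad
    for _ in range(n):
        points += [(t, 0.0), (t + depth / 2, depth), (t + duration - depth / 2, depth), (t + duration, 0.0)]
        t += duration + gap
    points.append((t + pad, 0.0))
    bt = np.array([p[0] for p in points])
    bd = np.array([p[1] for p in points])
    tt = np.arange(0.0, bt[-1] + 1e-9, 1.0)
    return DepthSeries(time=tt, depth=np.interp(tt, bt, bd), sample_rate=1.0)


class TestSurfaceBehavior:
    def test_surface_steady_state(self, bermuda):
        """On a constant 0-m record every tension stays at its surface
        steady-state value."""
        traj = simulate(flat_profile(300), bermuda, CFG)
        assert np.abs(traj.arterial - traj.arterial[0]).max() < 1e-6
        assert np.abs(traj.venous - traj.venous[0]).max() < 1e-6
        assert np.abs(traj.tissues - traj.tissues[0]).max() < 1e-6

    def test_arterial_equals_alveolar_at_surface(self, sarasota):
        traj = simulate(flat_profile(60), sarasota, CFG)
        assert traj.shunt[0] == 0.0
        assert np.allclose(traj.arterial[0], traj.alveolar[0], atol=1e-6)

    def test_profile_must_start_at_surface(self, sarasota):
        t = np.arange(100.0)
        prof = DepthSeries(time=t, depth=np.full_like(t, 5.0), sample_rate=1.0)
        with pytest.raises(ValueError, match="surface"):
            simulate(prof, sarasota, CFG)


class TestConservation:
    def test_closed_system_gas_conserved(self, bermuda):
        """With metabolism off, total gas (lung + blood + tissues) is
        invariant while submerged, for every gas species."""
        prof = generate_worked_dive("square", 60.0, 300.0, surface_pad_s=30.0)
        cfg = SolverConfig(dt=0.1, output_dt=1.0, metabolism_enabled=False)
        traj = simulate(prof, bermuda, cfg)
        wet = traj.depth > cfg.surface_threshold
        totals = gas_totals(traj)[wet]
        rel_drift = np.abs(totals - totals[0]).max(axis=0) / totals[0]
        assert np.all(rel_drift < 5e-3)

    def test_o2_mass_balance_audit(self, bermuda):
        """Net O2 uptake equals consumption plus store change to <0.5% over
        a surface-to-surface cycle."""
        prof = generate_worked_dive("square", 150.0, 480.0, surface_pad_s=60.0)
        audit = o2_balance_audit(simulate(prof, bermuda, CFG))
        assert abs(audit["relative_residual"]) < 0.005


class TestDiveResponse:
    def test_bermuda_schedule_switches_only_below_20m(self, bermuda):
        prof = generate_worked_dive("trapezoid", 15.0, 120.0, surface_pad_s=30.0)
        traj = simulate(prof, bermuda, CFG)
        # never deeper than 20 m: cardiac output stays at the surface value
        assert np.all(traj.q_tot == pytest.approx(bermuda.q_rest * bermuda.surface_q_multiplier / 60.0))

        deep = generate_worked_dive("trapezoid", 60.0, 180.0, surface_pad_s=30.0)
        traj2 = simulate(deep, bermuda, CFG)
        below = traj2.depth > 20.0
        assert np.all(traj2.q_tot[below] == pytest.approx(bermuda.q_rest / 60.0))
        assert np.all(traj2.q_tot[~below] == pytest.approx(bermuda.q_rest * bermuda.surface_q_multiplier / 60.0))

    def test_sarasota_dive_schedule_on_any_submergence(self, sarasota):
        prof = generate_worked_dive("trapezoid", 4.0, 60.0, surface_pad_s=30.0)
        traj = simulate(prof, sarasota, CFG)
        wet = traj.depth > 0.1
        assert np.all(traj.q_tot[wet] == pytest.approx(sarasota.q_rest / 60.0))


class TestEndDiveSummary:
    def test_single_dive_single_row(self, sarasota):
        prof = generate_worked_dive("trapezoid", 4.0, 60.0, surface_pad_s=30.0)
        traj = simulate(prof, sarasota, CFG)
        dives = segment_dives(prof)
        table = end_dive_summary(traj, dives)
        assert len(table) == 1
        assert table.loc[0, "duration_s"] == pytest.approx(dives.dives[0].duration_s)
        assert table.loc[0, "end_muscle_o2_kpa"] > 0

    def test_steady_cycling_gives_identical_summaries(self, sarasota):
        """Two identical shallow dives separated by a long recovery produce
        matching end-dive tensions."""
        prof = repeated_dives(depth=4.0, duration=60.0, gap=600.0, n=2)
        traj = simulate(prof, sarasota, CFG)
        table = end_dive_summary(traj, segment_dives(prof))
        assert len(table) == 2
        tension_cols = [c for c in table.columns if c.endswith("_kpa")]
        diffs = (table.loc[0, tension_cols] - table.loc[1, tension_cols]).abs()
        assert diffs.max() < 0.2

    def test_mismatched_record_rejected(self, sarasota):
        prof = generate_worked_dive("trapezoid", 4.0, 60.0, surface_pad_s=30.0)
        longer = generate_worked_dive("trapezoid", 4.0, 60.0, surface_pad_s=400.0)
        traj = simulate(prof, sarasota, CFG)
        with pytest.raises(ValueError, match="outside"):
            end_dive_summary(traj, segment_dives(longer))


class TestNumerics:
    def test_dt_convergence(self, bermuda):
        """Halving the step changes muscle PO2 by far less than the model
        tolerance (engine is converged at its default step)."""
        prof = generate_worked_dive("trapezoid", 100.0, 240.0, surface_pad_s=30.0)
        a = simulate(prof, bermuda, SolverConfig(dt=0.1, output_dt=1.0))
        b = simulate(prof, bermuda, SolverConfig(dt=0.05, output_dt=1.0))
        assert np.abs(a.tissues[:, 3, 1] - b.tissues[:, 3, 1]).max() < 0.05

    def test_trajectory_dataframe_schema(self, sarasota):
        traj = simulate(flat_profile(30), sarasota, CFG)
        df = traj.to_dataframe()
        assert len(df) == len(traj.time)
        assert {"time_s", "depth_m", "shunt", "pt_muscle_o2_kpa", "pv_ven_n2_kpa"} <= set(df.columns)

    def test_gas_state_view(self, sarasota):
        traj = simulate(flat_profile(30), sarasota, CFG)
        gs = traj.state(0)
        assert gs.depth == 0.0
        assert gs.perfusion["muscle"] == pytest.approx(0.65)
        assert gs.arterial["pa_o2"] == pytest.approx(traj.arterial[0, 1])
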