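import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from divegas.records import DepthSeries, read_depth_series, segment_dives, summarize
from divegas.synthetic import default_generator_config, generate_profile, profile_from_plan


def series(depths, dt=1.0):
    d = np.asarray(depths, dtype=float)
    return DepthSeries(time=np.arange(len(d)) * dt, depth=d, sample_rate=1.0 / dt)


def trapezoid(depth, total, ramp):
    """Symmetric trapezoid depth samples at 1 Hz, with surface padding."""
    t = np.arange(total + 21.0)
    bt = [0, 10, 10 + ramp, 10 + total - ramp, 10 + total, total + 20]
    bd = [0, 0, depth, depth, 0, 0]
    return DepthSeries(time=t, depth=np.interp(t, bt, bd), sample_rate=1.0)


class TestReadDepthSeries:
    def test_roundtrip_1hz(self, tmp_path):
        path = tmp_path / "p.csv"
        pd.DataFrame({"time_s": np.arange(30.0), "depth_m": np.linspace(0, 3, 30)}).to_csv(path, index=False)
        s = read_depth_series(path)
        assert len(s.time) == 30
        assert s.depth[-1] == pytest.approx(3.0)

    def test_negative_surface_reading_clipped(self, tmp_path, caplog):
        path = tmp_path / "p.csv"
        d = np.zeros(20)
        d[3] = -0.02
        pd.DataFrame({"time_s": np.arange(20.0), "depth_m": d}).to_csv(path, index=False)
        with caplog.at_level("WARNING"):
            s = read_depth_series(path)
        assert np.all(s.depth >= 0)
        assert any("clipping" in m for m in caplog.messages)

    def test_decimation_by_block_mean(self, tmp_path):
        rng = np.random.default_rng(1)
        t = np.arange(0, 20, 1 / 25)  # 25 Hz
        d = np.abs(np.sin(t)) * 5 + rng.normal(0, 0.01, t.size)
        d = np.clip(d, 0, None)
        path = tmp_path / "fast.csv"
        pd.DataFrame({"time_s": t, "depth_m": d}).to_csv(path, index=False)
        s = read_depth_series(path, target_hz=1.0)
        manual = d[: (len(d) // 25) * 25].reshape(-1, 25).mean(axis=1)
        assert np.allclose(s.depth, np.clip(manual, 0, None))

    def test_nonmonotone_time_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"time_s": [0.0, 2.0, 1.0], "depth_m": [0, 1, 0]}).to_csv(path, index=False)
        with pytest.raises(ValueError, match="increasing"):
            read_depth_series(path)


class TestSegmentation:
    def test_flat_surface_record_has_no_dives(self):
        rec = segment_dives(series(np.zeros(120)))
        assert rec.n_dives == 0
        assert rec.record_span_s == 119.0

    def test_trapezoid_crossing_times(self):
        """Start/end are the interpolated 0.1-m crossings of a 3-m, 30-s dive."""
        prof = trapezoid(3.0, 30.0, ramp=3.0)
        rec = segment_dives(prof)
        assert rec.n_dives == 1
        dv = rec.dives[0]
        # descent covers 3 m in 3 s -> crosses 0.1 m at 10 + 0.1 s
        assert dv.start_time == pytest.approx(10.1, abs=1e-9)
        assert dv.end_time == pytest.approx(40.0 - 0.1, abs=1e-9)
        assert dv.duration_s == pytest.approx(29.8, abs=1e-9)
        assert dv.max_depth_m == pytest.approx(3.0)

    def test_too_short_submergence_excluded(self):
        prof = trapezoid(2.0, 8.0, ramp=2.0)
        assert segment_dives(prof).n_dives == 0

    def test_too_shallow_submergence_excluded(self):
        prof = trapezoid(1.5, 40.0, ramp=2.0)  # strict: max depth must exceed 1.5 m
        assert segment_dives(prof).n_dives == 0
        prof2 = trapezoid(1.6, 40.0, ramp=2.0)
        assert segment_dives(prof2).n_dives == 1

    def test_idempotent_under_surface_padding(self):
        prof = trapezoid(5.0, 60.0, ramp=5.0)
        padded = DepthSeries(
            time=np.arange(len(prof.depth) + 300.0),
            depth=np.concatenate([np.zeros(150), prof.depth, np.zeros(150)]),
            sample_rate=1.0,
        )
        a, b = segment_dives(prof), segment_dives(padded)
        assert a.n_dives == b.n_dives == 1
        assert b.dives[0].duration_s == pytest.approx(a.dives[0].duration_s)
        assert b.dives[0].max_depth_m == pytest.approx(a.dives[0].max_depth_m)

    def test_span_partition_identity(self):
        """Leading pad + dives + surface intervals + trailing pad = span."""
        cfg = default_generator_config("sarasota", seed=7, record_span_hours=0.5)
        prof = generate_profile(cfg)
        rec = segment_dives(prof)
        assert rec.n_dives > 3
        total = (
            (rec.dives[0].start_time - prof.time[0])
            + sum(d.duration_s for d in rec.dives)
            + sum(rec.surface_intervals)
            + (prof.time[-1] - rec.dives[-1].end_time)
        )
        assert total == pytest.approx(rec.record_span_s, abs=1e-6)

    @given(st.integers(0, 1000))
    def test_all_reported_dives_satisfy_definition(self, seed):
        cfg = default_generator_config("bermuda", seed=seed, record_span_hours=0.2)
        rec = segment_dives(generate_profile(cfg))
        for dv in rec.dives:
            assert dv.max_depth_m > 1.5
            assert dv.duration_s > 10.0

    def test_noise_blip_merged(self):
        """A sub-0.1-m excursion shorter than one sample does not split a dive."""
        d = np.concatenate([np.zeros(5), np.full(20, 3.0), np.zeros(5)])
        t = np.arange(len(d), dtype=float)
        # insert a single 0.05-m sample mid-dive on a finer time base
        t2 = np.sort(np.concatenate([t, [14.5]]))
        d2 = np.interp(t2, t, d)
        d2[t2 == 14.5] = 0.05
        rec = segment_dives(DepthSeries(time=t2, depth=d2, sample_rate=1.0))
        assert rec.n_dives == 1


class TestSummarize:
    def test_single_dive_sd_flagged(self):
        rec = segment_dives(trapezoid(4.0, 40.0, ramp=4.0))
        table = summarize(rec)
        assert table.loc[0, "n_dives"] == 1
        assert bool(table.loc[0, "sd_undefined"])
        assert table.loc[0, "duration_s_sd"] == 0.0
        assert table.loc[0, "duration_s_mean"] == pytest.approx(rec.dives[0].duration_s)

    def test_depth_threshold_counts(self):
        plan = pd.DataFrame({
            "start_s": [10.0, 300.0, 700.0],
            "duration_s": [120.0, 200.0, 300.0],
            "max_depth_m": [50.0, 150.0, 250.0],
        })
        cfg = default_generator_config("bermuda", seed=0, record_span_hours=0.4)
        rec = segment_dives(profile_from_plan(plan, cfg))
        table = summarize(rec)
        assert table.loc[0, "n_dives_gt_100m"] == 2
        assert table.loc[0, "n_dives_gt_200m"] == 1

    def test_empty_record_flagged(self):
        table = summarize(segment_dives(series(np.zeros(60))))
        assert bool(table.loc[0, "empty"])
        assert table.loc[0, "dives_per_hour"] == 0.0
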