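"""Trajectory I/O, drift filtering, windowed RMS, screening, persistence inversion."""

import numpy as np
import pytest

from tethermech import (
    DriftSpec,
    NonStationaryError,
    RmsSeries,
    TetherModel,
    TpmSimConfig,
    CollapseSpec,
    Trajectory,
    circularity_screen,
    detect_stuck_events,
    drift_filter,
    mask_stuck_events,
    persistence_from_trajectory,
    read_trajectory,
    simulate_tpm,
    windowed_rms,
    write_trajectory,
)

from .conftest import BEAD_R_NM, LC_NM


def make_traj(x, y, rate=25.0):
    n = len(x)
    return Trajectory(t=np.arange(n) / rate, x=x, y=y)


class TestTrajectoryIO:
    def test_minimal_csv(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("time_s,x_nm,y_nm\n0.0,1,2\n0.04,3,4\n0.08,5,6\n")
        traj = read_trajectory(p)
        assert len(traj) == 3
        assert traj.sample_rate == pytest.approx(25.0)

    def test_timestamp_gap_rejected(self, tmp_path):
        p = tmp_path / "gap.csv"
        p.write_text("time_s,x_nm,y_nm\n0.0,1,2\n0.04,3,4\n0.20,5,6\n")
        with pytest.raises(ValueError, match="non-uniform"):
            read_trajectory(p)

    def test_non_numeric_rows_reported_with_line_numbers(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("time_s,x_nm,y_nm\n0.0,1,2\n0.04,oops,4\n0.08,5,6\n")
        with pytest.raises(ValueError, match=r"lines \[3\]"):
            read_trajectory(p)

    def test_missing_column(self, tmp_path):
        p = tmp_path / "cols.csv"
        p.write_text("time_s,x_nm\n0.0,1\n0.04,2\n")
        with pytest.raises(ValueError, match="y_nm"):
            read_trajectory(p)

    def test_simulator_output_round_trips(self, tmp_path, bare_dna_tether):
        traj = simulate_tpm(
            TpmSimConfig(model=bare_dna_tether, duration=10.0, seed=7)
        )
        write_trajectory(traj, tmp_path / "sim.csv")
        back = read_trajectory(tmp_path / "sim.csv")
        np.testing.assert_allclose(back.x, traj.x, rtol=1e-12)
        np.testing.assert_allclose(back.y, traj.y, rtol=1e-12)


class TestDriftFilter:
    def test_constant_offset_removed(self):
        traj = make_traj(np.full(1000, 100.0), np.zeros(1000))
        out = drift_filter(traj, 20.0)
        np.testing.assert_allclose(out.x, 0.0, atol=1e-9)

    def test_linear_drift_suppressed(self):
        # 1 nm/s ramp over 60 s accumulates 60 nm; interior residual of
        # moving-average subtraction of a ramp is exactly zero
        t = np.arange(1500) / 25.0
        traj = make_traj(1.0 * t, np.zeros_like(t))
        out = drift_filter(traj, 20.0)
        span = int(20.0 * 25) // 2
        interior = out.x[span:-span]
        assert np.max(np.abs(interior)) < 0.01 * 60.0

    def test_fast_tether_motion_preserved(self, bare_dna_tether):
        traj = simulate_tpm(
            TpmSimConfig(model=bare_dna_tether, duration=120.0, seed=3)
        )
        raw = windowed_rms(traj).rms.mean()
        filt = windowed_rms(drift_filter(traj, 20.0)).rms.mean()
        assert abs(filt - raw) / raw < 0.03

    def test_bad_window(self):
        traj = make_traj(np.zeros(100), np.zeros(100))
        with pytest.raises(ValueError):
            drift_filter(traj, 0.0)


class TestWindowedRms:
    def test_constant_position_zero_rms(self):
        traj = make_traj(np.full(500, 7.0), np.full(500, -3.0))
        assert np.allclose(windowed_rms(traj).rms, 0.0)

    def test_circular_motion_rms_is_radius(self):
        # x = a cos(wt), y = a sin(wt): in-plane variance about the center is a^2
        a, period = 120.0, 1.0
        t = np.arange(5000) / 25.0
        traj = make_traj(a * np.cos(2 * np.pi * t / period),
                         a * np.sin(2 * np.pi * t / period))
        series = windowed_rms(traj, window=20.0)
        np.testing.assert_allclose(series.rms, a, rtol=1e-3)

    def test_iid_gaussian_rms_is_sigma_root_two(self):
        rng = np.random.default_rng(11)
        sigma = 50.0
        traj = make_traj(rng.normal(0, sigma, 100_000),
                         rng.normal(0, sigma, 100_000))
        series = windowed_rms(traj, window=400.0)
        assert series.rms.mean() == pytest.approx(sigma * np.sqrt(2), rel=0.02)

    def test_output_length_and_times(self):
        traj = make_traj(np.zeros(200), np.zeros(200))
        series = windowed_rms(traj, window=4.0)
        assert len(series.rms) == 200 - 100 + 1
        assert series.t[0] == pytest.approx(np.mean(traj.t[:100]))

    def test_translation_invariance(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=500), rng.normal(size=500)
        a = windowed_rms(make_traj(x, y)).rms
        b = windowed_rms(make_traj(x + 123.0, y - 456.0)).rms
        np.testing.assert_allclose(a, b, atol=1e-8)

    def test_too_short_trajectory(self):
        traj = make_traj(np.zeros(50), np.zeros(50))
        with pytest.raises(ValueError, match="shorter"):
            windowed_rms(traj, window=4.0)


class TestCircularityScreen:
    def test_isotropic_passes(self):
        rng = np.random.default_rng(2)
        traj = make_traj(rng.normal(0, 100, 20000), rng.normal(0, 100, 20000))
        rep = circularity_screen(traj)
        assert rep.passed and rep.circularity > 0.9

    def test_twenty_percent_anisotropy_fails(self):
        # sigma_x = 1.2 sigma_y: circularity -> 1/1.2, deviation ~16.7% > 10%
        rng = np.random.default_rng(3)
        traj = make_traj(rng.normal(0, 120, 20000), rng.normal(0, 100, 20000))
        rep = circularity_screen(traj)
        assert not rep.passed
        assert rep.circularity == pytest.approx(1 / 1.2, abs=0.03)

    def test_one_dimensional_motion_fails(self):
        rng = np.random.default_rng(4)
        traj = make_traj(rng.normal(0, 100, 1000), np.zeros(1000))
        rep = circularity_screen(traj)
        assert not rep.passed and rep.circularity == pytest.approx(0.0, abs=1e-6)

    def test_zero_variance_fails_with_diagnostic(self):
        traj = make_traj(np.full(100, 5.0), np.full(100, 5.0))
        rep = circularity_screen(traj)
        assert not rep.passed and "degenerate" in rep.note

    def test_rotation_invariance(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(0, 120, 5000), rng.normal(0, 80, 5000)
        base = circularity_screen(make_traj(x, y)).circularity
        for theta in (0.3, 1.1, 2.5):
            xr = x * np.cos(theta) - y * np.sin(theta)
            yr = x * np.sin(theta) + y * np.cos(theta)
            rot = circularity_screen(make_traj(xr, yr)).circularity
            assert rot == pytest.approx(base, rel=1e-9)

    def test_screening_specificity_on_ensembles(self, bare_dna_tether):
        """Single isotropic tethers pass, 20%-anisotropic beads fail, >=95/100."""
        from .conftest import spawn_seeds

        iso_pass = aniso_fail = 0
        seeds = spawn_seeds(101, 200)
        for s in seeds[:100]:
            traj = simulate_tpm(
                TpmSimConfig(model=bare_dna_tether, duration=120.0, seed=s)
            )
            iso_pass += circularity_screen(traj).passed
        for s in seeds[100:]:
            traj = simulate_tpm(
                TpmSimConfig(model=bare_dna_tether, duration=120.0,
                             anisotropy=(1.2, 1.0), seed=s)
            )
            aniso_fail += not circularity_screen(traj).passed
        assert iso_pass >= 95
        assert aniso_fail >= 95


class TestStuckEvents:
    def test_constant_rms_no_events(self):
        s = RmsSeries(np.arange(300.0), np.full(300, 500.0))
        assert detect_stuck_events(s) == []

    def test_step_drop_detected_and_maskable(self):
        t = np.arange(300.0)
        rms = np.where(t < 60.0, 500.0, 100.0)
        events = detect_stuck_events(RmsSeries(t, rms))
        assert len(events) == 1
        assert events[0].time == pytest.approx(60.0, abs=2.0)
        assert events[0].magnitude == pytest.approx(400.0, abs=10.0)
        cleaned = mask_stuck_events(RmsSeries(t, rms), events)
        assert np.isnan(cleaned.rms[80:]).all()
        assert np.isfinite(cleaned.rms[:55]).all()

    def test_smooth_collapse_not_flagged(self):
        # minutes-long exponential decay is continuous, not a sticking event
        t = np.arange(0.0, 1800.0, 1.0)
        rms = 200.0 + 300.0 * np.exp(-t / (7.5 * 60.0))
        assert detect_stuck_events(RmsSeries(t, rms)) == []


class TestPersistenceFromTrajectory:
    @pytest.mark.parametrize("xi_true", [54.0, 150.0])
    def test_recovery_from_stationary_record(self, xi_true):
        model = TetherModel(LC_NM, xi_true, bead_radius=BEAD_R_NM)
        traj = simulate_tpm(TpmSimConfig(model=model, duration=600.0, seed=42))
        est = persistence_from_trajectory(traj, LC_NM, BEAD_R_NM)
        assert est.persistence_length == pytest.approx(xi_true, rel=0.10)
        assert est.stderr > 0

    def test_single_window_record_at_measured_rms(self):
        """A degenerate one-window record whose RMS is 508 nm inverts to 54 +/- 5."""
        rng = np.random.default_rng(9)
        n = 100  # exactly one 4 s window at 25 Hz
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        x -= x.mean()
        y -= y.mean()
        scale = 508.0 / np.sqrt(np.mean(x**2 + y**2))
        traj = make_traj(x * scale, y * scale)
        est = persistence_from_trajectory(traj, LC_NM, BEAD_R_NM)
        assert abs(est.persistence_length - 54.0) <= 5.0

    def test_collapsing_record_rejected_as_nonstationary(self, bare_dna_tether):
        traj = simulate_tpm(
            TpmSimConfig(
                model=bare_dna_tether, duration=900.0,
                collapse=CollapseSpec(tau_min=5.0, plateau_fraction=0.3), seed=8,
            )
        )
        with pytest.raises(NonStationaryError):
            persistence_from_trajectory(traj, LC_NM, BEAD_R_NM)


@pytest.mark.parametrize("xi_true", [30.0, 54.0, 100.0, 200.0])
def test_full_pipeline_recovers_persistence(tmp_path, xi_true):
    """simulate -> write -> read -> drift-filter -> screen -> RMS -> invert."""
    model = TetherModel(LC_NM, xi_true, bead_radius=BEAD_R_NM)
    cfg = TpmSimConfig(
        model=model, duration=600.0,
        drift=DriftSpec(amplitude=150.0, kind="linear"),
        seed=2024,
    )
    write_trajectory(simulate_tpm(cfg), tmp_path / "run.csv")
    traj = drift_filter(read_trajectory(tmp_path / "run.csv"), 20.0)
    assert circularity_screen(traj).passed
    est = persistence_from_trajectory(traj, LC_NM, BEAD_R_NM)
    assert est.persistence_length == pytest.approx(xi_true, rel=0.10)
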