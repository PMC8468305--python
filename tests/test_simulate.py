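"""Synthetic race generator: racing lines, speed profile, sampling, noise."""

import numpy as np
import pandas as pd
import pytest
from pydantic import ValidationError

import houndpath as hp


class TestSpeedProfile:
    def test_default_profile_anchor_points(self):
        cfg = hp.SimulationConfig()
        speed = hp.make_speed_profile(cfg)
        assert speed(0.0) == pytest.approx(0.0, abs=1e-12)
        assert speed(120.0) == pytest.approx(19.4, rel=1e-12)
        assert speed(525.0) == pytest.approx(16.1, rel=1e-12)

    def test_long_distance_variant(self):
        cfg = hp.SimulationConfig(
            race_distance=725.0, race_label="725", end_speed=15.4
        )
        speed = hp.make_speed_profile(cfg)
        assert speed(725.0) == pytest.approx(15.4, rel=1e-12)

    def test_monotone_rise_then_linear_decay(self):
        speed = hp.make_speed_profile(hp.SimulationConfig())
        d = np.linspace(0, 525, 2000)
        v = np.asarray(speed(d))
        rise = v[d <= 120.0]
        decay = v[d >= 120.0]
        assert np.all(np.diff(rise) >= -1e-12)
        assert np.all(np.diff(decay) <= 1e-12)

    def test_motion_law_consistency(self):
        speed = hp.make_speed_profile(hp.SimulationConfig())
        t = speed.time_at_distance(525.0)
        assert speed.distance_at_time(t) == pytest.approx(525.0, abs=1e-6)
        # distance covered increases with time
        ts = np.linspace(0, t, 200)
        assert np.all(np.diff(speed.distance_at_time(ts)) > 0)

    def test_invalid_profile_rejected(self):
        with pytest.raises((ValidationError, ValueError)):
            hp.SimulationConfig(peak_speed=15.0, end_speed=16.0)
        with pytest.raises((ValidationError, ValueError)):
            hp.SimulationConfig(peak_distance=600.0, race_distance=525.0)


class TestRacingLine:
    def test_zero_easement_equals_offset_path(self, track):
        line = hp.make_racing_line(track, 1.0, 1.0, easement_length=0.0)
        ref = hp.offset_path(track, 1.0)
        assert line.loop_length == pytest.approx(ref.loop_length, rel=1e-12)
        d = hp.stadium_rail_distance(track, line.vertices[:-1])
        assert np.allclose(d, 1.0, atol=1e-6)

    def test_curvature_profile_no_overshoot(self, track):
        line = hp.make_racing_line(track, 1.5, 0.9, easement_length=25.0)
        kappa_bend = 1.0 / (51.0 + 0.9)
        assert np.max(np.abs(line.curvature)) == pytest.approx(kappa_bend, rel=1e-9)
        assert np.min(line.curvature) >= -1e-12

    def test_fitted_easement_honours_both_offsets(self, track):
        line = hp.make_racing_line(track, 1.5, 0.9)
        labels = hp.classify_sections(
            track, line.vertices[:-1],
            core_margin=line.meta["easement_length"] / 2 + 5.0,
        )
        d = hp.stadium_rail_distance(track, line.vertices[:-1])
        assert np.allclose(d[labels == "straight"], 1.5, atol=0.01)
        assert np.allclose(d[labels == "bend"], 0.9, atol=0.01)

    def test_explicit_easement_reports_achieved_straight_offset(self, track):
        line = hp.make_racing_line(track, 1.5, 0.9, easement_length=20.0)
        labels = hp.classify_sections(track, line.vertices[:-1], core_margin=16.0)
        d = hp.stadium_rail_distance(track, line.vertices[:-1])
        achieved = line.meta["achieved_straight_offset"]
        assert np.allclose(d[labels == "straight"], achieved, atol=0.01)
        assert np.allclose(d[labels == "bend"], 0.9, atol=0.01)

    def test_easement_too_long_rejected(self, track):
        with pytest.raises(ValueError):
            hp.make_racing_line(track, 1.0, 1.0, easement_length=90.0)

    def test_curvature_continuous_piecewise_linear(self, track):
        line = hp.make_racing_line(track, 1.5, 0.9, easement_length=25.0)
        dk_ds = np.diff(line.curvature) / np.diff(line.arclengths)
        # slope of the ramps is kappa_b / e; nothing steeper anywhere
        kappa_bend = 1.0 / 51.9
        assert np.max(np.abs(dk_ds)) <= kappa_bend / 25.0 * 1.05


class TestSimulateRace:
    def test_zero_noise_samples_on_racing_line(self, track, noisefree_race):
        rec, truth, cfg = noisefree_race
        rail = hp.rail_path(track)
        for sid in rec.greyhounds[:3]:
            sub = rec.subject_frame(sid)
            meta = rec.metadata["subjects"][sid]
            line = hp.make_racing_line(
                track,
                meta["bend_offset"] + 10,  # ignored: easement explicit below
                meta["bend_offset"],
                easement_length=meta["easement_length"],
            )
            pts = sub[["x_m", "y_m"]].to_numpy()
            d = [
                np.min(np.hypot(*(line.vertices - p).T)) for p in pts[::40]
            ]
            assert np.max(d) < 0.06  # vertex-spacing tolerance

    def test_determinism_same_seed(self, track):
        cfg = hp.SimulationConfig(rng_seed=9)
        r1, t1 = hp.simulate_race(track, cfg)
        r2, t2 = hp.simulate_race(track, cfg)
        pd.testing.assert_frame_equal(r1.data, r2.data)
        pd.testing.assert_frame_equal(t1.data, t2.data)

    def test_different_seed_differs(self, track):
        r1, _ = hp.simulate_race(track, hp.SimulationConfig(rng_seed=1))
        r2, _ = hp.simulate_race(track, hp.SimulationConfig(rng_seed=2))
        assert not r1.data["x_m"].equals(r2.data["x_m"])

    def test_planar_rms_noise_calibration(self, track):
        # per-axis 0.106 m should give ~0.150 m planar RMS
        cfg = hp.SimulationConfig(rng_seed=13)
        rec, truth = hp.simulate_race(track, cfg)
        err = (
            rec.data[["x_m", "y_m"]].to_numpy()
            - truth.data[["x_m", "y_m"]].to_numpy()
        )
        grey = rec.data["subject_id"] != hp.LURE_ID
        err = err[grey.to_numpy()]
        assert len(err) >= 5000
        rms = np.sqrt(np.mean(np.sum(err**2, axis=1)))
        assert rms == pytest.approx(0.150, rel=0.05)

    def test_distance_fidelity(self, noisefree_race):
        rec, truth, cfg = noisefree_race
        for sid in truth.greyhounds:
            xy = truth.subject_frame(sid)[["x_m", "y_m"]].to_numpy()
            d = np.sum(np.hypot(*np.diff(xy, axis=0).T))
            assert d == pytest.approx(cfg.race_distance, rel=5e-3)

    def test_speed_recovery(self, noisefree_race):
        rec, truth, cfg = noisefree_race
        profile = hp.make_speed_profile(cfg)
        sub = truth.subject_frame("g1")
        t = sub["t_s"].to_numpy()
        v = hp.instantaneous_speed(t, sub["x_m"].to_numpy(), sub["y_m"].to_numpy())
        xy = sub[["x_m", "y_m"]].to_numpy()
        dist = np.concatenate([[0], np.cumsum(np.hypot(*np.diff(xy, axis=0).T))])
        away = t > 2.0
        expected = np.asarray(profile(dist[away]))
        assert np.max(np.abs(v[away] - expected) / expected) < 0.01

    def test_curvature_recovery_on_bend_cores(self, track, noisefree_race):
        rec, truth, cfg = noisefree_race
        for sid in ("g1", "g5"):
            meta = truth.metadata["subjects"][sid]
            kappa_line = 1.0 / (51.0 + meta["bend_offset"])
            sub = hp.resample_to_frequency(truth.subject_frame(sid), 3.34)
            sub = sub[sub["t_s"] > 3.0].reset_index(drop=True)  # past launch
            kap = hp.curvature_series(sub["x_m"].to_numpy(), sub["y_m"].to_numpy())
            margin = meta["easement_length"] / 2 + 10.0
            labels = hp.classify_sections(
                track, sub[["x_m", "y_m"]].to_numpy(), core_margin=margin
            )
            est = kap[labels == "bend"]
            assert len(est) > 20
            assert np.allclose(est, kappa_line, rtol=5e-3)

    def test_median_rate_within_jitter(self, noisy_race):
        rec, _, cfg = noisy_race
        rate = rec.median_sample_rate("g1")
        assert (
            cfg.sample_rate_mean - cfg.sample_rate_jitter - 1e-6
            <= rate
            <= cfg.sample_rate_mean + cfg.sample_rate_jitter + 1e-6
        )

    def test_lure_present(self, noisy_race):
        rec, _, _ = noisy_race
        assert hp.LURE_ID in rec.subjects
        assert len(rec.greyhounds) == 8


class TestInjectArtifacts:
    def test_zero_window_unchanged(self, track, noisy_race):
        rec, _, cfg = noisy_race
        cfg0 = cfg.model_copy(update={"artifact_window": 0.0})
        out = hp.inject_artifacts(rec, cfg0)
        pd.testing.assert_frame_equal(out.data, rec.data)
        assert out.metadata["n_artifacts"] == 0

    def test_artifact_bookkeeping(self, track, noisy_race):
        rec, _, cfg = noisy_race
        cfg1 = cfg.model_copy(
            update={"artifact_window": 1.0, "artifact_fraction": 0.3,
                    "artifact_magnitude": 2.0}
        )
        out = hp.inject_artifacts(rec, cfg1)
        moved = ~np.isclose(
            out.data["x_m"].to_numpy(), rec.data["x_m"].to_numpy()
        ) | ~np.isclose(out.data["y_m"].to_numpy(), rec.data["y_m"].to_numpy())
        assert moved.sum() == out.metadata["n_artifacts"]
        assert len(out.metadata["artifact_rows"]) == out.metadata["n_artifacts"]
        # every displaced sample is displaced by exactly the magnitude
        d = np.hypot(
            out.data["x_m"].to_numpy() - rec.data["x_m"].to_numpy(),
            out.data["y_m"].to_numpy() - rec.data["y_m"].to_numpy(),
        )
        assert np.allclose(d[moved], 2.0, atol=1e-9)

    def test_samples_after_window_untouched(self, track, noisy_race):
        rec, _, cfg = noisy_race
        out = hp.inject_artifacts(rec, cfg)
        late = rec.data["t_s"].to_numpy() >= cfg.artifact_window
        assert np.array_equal(
            out.data.loc[late, ["x_m", "y_m"]].to_numpy(),
            rec.data.loc[late, ["x_m", "y_m"]].to_numpy(),
        )
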