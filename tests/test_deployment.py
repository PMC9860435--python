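"""Deployment state machine: intervalometer and triggered runs, rest
periods, exit conditions, folder layout, log replay, determinism."""

import filecmp
from pathlib import Path

import numpy as np
import pytest

from octotrigger import default_settings
from octotrigger.config import parse_settings
from octotrigger.deployment import (
    DeploymentRecord,
    HardwareContract,
    RampVoltage,
    SimClock,
    SimStorage,
    SimulatedCamera,
    check_exit,
    replay_deployment,
    run_deployment,
)
from octotrigger.simulate import SceneSpec, TargetSpec


def _intervalometer_settings():
    s = default_settings()
    s.general.collection_type = "still_intervalometer"
    return s


def _static_camera(duration_s=None):
    return SimulatedCamera(SceneSpec(duration_frames=0, seed=21),
                           duration_s=duration_s)


@pytest.fixture(scope="module")
def triggered_run(tmp_path_factory):
    """A 900 s triggered deployment with one fast target pass at t=200 s."""
    s = default_settings()
    scene = SceneSpec(duration_frames=900, seed=22)
    target = TargetSpec(entry_frame=200, velocity=(16.0, 0.0),
                        start_center=(-25.0, 120.0), contrast=60)
    hw = HardwareContract(camera=SimulatedCamera(scene, [target]))
    rec = run_deployment(hw, s, tmp_path_factory.mktemp("triggered"))
    return rec, s


def test_intervalometer_defaults_capture_exactly_ten(tmp_path):
    s = _intervalometer_settings()
    hw = HardwareContract(camera=_static_camera())
    rec = run_deployment(hw, s, tmp_path)
    assert rec.images_captured == 10
    assert rec.exit_reason == "max_images"
    assert np.allclose(np.diff(rec.capture_times), 1.0)
    assert len(list((rec.out_dir / "full").iterdir())) == 10


def test_deployment_folder_layout_and_snapshot(tmp_path):
    s = _intervalometer_settings()
    hw = HardwareContract(camera=_static_camera())
    rec = run_deployment(hw, s, tmp_path)
    assert (rec.out_dir / "settings.cfg").exists()
    assert (rec.out_dir / "log.csv").exists()
    assert (rec.out_dir / "full").is_dir() and (rec.out_dir / "tei").is_dir()
    assert parse_settings((rec.out_dir / "settings.cfg").read_text()) == s
    assert rec.name.startswith("D") and "-T" in rec.name


def test_triggered_run_one_capture_and_rest_gap(triggered_run):
    rec, s = triggered_run
    assert rec.images_captured == 1
    assert len(rec.trigger_times) == 1
    tt = rec.trigger_times[0]
    # no TEI evaluation lands inside the 5-minute rest window
    in_rest = [t for t in rec.eval_times if tt < t < tt + 300.0]
    assert in_rest == []
    next_eval = min(t for t in rec.eval_times if t > tt)
    assert next_eval - tt == pytest.approx(300.0)


def test_every_evaluated_tei_is_stored(triggered_run):
    rec, _ = triggered_run
    stored = list((rec.out_dir / "tei").iterdir())
    assert len(stored) == rec.teis_evaluated


def test_replay_from_log_matches_state_trace(triggered_run):
    rec, _ = triggered_run
    assert replay_deployment(rec.out_dir) == rec.state_trace
    states = [s for _, s in rec.state_trace]
    assert states == ["waiting", "sensing", "resting", "sensing", "shutdown"]


def test_low_voltage_shutdown_after_crossing(tmp_path):
    # voltage crosses 11 V at t = 3600 s; captures every 600 s
    s = _intervalometer_settings()
    s.intervalometer.max_images = 100
    s.intervalometer.image_interval = 600.0
    hw = HardwareContract(
        camera=_static_camera(),
        voltage=RampVoltage(v0=11.5, slope_per_hour=-0.5),
    )
    rec = run_deployment(hw, s, tmp_path)
    assert rec.exit_reason == "low_voltage"
    shutdown_t = rec.state_trace[-1][0]
    assert shutdown_t >= 3600.0
    assert all(v >= 11.0 for _, v in rec.voltage_trace)


def test_voltage_boundary_is_strict(settings):
    rec = DeploymentRecord(
        name="D01012022-T000000", settings=settings,
        start=None, mode="triggered", out_dir=Path("."),
    )

    class FixedVolts:
        def __init__(self, v):
            self.v = v

        def volts(self, t):
            return self.v

    hw = HardwareContract(camera=_static_camera(), voltage=FixedVolts(10.9))
    assert check_exit(rec, hw, settings) == "low_voltage"
    hw = HardwareContract(camera=_static_camera(), voltage=FixedVolts(11.0))
    assert check_exit(rec, hw, settings) is None


def test_disk_full_stops_before_capture(tmp_path):
    s = _intervalometer_settings()
    s.camera.image_type = "bmp"  # deterministic ~w*h file size
    # room for two worst-case monochrome M-tier images, minus headers
    hw = HardwareContract(camera=_static_camera(),
                          storage=SimStorage(capacity_bytes=2 * 2048 * 1520 + 2048))
    rec = run_deployment(hw, s, tmp_path)
    assert rec.exit_reason == "disk_full"
    assert 1 <= rec.images_captured < 10


def test_max_runtime_limits_sensing_period(tmp_path):
    s = default_settings()
    s.motion.max_runtime = 2  # minutes
    hw = HardwareContract(camera=_static_camera(duration_s=10_000))
    rec = run_deployment(hw, s, tmp_path)
    assert rec.exit_reason == "max_runtime"
    assert rec.sensing_elapsed > 120.0
    assert rec.sensing_elapsed < 130.0  # stops promptly after the limit


def test_end_of_input_when_scene_runs_out(tmp_path):
    s = default_settings()
    hw = HardwareContract(camera=SimulatedCamera(SceneSpec(duration_frames=120,
                                                           seed=23)))
    rec = run_deployment(hw, s, tmp_path)
    assert rec.exit_reason == "end_of_input"


def test_fixed_seed_runs_are_bit_identical(tmp_path):
    s = default_settings()
    scene = SceneSpec(duration_frames=150, seed=24)
    target = TargetSpec(entry_frame=50, velocity=(16.0, 0.0),
                        start_center=(-25.0, 120.0), contrast=60)

    def go(sub):
        hw = HardwareContract(camera=SimulatedCamera(scene, [target]),
                              clock=SimClock())
        return run_deployment(hw, s, tmp_path / sub)

    a, b = go("a"), go("b")
    assert a.name == b.name
    assert (a.out_dir / "log.csv").read_text() == (b.out_dir / "log.csv").read_text()
    files_a = sorted(p.name for p in (a.out_dir / "tei").iterdir())
    files_b = sorted(p.name for p in (b.out_dir / "tei").iterdir())
    assert files_a == files_b
    for name in files_a[:5] + files_a[-5:]:
        assert filecmp.cmp(a.out_dir / "tei" / name, b.out_dir / "tei" / name,
                           shallow=False)


def test_unwritable_output_fails_before_acquisition(tmp_path):
    target = tmp_path / "taken"
    target.write_text("a file, not a directory")
    s = _intervalometer_settings()
    hw = HardwareContract(camera=_static_camera())
    with pytest.raises(OSError):
        run_deployment(hw, s, target)


def test_fast_global_drift_ghost_triggers_after_rest(tmp_path):
    """Known limitation, pinned: the background model is frozen during
    the post-trigger rest, so global luminance drift fast enough to move
    the scene by more than the threshold within one rest period produces
    a spurious trigger at rest end (here: 15-min drift period, +-10 grey,
    5-min rest puts ~14 grey levels across the rest window)."""
    s = default_settings()
    scene = SceneSpec(duration_frames=950, seed=25, drift_period_s=900.0,
                      drift_amplitude=10.0)
    target = TargetSpec(entry_frame=200, velocity=(16.0, 0.0),
                        start_center=(-25.0, 120.0), contrast=60)
    hw = HardwareContract(camera=SimulatedCamera(scene, [target]))
    rec = run_deployment(hw, s, tmp_path, save_tei=False)
    assert len(rec.trigger_times) >= 2
    real = rec.trigger_times[0]
    ghost = rec.trigger_times[1]
    assert ghost == pytest.approx(real + 300.0)  # exactly at rest end
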