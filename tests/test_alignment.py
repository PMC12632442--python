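"""Sensor-to-segment alignment: prescribed-movement and walking routes."""

import numpy as np
import pytest

import headturnkit as htk
from headturnkit import alignment as aln
from headturnkit._rotations import euler_zyx, is_proper_rotation, rotation_angle_deg


def prescribed_recording(Q=None, noise_sd=0.0, seed=0, fs=100.0):
    """Prescribed-movement segment, optionally pre-rotated into a sensor
    frame by mounting rotation Q (sensor = Q @ segment)."""
    acc, gyr = htk.make_prescribed_segment(fs)
    if Q is not None:
        acc = acc @ Q.T
        gyr = gyr @ Q.T
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        gyr = gyr + rng.normal(0, noise_sd, gyr.shape)
        acc = acc + rng.normal(0, 0.01, acc.shape)
    n = acc.shape[0]
    return htk.ImuRecording(np.arange(n) / fs, acc, gyr, fs, "head")


def gait_recording(C=np.eye(3), n_steps=120, cadence=2.0, fs=100.0):
    va, steps = htk.make_gait_segment(n_steps, cadence, fs)
    n = va.size
    accel = np.zeros((n, 3))
    accel[:, 2] = va
    rec = htk.ImuRecording(
        np.arange(n) / fs, accel @ C.T, np.zeros((n, 3)), fs, "lumbar"
    )
    bout = htk.WalkingBout(
        step_times=steps, start=float(steps[0]), end=float(steps[-1]), long=True
    )
    return rec, bout


class TestDetectPrescribed:
    def test_single_event(self):
        rec = prescribed_recording()
        events = aln.detect_prescribed_movements(rec)
        assert len(events) == 1
        ev = events[0]
        assert ev.shake_peaks[2] < ev.nod_peaks[0] < ev.jump_peaks[0]

    def test_weak_jumps_not_detected(self):
        acc, gyr = htk.make_prescribed_segment(100, jump_peak_ms2=9.0)
        rec = htk.ImuRecording(np.arange(acc.shape[0]) / 100, acc, gyr, 100, "head")
        assert aln.detect_prescribed_movements(rec) == []

    def test_two_separated_events(self):
        acc, gyr = htk.make_prescribed_segment(100)
        n = acc.shape[0]
        gap = 60 * 100
        acc2 = np.vstack([acc, np.tile([0, 0, -1.0], (gap, 1)), acc])
        gyr2 = np.vstack([gyr, np.zeros((gap, 3)), gyr])
        rec = htk.ImuRecording(
            np.arange(acc2.shape[0]) / 100, acc2, gyr2, 100, "head"
        )
        assert len(aln.detect_prescribed_movements(rec)) == 2


class TestPrescribedAlignment:
    def test_identity_when_already_anatomical(self):
        rec = prescribed_recording()
        ev = aln.detect_prescribed_movements(rec)[0]
        tf = aln.alignment_from_prescribed(rec, ev)
        assert np.abs(tf.R - np.eye(3)).max() < 1e-6
        assert tf.provenance == "prescribed"

    @pytest.mark.parametrize(
        "euler", [(20, -15, 10), (-35, 5, 25), (30, 15, -20), (5, 0, 0)]
    )
    def test_known_rotation_recovered(self, euler):
        Q = euler_zyx(*euler)
        rec = prescribed_recording(Q=Q)
        ev = aln.detect_prescribed_movements(rec)[0]
        tf = aln.alignment_from_prescribed(rec, ev)
        assert np.abs(tf.R @ Q - np.eye(3)).max() < 1e-3

    def test_noisy_vertical_axis_error_below_2deg(self):
        """Monte-Carlo: with 1 deg/s gyro noise the recovered yaw (vertical)
        axis stays within 2 degrees (median over 20 seeds)."""
        Q = euler_zyx(15, -10, 20)
        errs = []
        for seed in range(20):
            rec = prescribed_recording(Q=Q, noise_sd=1.0, seed=seed)
            ev = aln.detect_prescribed_movements(rec)[0]
            tf = aln.alignment_from_prescribed(rec, ev)
            v_rec = tf.R[2]  # yaw axis row, sensor coordinates
            v_true = Q[:, 2]
            errs.append(
                np.rad2deg(np.arccos(np.clip(np.dot(v_rec, v_true), -1, 1)))
            )
        assert np.median(errs) < 2.0

    def test_parallel_axes_rejected(self):
        """Shake and nod about the same axis cannot define a frame."""
        acc, gyr = htk.make_prescribed_segment(100)
        gyr[:, 1] += gyr[:, 2]
        gyr[:, 2] = gyr[:, 1]  # nod == shake axis
        rec = htk.ImuRecording(np.arange(acc.shape[0]) / 100, acc, gyr, 100, "head")
        events = aln.detect_prescribed_movements(rec)
        if events:
            with pytest.raises(aln.AlignmentError, match="parallel"):
                aln.alignment_from_prescribed(rec, events[0])

    def test_transforms_are_proper_rotations(self):
        for euler in [(10, 5, -5), (40, -25, 15)]:
            rec = prescribed_recording(Q=euler_zyx(*euler), noise_sd=0.5, seed=1)
            ev = aln.detect_prescribed_movements(rec)[0]
            tf = aln.alignment_from_prescribed(rec, ev)
            assert is_proper_rotation(tf.R, atol=1e-9)


class TestWalkingAlignment:
    def test_level_gait_gives_identity(self):
        rec, bout = gait_recording()
        tf = aln.alignment_from_walking(rec, bout)
        assert np.abs(tf.R - np.eye(3)).max() < 1e-9
        assert tf.provenance == "walking"

    @pytest.mark.parametrize("tilt", [-20, -10, 5, 10, 20])
    def test_single_axis_ml_tilt_recovered(self, tilt):
        rec, bout = gait_recording(C=euler_zyx(0, tilt, 0))
        tf = aln.alignment_from_walking(rec, bout)
        assert rotation_angle_deg(tf.R @ euler_zyx(0, tilt, 0)) < 0.1
        aligned = aln.apply_transform(rec, tf)
        assert abs(aligned.accel[:, 2].mean()) < 0.01

    @pytest.mark.parametrize("tilt", [-20, -10, 10, 20])
    def test_single_axis_ap_tilt_recovered(self, tilt):
        rec, bout = gait_recording(C=euler_zyx(0, 0, tilt))
        tf = aln.alignment_from_walking(rec, bout)
        assert rotation_angle_deg(tf.R @ euler_zyx(0, 0, tilt)) < 0.1
        aligned = aln.apply_transform(rec, tf)
        assert abs(aligned.accel[:, 2].mean()) < 0.01

    def test_composed_tilt_matches_brute_force_vertical(self):
        """For combined tilts the two-angle matrix is compared against the
        minimal rotation mapping the mean accel vector onto the vertical."""
        for ml in (-20, -10, 10, 20):
            for ap in (-20, -10, 10, 20):
                C = euler_zyx(0, ml, ap)
                rec, bout = gait_recording(C=C, n_steps=100)
                tf = aln.alignment_from_walking(rec, bout)
                aligned = aln.apply_transform(rec, tf)
                # matrix route: vertical residual bounded
                assert abs(aligned.accel[:, 2].mean()) < 0.01
                # exact route: perfect gravity recovery
                tfx = aln.alignment_from_walking(rec, bout, method="exact")
                alx = aln.apply_transform(rec, tfx)
                assert abs(alx.accel[:, 2].mean()) < 1e-9

    def test_short_bout_rejected(self):
        rec, bout = gait_recording(n_steps=50)
        with pytest.raises(aln.AlignmentError, match="steps"):
            aln.alignment_from_walking(rec, bout)

    def test_non_quasi_static_rejected(self):
        rec, bout = gait_recording()
        rec.accel *= 1.5  # mean magnitude 1.5 g
        with pytest.raises(aln.AlignmentError, match="quasi-static"):
            aln.alignment_from_walking(rec, bout)


class TestApplyTransform:
    def test_identity_transform_is_noop(self):
        rec = prescribed_recording()
        tf = aln.RotationTransform(R=np.eye(3))
        out = aln.apply_transform(rec, tf)
        assert np.array_equal(out.gyro, rec.gyro)
        assert np.array_equal(out.accel, rec.accel)
        assert out.frame == "segment"

    def test_rotation_is_isometric_on_gyro(self):
        rec = prescribed_recording(Q=euler_zyx(30, 10, -20))
        tf = aln.RotationTransform(R=euler_zyx(10, 40, 5).T)
        out = aln.apply_transform(rec, tf)
        assert np.allclose(
            np.linalg.norm(out.gyro, axis=1), np.linalg.norm(rec.gyro, axis=1)
        )

    def test_inverse_recovers_gyro(self):
        rec = prescribed_recording()
        R = euler_zyx(25, -10, 5)
        out = aln.apply_transform(rec, aln.RotationTransform(R=R))
        out.frame = "sensor"
        back = aln.apply_transform(out, aln.RotationTransform(R=R.T))
        assert np.allclose(back.gyro, rec.gyro, atol=1e-12)

    def test_frame_mismatch_rejected(self):
        rec = prescribed_recording()
        out = aln.apply_transform(rec, aln.RotationTransform(R=np.eye(3)))
        with pytest.raises(ValueError, match="sensor-frame"):
            aln.apply_transform(out, aln.RotationTransform(R=np.eye(3)))


class TestTimeline:
    def _long_recording(self):
        fs = 100.0
        n = int(3 * 3600 * fs)
        accel = np.zeros((n, 3))
        accel[:, 2] = -1.0
        acc_p, gyr_p = htk.make_prescribed_segment(fs)
        gyro = np.zeros((n, 3))
        i0 = int(600 * fs)
        accel[i0 : i0 + acc_p.shape[0]] = acc_p
        gyro[i0 : i0 + gyr_p.shape[0]] = gyr_p
        va, steps = htk.make_gait_segment(120, 2.0, fs)
        i1 = int(2.5 * 3600 * fs)
        accel[i1 : i1 + va.size, 2] += va - (-1.0)
        rec = htk.ImuRecording(np.arange(n) / fs, accel, gyro, fs, "head")
        bout = htk.WalkingBout(
            step_times=i1 / fs + steps,
            start=i1 / fs + steps[0],
            end=i1 / fs + steps[-1],
            long=True,
        )
        return rec, bout

    def test_prescribed_only_covers_rest_of_day(self):
        rec, _ = self._long_recording()
        events = aln.detect_prescribed_movements(rec)
        timeline = aln.build_alignment_timeline(rec, events, [])
        aligned = [iv for iv in timeline if iv.transform is not None]
        assert len(aligned) == 1
        assert aligned[0].end == rec.time_s[-1]

    def test_walking_bout_splits_timeline(self):
        rec, bout = self._long_recording()
        events = aln.detect_prescribed_movements(rec)
        timeline = aln.build_alignment_timeline(rec, events, [bout])
        aligned = [iv for iv in timeline if iv.transform is not None]
        assert [iv.transform.provenance for iv in aligned] == [
            "prescribed",
            "walking",
        ]
        assert aligned[0].end == aligned[1].start == bout.start

    def test_no_source_flags_unaligned(self):
        rec, _ = self._long_recording()
        timeline = aln.build_alignment_timeline(rec, [], [])
        assert len(timeline) == 1
        assert timeline[0].transform is None

    def test_walking_bout_near_prescribed_event_is_dropped(self):
        rec, bout = self._long_recording()
        events = aln.detect_prescribed_movements(rec)
        near = htk.WalkingBout(
            step_times=bout.step_times - (bout.start - 700.0),
            start=700.0,
            end=700.0 + (bout.end - bout.start),
            long=True,
        )
        timeline = aln.build_alignment_timeline(rec, events, [near])
        aligned = [iv for iv in timeline if iv.transform is not None]
        assert [iv.transform.provenance for iv in aligned] == ["prescribed"]
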