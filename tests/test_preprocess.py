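"""Tests for standardization, exclusions, and tracking-derived measures."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as stn
from scipy.spatial.transform import Rotation

from glampi import (
    RawTrial,
    apply_exclusions,
    head_pitch,
    oob_angle,
    produced_turn,
    reconstruct_speed,
    standardize_dataset,
    standardize_trial,
)


def make_raw(c1, c2, c3, response, oob=False, oob_point=None, speed=1.0):
    c1, c2, c3 = map(np.asarray, (c1, c2, c3))
    l1 = np.hypot(*(c2 - c1))
    l2 = np.hypot(*(c3 - c2))
    return RawTrial(
        cone1=c1.astype(float),
        cone2=c2.astype(float),
        cone3=c3.astype(float),
        t_start=0.0,
        t_c2=l1 / speed,
        t_c3=(l1 + l2) / speed,
        response=None if response is None else np.asarray(response, float),
        oob=oob,
        oob_point=None if oob_point is None else np.asarray(oob_point, float),
    )


class TestStandardize:
    def test_right_turn_trial_is_flipped(self):
        # (1,1)->(1,3)->(3,3) turns right; canonical form mirrors it left
        raw = make_raw((1, 1), (1, 3), (3, 3), response=(1.5, 2.0))
        std = standardize_trial(raw)
        assert std.l1 == pytest.approx(2.0)
        assert std.l2 == pytest.approx(2.0)
        assert std.theta2 == pytest.approx(np.pi / 2)
        assert std.T1 == pytest.approx(2.0)
        assert std.T2 == pytest.approx(2.0)

    def test_canonical_trial_unchanged(self):
        raw = make_raw((0, 0), (2, 0), (2, 2), response=(0.3, 0.2))
        std = standardize_trial(raw)
        assert std.endpoint == pytest.approx([0.3, 0.2], abs=1e-12)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        angle=stn.floats(-np.pi, np.pi),
        tx=stn.floats(-10, 10),
        ty=stn.floats(-10, 10),
        mirror=stn.booleans(),
    )
    def test_invariant_under_rigid_motion_and_mirror(self, angle, tx, ty, mirror):
        base = make_raw((0, 0), (2, 0), (2.5, 1.8), response=(0.4, 0.3))
        ref = standardize_trial(base)
        c, s = np.cos(angle), np.sin(angle)
        rot = np.array([[c, -s], [s, c]])

        def xf(p):
            q = np.asarray(p, float)
            if mirror:
                q = q * np.array([1, -1])
            return rot @ q + np.array([tx, ty])

        moved = make_raw(xf(base.cone1), xf(base.cone2), xf(base.cone3), xf(base.response))
        std = standardize_trial(moved)
        for attr in ("l1", "l2", "theta2", "theta3", "l3", "correct_l3", "correct_angle"):
            assert getattr(std, attr) == pytest.approx(getattr(ref, attr), abs=1e-9)

    def test_coincident_cones_rejected(self):
        raw = make_raw((0, 0), (0, 0), (1, 1), response=(0, 0.5))
        raw.t_c2 = 1.0  # avoid zero leg time masking the geometry error
        with pytest.raises(ValueError):
            standardize_trial(raw)


class TestProducedTurn:
    def test_perfect_response_hits_correct_angle(self):
        raw = make_raw((0, 0), (2, 0), (2, 2), response=(0, 0))
        std = standardize_trial(raw)
        assert std.theta3 == pytest.approx(std.correct_angle, abs=1e-12)
        assert std.correct_angle == pytest.approx(3 * np.pi / 4)

    def test_hand_geometry_oracle(self):
        # heading (-1,1), response direction (-0.8,-0.9): ccw angle 1.6296
        raw = make_raw((0, -2), (0, 0), (-1, 1), response=(-1.8, 0.1))
        assert produced_turn(raw) == pytest.approx(1.6296, abs=1e-4)

    def test_clockwise_response_wraps_high(self):
        heading = np.array([-1.0, 1.0]) / np.sqrt(2)
        ten = np.deg2rad(10)
        c, s = np.cos(-ten), np.sin(-ten)
        d = np.array([c * heading[0] - s * heading[1], s * heading[0] + c * heading[1]])
        raw = make_raw((0, -2), (0, 0), (-1, 1), response=tuple(np.array([-1, 1]) + d))
        assert produced_turn(raw) == pytest.approx(2 * np.pi - ten, abs=1e-9)

    def test_endpoint_at_cone3_rejected(self):
        raw = make_raw((0, 0), (2, 0), (2, 2), response=(2, 2))
        with pytest.raises(ValueError):
            produced_turn(raw)


class TestOobAngle:
    def test_collinear_overshoot_gives_correct_angle(self):
        raw = make_raw((0, 0), (2, 0), (2, 2), response=None, oob=True, oob_point=(-1, -1))
        std = standardize_trial(raw)
        assert oob_angle(raw) == pytest.approx(std.correct_angle, abs=1e-12)
        assert std.l3 is None  # distance absent, not zero

    def test_matches_produced_turn_on_same_endpoint(self):
        point = (0.2, 0.4)
        oob = make_raw((0, 0), (2, 0), (2, 2), response=None, oob=True, oob_point=point)
        complete = make_raw((0, 0), (2, 0), (2, 2), response=point)
        assert oob_angle(oob) == pytest.approx(produced_turn(complete), abs=1e-12)

    def test_missing_point_is_tracking_fault(self):
        rows = pd.DataFrame(
            [
                dict(participant="p0", group="elderly", condition="no_change", environment=1, trial=0,
                     c1x=0, c1y=0, c2x=2, c2y=0, c3x=2, c3y=2, t_start=0, t_c2=2, t_c3=4, t_end=9,
                     resp_x=np.nan, resp_y=np.nan, oob=True, oob_x=np.nan, oob_y=np.nan, speed=1.0)
            ]
        )
        std = standardize_dataset(rows)
        assert not std["valid"].iloc[0]
        kept, report = apply_exclusions(std)
        assert len(kept) == 0
        assert report.trials["reason"].iloc[0] == "tracking_fault"


class TestExclusions:
    def _cohort_frame(self, n_trials=8, short_trial=None):
        rows = []
        for i in range(n_trials):
            resp = (0.3, 0.2)
            if short_trial == i:
                resp = (2.0, 1.6)  # 0.4 m from cone 3
            rows.append(
                dict(participant="p0", group="elderly", condition="no_change", environment=1, trial=i,
                     c1x=0, c1y=0, c2x=2, c2y=0, c3x=2, c3y=2, t_start=0, t_c2=2, t_c3=4, t_end=9,
                     resp_x=resp[0], resp_y=resp[1], oob=False, oob_x=np.nan, oob_y=np.nan, speed=1.0)
            )
        return pd.DataFrame(rows)

    def test_short_response_dropped(self):
        std = standardize_dataset(self._cohort_frame(short_trial=3))
        kept, report = apply_exclusions(std)
        assert len(kept) == 7
        assert report.trials.loc[report.trials["trial"] == 3, "reason"].iloc[0] == "short_response"

    def test_cell_below_seven_usable_dropped(self):
        std = standardize_dataset(self._cohort_frame(n_trials=7, short_trial=0))
        kept, report = apply_exclusions(std)
        assert len(kept) == 0  # 6 usable trials: whole cell dropped
        assert not report.cells["keep"].iloc[0]


class TestSpeed:
    def _track(self, speeds, dt=0.1):
        t = np.arange(len(speeds) + 1) * dt
        x = np.concatenate([[0.0], np.cumsum(np.asarray(speeds) * dt)])
        return pd.DataFrame({"t": t, "x": x, "y": 0.0})

    def test_stationary_gives_missing_value(self):
        track = self._track(np.zeros(50))
        assert np.isnan(reconstruct_speed(track))

    def test_half_stationary_half_moving(self):
        track = self._track(np.concatenate([np.zeros(150), np.ones(900), np.zeros(150)]))
        est = reconstruct_speed(track)
        assert est == pytest.approx(1.0, rel=0.07)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            reconstruct_speed(pd.DataFrame({"t": [0.0], "x": [0.0], "y": [0.0]}))


class TestHeadPitch:
    def test_level_forward_is_orthogonal_to_up(self):
        assert head_pitch([[1.0, 0, 0, 0]]) == pytest.approx(90.0, abs=1e-9)

    def test_thirty_degree_downward_tilt(self):
        q = Rotation.from_euler("Y", 30, degrees=True).as_quat()  # x,y,z,w
        assert head_pitch([[q[3], q[0], q[1], q[2]]]) == pytest.approx(120.0, abs=1e-9)

    def test_random_quaternion_matches_rotation_matrix_oracle(self, rng):
        for _ in range(20):
            q = rng.standard_normal(4)
            q /= np.linalg.norm(q)
            rot = Rotation.from_quat([q[1], q[2], q[3], q[0]])
            fwd = rot.as_matrix() @ np.array([1.0, 0, 0])
            expected = np.degrees(np.arccos(np.clip(fwd[2], -1, 1)))
            assert head_pitch([q]) == pytest.approx(expected, abs=1e-9)

    def test_zero_norm_rejected(self):
        with pytest.raises(ValueError):
            head_pitch([[0.0, 0.0, 0.0, 0.0]])
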