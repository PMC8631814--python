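"""Channel metrology: co-registration, cross sections, wall classification,
LD/DD/CW/CD reduction and margin-violation length."""

import numpy as np
import pytest

from channelmill.carve import ExecutionError, carve
from channelmill.geometry import RigidTransform
from channelmill.metrics import (
    ChannelMeasurement,
    coregister,
    margin_violation_length,
    measure_channel,
    sample_cross_sections,
)

from .conftest import make_flat_site, make_straight_plan, straight_channel_toolpath


def random_transform(rng):
    axis = rng.normal(size=3)
    return RigidTransform.from_axis_angle(
        axis / np.linalg.norm(axis), rng.uniform(-0.5, 0.5), rng.uniform(-5, 5, 3)
    )


class TestCoregister:
    def test_identity(self):
        fid = np.array([[0, 0, 0], [10, 0, 0], [0, 10, 0], [10, 10, 2]], dtype=float)
        t = coregister(fid, fid)
        assert np.allclose(t.rotation, np.eye(3), atol=1e-12)

    def test_recovers_scanner_frame(self):
        rng = np.random.default_rng(20)
        fid = rng.uniform(0, 20, (4, 3))
        scanner = random_transform(rng)
        back = coregister(fid, scanner.apply(fid))
        inv = scanner.inverse()
        assert np.allclose(back.rotation, inv.rotation, atol=1e-9)
        assert np.allclose(back.translation, inv.translation, atol=1e-9)

    def test_three_of_four_fiducials_sufficient(self):
        rng = np.random.default_rng(21)
        fid = rng.uniform(0, 20, (4, 3))
        scanner = random_transform(rng)
        back = coregister(fid[:3], scanner.apply(fid[:3]))
        assert np.allclose(back.rotation, scanner.inverse().rotation, atol=1e-9)


class TestCrossSections:
    def test_section_count(self, flat_site, flat_plan, flat_carve):
        s_values = np.arange(0.0, 16.0 + 0.05, 0.1)
        sections = sample_cross_sections(flat_carve.postop, flat_plan, s_values)
        assert len(sections) == 161

    def test_rays_perpendicular_to_tangent(self, flat_plan):
        from channelmill.metrics import _section_frames

        frames = _section_frames(flat_plan, np.array([3.0, 8.0]))
        th = np.linspace(0, 2 * np.pi, 90, endpoint=False)
        for f in frames:
            dirs = np.cos(th)[:, None] * f.right + np.sin(th)[:, None] * f.up
            assert np.abs(dirs @ f.tangent).max() < 1e-9

    def test_five_wall_groups_in_clean_section(self, flat_site, flat_plan, flat_carve):
        sections = sample_cross_sections(flat_carve.postop, flat_plan, np.array([8.0]))
        sec = sections[0]
        assert not sec.missing
        for group in ("top_left", "left", "bottom", "right", "top_right"):
            assert len(sec.group(group)) >= 1


class TestClosedLoopMeasurement:
    def test_perfect_carve_recovers_plan(self, flat_site, flat_plan, flat_carve):
        meas = measure_channel(flat_carve.postop, flat_plan, spacing=0.1, rays=90,
                               s_range=(1.0, flat_plan.length - 1.0))
        ok = ~meas.missing
        assert ok.mean() > 0.95
        assert abs(meas.ld[ok].mean()) <= 0.1
        assert abs(meas.dd[ok].mean()) <= 0.1
        assert meas.cw[ok].mean() == pytest.approx(1.2, abs=0.1)
        assert meas.cd[ok].mean() == pytest.approx(2.3, abs=0.1)

    def test_left_bias_sign_convention(self, flat_site, flat_plan):
        # milling direction +x, tool axis +z: left is +y, reported negative
        err = ExecutionError(RigidTransform(np.eye(3), [0.0, 0.2, 0.0]))
        res = carve(flat_site, straight_channel_toolpath(flat_plan), err, voxel=0.05)
        meas = measure_channel(res.postop, flat_plan, spacing=0.1, rays=90,
                               s_range=(1.0, flat_plan.length - 1.0))
        assert meas.ld[~meas.missing].mean() == pytest.approx(-0.2, abs=0.1)

    def test_deep_bias_sign_convention(self, flat_site, flat_plan):
        err = ExecutionError(RigidTransform(np.eye(3), [0.0, 0.0, -0.3]))
        res = carve(flat_site, straight_channel_toolpath(flat_plan), err, voxel=0.05)
        meas = measure_channel(res.postop, flat_plan, spacing=0.1, rays=90,
                               s_range=(1.0, flat_plan.length - 1.0))
        assert meas.dd[~meas.missing].mean() == pytest.approx(-0.3, abs=0.1)

    def test_rigid_motion_invariance(self, flat_site, flat_plan, flat_carve):
        base = measure_channel(flat_carve.postop, flat_plan, spacing=0.2, rays=60,
                               s_range=(2.0, 10.0))
        t = random_transform(np.random.default_rng(22))
        moved = measure_channel(flat_carve.postop.transformed(t),
                                flat_plan.transformed(t), spacing=0.2, rays=60,
                                s_range=(2.0, 10.0))
        ok = ~(base.missing | moved.missing)
        for a, b in ((base.ld, moved.ld), (base.dd, moved.dd),
                     (base.cw, moved.cw), (base.cd, moved.cd)):
            assert np.abs(a[ok] - b[ok]).max() < 1e-6


@pytest.fixture(scope="module")
def carved_with_void():
    # air cell centered on the right wall of the groove at x = 12
    site = make_flat_site(air_cells=[[12.0, 10.6, -1.2, 0.8]])
    plan = make_straight_plan(site)
    res = carve(site, straight_channel_toolpath(plan), voxel=0.05)
    meas = measure_channel(res.postop, plan, spacing=0.1, rays=90,
                           s_range=(1.0, plan.length - 1.0))
    return site, plan, meas


class TestAirCellGaps:

    def test_void_sections_flagged_missing(self, carved_with_void):
        _, plan, meas = carved_with_void
        s_global = meas.s + plan.surface_points[0, 0]  # plan starts at x=4
        in_void = np.abs(s_global + 4.0 - 12.0 - 4.0) < 0.5
        in_void = np.abs((meas.s + 4.0) - 12.0) < 0.5
        assert meas.missing[in_void].mean() > 0.5
        far = np.abs((meas.s + 4.0) - 12.0) > 2.0
        assert meas.missing[far].mean() < 0.05

    def test_missing_data_neutrality(self, carved_with_void, flat_carve, flat_plan):
        """Voids change statistics only through removed sections."""
        _, plan, meas_void = carved_with_void
        meas_clean = measure_channel(flat_carve.postop, flat_plan, spacing=0.1,
                                     rays=90, s_range=(1.0, flat_plan.length - 1.0))
        keep = ~meas_void.missing & ~meas_clean.missing
        # on sections that survive in both, the void changes nothing material
        assert np.nanmax(np.abs(meas_void.cw[keep] - meas_clean.cw[keep])) < 0.05
        assert np.nanmax(np.abs(meas_void.ld[keep] - meas_clean.ld[keep])) < 0.05


class TestMarginViolation:
    def make_measurement(self, ld, missing=None):
        n = len(ld)
        ld = np.asarray(ld, dtype=float)
        if missing is None:
            missing = np.zeros(n, dtype=bool)
        return ChannelMeasurement(
            s=np.arange(n) * 0.1, ld=ld, dd=np.zeros(n), cw=np.full(n, 1.2),
            cd=np.full(n, 2.3), missing=missing, centerline=np.zeros((n, 3)),
            spacing=0.1, tool_diameter=1.2, channel_depth=2.3,
        )

    def test_small_errors_give_zero(self):
        meas = self.make_measurement(np.full(100, 0.4))
        assert margin_violation_length(meas, 1.0) == 0.0

    def test_constructed_stretch(self):
        ld = np.zeros(100)
        ld[30:50] = 1.2  # 20 sections at 0.1 mm spacing
        meas = self.make_measurement(ld)
        assert margin_violation_length(meas, 1.0) == pytest.approx(2.0)

    def test_all_missing_warns_and_returns_zero(self):
        meas = self.make_measurement(np.full(10, 2.0), missing=np.ones(10, dtype=bool))
        with pytest.warns(UserWarning):
            assert margin_violation_length(meas, 1.0) == 0.0
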