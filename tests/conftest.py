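"""Shared fixtures: analytic flat sites with hand-built straight plans for
carve/metrology oracles, and session-scoped desk-scale study runs reused by
the acceptance tests."""

from __future__ import annotations

import numpy as np
import pytest

from channelmill.geometry import Trajectory
from channelmill.planner import ChannelPlan, PlanParams, PlaneFrame
from channelmill.geometry import BezierSegment, CompositePath
from channelmill.site import (
    FANTAIL_TEMPLATE,
    ForbiddenStructure,
    Polyline,
    SurgicalSite,
    fantail_pose_from_points,
    tripod_pose_from_points,
)
from channelmill.study import StudyConfig, run_study
from channelmill.toolpath import ToolPath

STUDY_SEED = 3  # fixed study seed for the whole suite


def make_flat_site(extent=(24.0, 20.0), thickness=6.0, spacing=0.5, air_cells=()):
    """Flat slab site: outer surface exactly z=0, inner z=-thickness."""
    from channelmill.site import _grid_mesh

    lx, ly = extent
    xs = np.arange(0.0, lx + spacing / 2, spacing)
    ys = np.arange(0.0, ly + spacing / 2, spacing)
    zero = np.zeros((len(xs), len(ys)))
    outer = _grid_mesh(xs, ys, zero)
    inner = _grid_mesh(xs, ys, zero - thickness, flip=True)
    entry = np.array([2.0, ly / 2, 0.0])
    exit_pt = np.array([lx - 2.0, ly / 2, 0.0])
    fantail_points = exit_pt + FANTAIL_TEMPLATE
    legs = np.array([[3.0, 3.0, 0.0], [5.0, 3.0, 0.0], [4.0, 5.0, 0.0]])
    site = SurgicalSite(
        outer=outer,
        inner=inner,
        fiducials=np.array(
            [[2, 5, 0.5], [2, ly - 5, 0.5], [6, 5, 0.5], [6, ly - 5, 0.5]], dtype=float
        ),
        tripod_pose=tripod_pose_from_points(legs),
        fantail_pose=fantail_pose_from_points(*fantail_points),
        fantail_points=fantail_points,
        incision=Polyline([[1, ly - 1, 0], [lx - 1, ly - 1, 0]]),
        trajectory=Trajectory(entry, [0.0, 0.0, -1.0], 25.0),
        forbidden=[],
        air_cells=np.asarray(air_cells, dtype=float).reshape(-1, 4),
    )
    return site


def make_straight_plan(site, x0=4.0, x1=None, depth=2.3, tool=1.2, spacing=0.1):
    """Hand-built straight channel plan along +x at the slab mid-line."""
    lx, ly = site.outer.vertices[:, 0].max(), site.outer.vertices[:, 1].max()
    if x1 is None:
        x1 = lx - 4.0
    y = ly / 2.0
    n = int(round((x1 - x0) / spacing)) + 1
    s = np.linspace(0.0, x1 - x0, n)
    surf = np.column_stack([x0 + s, np.full(n, y), np.zeros(n)])
    axes = np.tile([0.0, 0.0, 1.0], (n, 1))
    frame = PlaneFrame(
        origin=np.array([x0, y, 0.0]),
        u=np.array([1.0, 0.0, 0.0]),
        v=np.array([0.0, 1.0, 0.0]),
        n=np.array([0.0, 0.0, 1.0]),
    )
    length = x1 - x0
    third = length / 3.0
    cp = lambda a, b: BezierSegment(
        np.array([[a, 0, 0], [a + (b - a) / 3, 0, 0], [b - (b - a) / 3, 0, 0], [b, 0, 0]])
    )
    path2d = CompositePath([cp(0, third), cp(third, 2 * third), cp(2 * third, length)])
    params = PlanParams(target_length=length + 1.0, channel_depth=depth, tool_diameter=tool)
    return ChannelPlan(
        frame=frame,
        path2d=path2d,
        s=s,
        surface_points=surf,
        bottom_points=surf - depth * axes,
        tool_axes=axes,
        params=params,
        flags={"achieved_length": length, "min_curvature_radius": float("inf"),
               "curvature_warning": False, "self_intersecting": False},
    )


def straight_channel_toolpath(plan):
    n = len(plan.s)
    return ToolPath(
        plan.bottom_points, plan.tool_axes, np.full(n, "channel"),
        np.full(n, 2.0), plan.params.tool_diameter, 30_000.0,
    )


@pytest.fixture(scope="session")
def flat_site():
    return make_flat_site()


@pytest.fixture(scope="session")
def flat_plan(flat_site):
    return make_straight_plan(flat_site)


@pytest.fixture(scope="session")
def flat_carve(flat_site, flat_plan):
    from channelmill.carve import carve

    return carve(flat_site, straight_channel_toolpath(flat_plan), voxel=0.05)


@pytest.fixture(scope="session")
def study_config():
    return StudyConfig(seed=STUDY_SEED)


@pytest.fixture(scope="session")
def zero_error_report(study_config):
    """12-site desk-scale study with no injected error."""
    return run_study(study_config)


@pytest.fixture(scope="session")
def jitter_report():
    """Smooth navigation jitter of sigma 0.1 mm, channel pass only (the
    widening is excluded from LD/DD measurement, so leaving it unmilled
    doubles the measured window per site)."""
    return run_study(
        StudyConfig(seed=STUDY_SEED, jitter_sigma_lateral=0.1,
                    jitter_sigma_depth=0.1, widening_location="")
    )


@pytest.fixture(scope="session")
def planned_desk_site(study_config):
    """One planned desk-scale site with its full toolpath."""
    from channelmill.study import _planned_site, _site_seed

    return _planned_site(study_config, _site_seed(study_config, 0))


@pytest.fixture(scope="session")
def bias_recovery_trials(planned_desk_site):
    """Rigid translation biases carved into one site and re-measured.

    Returns a list of (bias vector, measurement, plan) triples for 20 seeded
    biases with norm <= 0.3 mm, carving the channel pass only.
    """
    from channelmill.carve import carve, inject_error
    from channelmill.metrics import measure_channel

    site, plan, _, tp = planned_desk_site
    mask = tp.phases == "channel"
    channel_tp = ToolPath(tp.positions[mask], tp.axes[mask], tp.phases[mask],
                          tp.feeds[mask], tp.tool_diameter, tp.spindle_rpm)
    trials = []
    seed = 900
    while len(trials) < 20:
        err = inject_error(seed, bias_translation_sigma=0.12)
        seed += 1
        if np.linalg.norm(err.bias.translation) > 0.3:
            continue
        res = carve(site, channel_tp, err, voxel=0.05)
        meas = measure_channel(res.postop, plan, spacing=0.15, rays=90,
                               s_range=(1.0, plan.length - 1.0))
        trials.append((err.bias.translation, meas, plan))
    return trials
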