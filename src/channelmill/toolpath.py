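"""Executable milling toolpaths.

Turns a :class:`~channelmill.planner.ChannelPlan` into ordered waypoint
sequences for the five milling phases: cylindrical access-point preparation
at the drill trajectory, the curvature-optimized tunnel-to-surface
transition, the channel pass itself, the contour-offset spiral filling of a
channel widening, and the ramped fantail implant-bed recess.  Also hosts the
force-based feed-velocity law.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, minimize
from scipy.spatial import cKDTree
from shapely import contains_xy
from shapely.geometry import LineString, Point, Polygon
from shapely.geometry.polygon import orient

from .geometry import BezierSegment, CompositePath
from .planner import ChannelPlan, InfeasiblePlanError

__all__ = [
    "ToolPath",
    "WideningSpec",
    "FeedCommand",
    "access_prep_path",
    "transition_path",
    "widening_boundary",
    "spiral_fill",
    "implant_bed_path",
    "feed_velocity",
    "coverage_fraction",
    "build_full_toolpath",
    "PHASES",
]

PHASES = ("access_prep", "transition", "channel", "widening", "bed")

DEFAULT_SPINDLE_RPM = 30_000.0
DEFAULT_FEED = 2.0  # mm/s forward velocity setpoint


@dataclass
class ToolPath:
    """Ordered milling waypoints with tool axes, phase labels and feeds."""

    positions: np.ndarray
    axes: np.ndarray
    phases: np.ndarray
    feeds: np.ndarray
    tool_diameter: float = 1.2
    spindle_rpm: float = DEFAULT_SPINDLE_RPM

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.axes = np.atleast_2d(np.asarray(self.axes, dtype=float))
        self.phases = np.asarray(self.phases)
        self.feeds = np.asarray(self.feeds, dtype=float)
        n = len(self.positions)
        if not (len(self.axes) == len(self.phases) == len(self.feeds) == n):
            raise ValueError("waypoint arrays must share a length")
        norms = np.linalg.norm(self.axes, axis=1)
        if n and not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("tool axes must be unit-norm")

    def __len__(self) -> int:
        return len(self.positions)

    @staticmethod
    def concat(paths: list) -> "ToolPath":
        paths = [p for p in paths if len(p)]
        return ToolPath(
            np.vstack([p.positions for p in paths]),
            np.vstack([p.axes for p in paths]),
            np.concatenate([p.phases for p in paths]),
            np.concatenate([p.feeds for p in paths]),
            tool_diameter=paths[0].tool_diameter,
            spindle_rpm=paths[0].spindle_rpm,
        )

    def densified(self, max_spacing: float = 0.2) -> "ToolPath":
        """Insert linear waypoints so consecutive spacing within a phase
        never exceeds ``max_spacing``."""
        pos, ax, ph, fd = [], [], [], []
        for i in range(len(self) - 1):
            pos.append(self.positions[i])
            ax.append(self.axes[i])
            ph.append(self.phases[i])
            fd.append(self.feeds[i])
            if self.phases[i] != self.phases[i + 1]:
                continue
            d = float(np.linalg.norm(self.positions[i + 1] - self.positions[i]))
            if d > max_spacing:
                k = int(np.ceil(d / max_spacing))
                for j in range(1, k):
                    t = j / k
                    pos.append((1 - t) * self.positions[i] + t * self.positions[i + 1])
                    a = (1 - t) * self.axes[i] + t * self.axes[i + 1]
                    ax.append(a / np.linalg.norm(a))
                    ph.append(self.phases[i])
                    fd.append(self.feeds[i])
        pos.append(self.positions[-1])
        ax.append(self.axes[-1])
        ph.append(self.phases[-1])
        fd.append(self.feeds[-1])
        return ToolPath(
            np.asarray(pos), np.asarray(ax), np.asarray(ph), np.asarray(fd),
            self.tool_diameter, self.spindle_rpm,
        )

    def phase_order(self) -> list:
        out = []
        for p in self.phases:
            if not out or out[-1] != p:
                out.append(str(p))
        return out


@dataclass
class FeedCommand:
    velocity: float
    interrupt: bool = False


def feed_velocity(
    force: float, v_set: float = 2.0, f_lin: float = 4.0, f_max: float = 10.0
) -> FeedCommand:
    """Force-based feed-forward velocity law.

    Full setpoint velocity up to ``f_lin``, then a linear decrease reaching
    zero at ``f_max``, where the system interrupts and asks for user
    interaction.
    """
    if force < 0:
        raise ValueError("force must be non-negative")
    if force >= f_max:
        return FeedCommand(0.0, interrupt=True)
    if force <= f_lin:
        return FeedCommand(float(v_set))
    return FeedCommand(float(v_set * (f_max - force) / (f_max - f_lin)))


# ---------------------------------------------------------------------------
# access-point preparation
# ---------------------------------------------------------------------------


def _plane_basis(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, axis)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, ref)
    e1 /= np.linalg.norm(e1)
    return e1, np.cross(axis, e1)


def access_prep_path(
    traj,
    prep_diameter: float = 1.8,
    level_step: float = 1.0,
    prep_depth: float = 5.0,
    tool_diameter: float = 1.2,
    feed: float = DEFAULT_FEED,
    spindle_rpm: float = DEFAULT_SPINDLE_RPM,
) -> ToolPath:
    """Cylindrical pre-milling at the drill trajectory entry.

    Milled in ``level_step`` levels down to ``prep_depth``: per level a
    central plunge along the trajectory axis, then a circle about the axis
    at radius (prep_diameter - tool_diameter) / 2.
    """
    if prep_diameter < tool_diameter:
        raise ValueError("prep diameter smaller than the tool diameter")
    a = traj.axis  # into the bone
    e1, e2 = _plane_basis(a)
    r = (prep_diameter - tool_diameter) / 2.0
    n_levels = int(round(prep_depth / level_step))
    pos, axes = [], []
    tool_axis = -a
    for lvl in range(1, n_levels + 1):
        center = traj.entry + a * (lvl * level_step)
        pos.append(center)
        axes.append(tool_axis)
        if r > 1e-9:
            n_pts = max(8, int(np.ceil(2 * np.pi * r / 0.2)) + 1)
            th = np.linspace(0.0, 2 * np.pi, n_pts)
            ring = center + r * (np.cos(th)[:, None] * e1 + np.sin(th)[:, None] * e2)
            pos.extend(ring)
            axes.extend([tool_axis] * len(ring))
    pos = np.asarray(pos)
    n = len(pos)
    return ToolPath(
        pos,
        np.asarray(axes),
        np.full(n, "access_prep"),
        np.full(n, feed),
        tool_diameter,
        spindle_rpm,
    )


# ---------------------------------------------------------------------------
# tunnel-to-surface transition
# ---------------------------------------------------------------------------


def transition_path(p0, t0, p1, t1, tool_diameter: float = 1.2) -> CompositePath:
    """Curvature-optimized G1 cubic connecting two oriented waypoints.

    Positions and tangent directions are matched at both ends; the two
    tangent magnitudes are chosen to minimize the maximum curvature.
    """
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    t0 = np.asarray(t0, dtype=float)
    t1 = np.asarray(t1, dtype=float)
    t0 = t0 / np.linalg.norm(t0)
    t1 = t1 / np.linalg.norm(t1)
    chord = float(np.linalg.norm(p1 - p0))
    if chord < 1e-9:
        cp = np.vstack([p0, p0, p1, p1])
        return CompositePath([BezierSegment(cp)])
    if np.dot(t0, t1) < -0.999 and chord < tool_diameter:
        raise InfeasiblePlanError(
            "anti-parallel transition tangents closer than one tool diameter"
        )

    ts = np.linspace(0.02, 0.98, 60)

    def build(m0, m1):
        return BezierSegment(np.vstack([p0, p0 + m0 * t0, p1 - m1 * t1, p1]))

    def cost(logm):
        seg = build(np.exp(logm[0]), np.exp(logm[1]))
        return float(seg.curvature(ts).max())

    res = minimize(
        cost,
        np.log([chord / 3.0, chord / 3.0]),
        method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-8, "maxiter": 400},
    )
    m0, m1 = np.exp(res.x)
    return CompositePath([build(m0, m1)])


# ---------------------------------------------------------------------------
# widening
# ---------------------------------------------------------------------------


@dataclass
class WideningSpec:
    """Widening region around one channel curve.

    The closed boundary is formed by two Bezier curves tangent to the
    channel at the window ends: an inner (taut) curve whose length is the
    shortest lead route through the region, and an outer (bulged) curve
    whose length is the longest smooth route.  The size class fixes those
    lengths relative to the planned window length (small: -1.0 / +2.0 mm).
    """

    location: str
    size: tuple
    s_interval: tuple                 # (start, end) arc length on the planar path
    inner_curve: BezierSegment
    outer_curve: BezierSegment
    boundary2d: np.ndarray            # closed polygon, plane coordinates
    shortest_route: float
    longest_route: float

    def to_dict(self) -> dict:
        return {
            "location": self.location,
            "size": list(self.size),
            "s_interval": list(self.s_interval),
            "inner_curve": self.inner_curve.control_points.tolist(),
            "outer_curve": self.outer_curve.control_points.tolist(),
            "shortest_route": self.shortest_route,
            "longest_route": self.longest_route,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "WideningSpec":
        inner = BezierSegment(np.asarray(d["inner_curve"]))
        outer = BezierSegment(np.asarray(d["outer_curve"]))
        return cls(
            d["location"], tuple(d["size"]), tuple(d["s_interval"]), inner, outer,
            _boundary_from_curves(inner, outer), d["shortest_route"], d["longest_route"],
        )


def _boundary_from_curves(inner: BezierSegment, outer: BezierSegment, n: int = 120) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n)
    fwd = inner.evaluate(t)[:, :2]
    back = outer.evaluate(t[::-1])[:, :2]
    return np.vstack([fwd, back[1:]])


def _hermite_family(p_a, t_a, p_b, t_b, arm):
    def make(lam):
        cp = np.vstack(
            [p_a, p_a + lam * arm * t_a, p_b - lam * arm * t_b, p_b]
        )
        return BezierSegment(cp)
    return make


def widening_boundary(
    plan: ChannelPlan,
    location: str = "curve1",
    size: tuple = (-1.0, 2.0),
    window_fraction: float = 0.35,
) -> WideningSpec | list:
    """Construct the widening boundary tangent to the channel path.

    ``location`` is "curve1", "curve2" or "both".  The planned window is the
    arc-length interval centered on the chosen curve; the boundary's inner
    and outer curves meet the route-length window [planned + size[0],
    planned + size[1]] within 0.3 mm.
    """
    if location == "both":
        return [
            widening_boundary(plan, "curve1", size, window_fraction),
            widening_boundary(plan, "curve2", size, window_fraction),
        ]
    if location not in ("curve1", "curve2"):
        raise ValueError("location must be 'curve1', 'curve2' or 'both'")

    path = plan.path2d
    seg_lengths = [seg.arc_length() for seg in path.segments]
    total = sum(seg_lengths)
    center = seg_lengths[0] if location == "curve1" else seg_lengths[0] + seg_lengths[1]
    half = window_fraction * total / 2.0
    # the window must stay on one side of the S inflection (mid of the
    # middle segment), where the bulge direction flips
    inflection = seg_lengths[0] + seg_lengths[1] / 2.0
    if location == "curve1":
        lo_cap, hi_cap = 0.5, inflection - 0.3
    else:
        lo_cap, hi_cap = inflection + 0.3, total - 0.5

    s2, pts, tang = path.sample_by_arclength(0.02)
    pts2, tang2 = pts[:, :2], tang[:, :2]

    def window_geometry(half_width):
        sa = max(lo_cap, center - half_width)
        sb = min(hi_cap, center + half_width)
        ia = int(np.argmin(np.abs(s2 - sa)))
        ib = int(np.argmin(np.abs(s2 - sb)))
        p_a, p_b = pts2[ia], pts2[ib]
        t_a = tang2[ia] / np.linalg.norm(tang2[ia])
        t_b = tang2[ib] / np.linalg.norm(tang2[ib])
        lw = float(s2[ib] - s2[ia])
        chord = float(np.linalg.norm(p_b - p_a))
        return sa, sb, p_a, t_a, p_b, t_b, lw, chord, (ia, ib)

    sa, sb, p_a, t_a, p_b, t_b, lw, chord, (ia, ib) = window_geometry(half)
    # the shortest route cannot be shorter than the chord: grow the window
    # (within the curve's own half of the S) until there is enough slack
    grow = half
    while lw + size[0] < chord + 0.3 and grow < hi_cap - lo_cap:
        grow *= 1.3
        sa, sb, p_a, t_a, p_b, t_b, lw, chord, (ia, ib) = window_geometry(grow)
    if lw + size[0] < chord + 0.02:
        raise InfeasiblePlanError(
            f"widening at {location} infeasible (window too straight); "
            "try the other curve"
        )

    p_a3 = np.append(p_a, 0.0)
    p_b3 = np.append(p_b, 0.0)
    t_a3 = np.append(t_a, 0.0)
    t_b3 = np.append(t_b, 0.0)
    make = _hermite_family(p_a3, t_a3, p_b3, t_b3, lw / 3.0)

    def length_of(lam):
        return make(lam).arc_length()

    def solve(target):
        lo, hi = 1e-4, 1.0
        while length_of(hi) < target and hi < 16.0:
            hi *= 1.6
        if length_of(lo) > target or length_of(hi) < target:
            raise InfeasiblePlanError("widening route length not bracketable")
        return brentq(lambda lam: length_of(lam) - target, lo, hi, xtol=1e-6)

    lam_in = solve(lw + size[0])
    lam_out = solve(lw + size[1])
    inner, outer = make(lam_in), make(lam_out)
    boundary = _boundary_from_curves(inner, outer)

    poly = Polygon(boundary)
    if not poly.is_valid:
        poly = poly.buffer(0)
    # containment of the widened channel stretch (away from the tangent
    # ends, where boundary and channel touch by construction)
    core = (s2 >= s2[ia] + 0.5) & (s2 <= s2[ib] - 0.5)
    mid = pts2[core]
    if len(mid):
        inside = contains_xy(poly.buffer(0.01), mid[:, 0], mid[:, 1])
        if not np.all(inside):
            raise InfeasiblePlanError(
                "widening boundary does not enclose the channel window"
            )

    spec = WideningSpec(
        location=location,
        size=tuple(size),
        s_interval=(float(s2[ia]), float(s2[ib])),
        inner_curve=inner,
        outer_curve=outer,
        boundary2d=boundary,
        shortest_route=float(inner.arc_length()),
        longest_route=float(outer.arc_length()),
    )
    plan.widening = spec
    return spec


# ---------------------------------------------------------------------------
# contour-offset spiral fill
# ---------------------------------------------------------------------------


def _ring_coords(poly, ccw: bool) -> np.ndarray:
    p = orient(poly, 1.0 if ccw else -1.0)
    return np.asarray(p.exterior.coords)


def _resample_closed(coords: np.ndarray, spacing: float) -> np.ndarray:
    seg = np.linalg.norm(np.diff(coords, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] < 1e-9:
        return coords[:1]
    n = max(8, int(np.ceil(s[-1] / spacing)))
    si = np.linspace(0.0, s[-1], n + 1)
    return np.column_stack([np.interp(si, s, coords[:, k]) for k in range(coords.shape[1])])


def spiral_fill(
    boundary,
    tool_diameter: float = 1.2,
    overlap: float = 0.70,
    climb: bool = True,
    point_spacing: float = 0.1,
    feed: float = DEFAULT_FEED,
    spindle_rpm: float = DEFAULT_SPINDLE_RPM,
) -> ToolPath:
    """Pocket-fill a simple closed boundary by contour offsetting.

    Inward offsets of the boundary at step tool_diameter * (1 - overlap)
    (0.36 mm at the defaults) down to collapse, connected center-outward
    into one continuous spiral.  With ``climb`` the rings are traversed
    counter-clockwise (down-cutting for a clockwise-rotating spindle seen
    from the shank); waypoints are in the boundary plane (z = 0) with the
    tool axis +z.  Boundaries narrower than the tool collapse to a single
    center-line pass.
    """
    boundary = np.asarray(boundary, dtype=float)
    poly = Polygon(boundary[:, :2])
    if not poly.is_valid or poly.is_empty:
        poly = poly.buffer(0)
        if poly.is_empty:
            raise ValueError("boundary is not a simple closed curve")
    r_tool = tool_diameter / 2.0
    step = tool_diameter * (1.0 - overlap)

    rings: list[np.ndarray] = []
    current = poly.buffer(-r_tool)
    if current.is_empty:
        # narrower than the tool: single pass along the deepest inset
        lo, hi = 0.0, r_tool
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            if poly.buffer(-mid).is_empty:
                hi = mid
            else:
                lo = mid
        inset = poly.buffer(-lo * 0.999)
        bounds_extent = 0.0
        if not inset.is_empty:
            bx0, by0, bx1, by1 = inset.bounds
            bounds_extent = max(bx1 - bx0, by1 - by0)
        if inset.is_empty or bounds_extent < 0.05:
            c = poly.representative_point()
            pos = np.array([[c.x, c.y, 0.0]])
        else:
            geoms = getattr(inset, "geoms", [inset])
            coords = np.vstack([_ring_coords(g, climb) for g in geoms])
            pos = np.column_stack([coords, np.zeros(len(coords))])
        n = len(pos)
        return ToolPath(pos, np.tile([0.0, 0.0, 1.0], (n, 1)), np.full(n, "widening"),
                        np.full(n, feed), tool_diameter, spindle_rpm)

    last_nonempty = current
    while not current.is_empty:
        geoms = getattr(current, "geoms", [current])
        for g in geoms:
            rings.append(_resample_closed(_ring_coords(g, climb), point_spacing))
        last_nonempty = current
        current = current.buffer(-step)

    # center finish point of the innermost region
    center = last_nonempty.representative_point()
    pieces = [np.array([[center.x, center.y]])]
    # connect rings center-outward, rotating each ring start to the previous end
    for ring in reversed(rings):
        prev_end = pieces[-1][-1]
        closed = ring[:-1] if np.allclose(ring[0], ring[-1]) else ring
        i0 = int(np.argmin(np.linalg.norm(closed - prev_end, axis=1)))
        rolled = np.roll(closed, -i0, axis=0)
        pieces.append(np.vstack([rolled, rolled[:1]]))
    xy = np.vstack(pieces)
    pos = np.column_stack([xy, np.zeros(len(xy))])
    n = len(pos)
    path = ToolPath(pos, np.tile([0.0, 0.0, 1.0], (n, 1)), np.full(n, "widening"),
                    np.full(n, feed), tool_diameter, spindle_rpm)
    return path.densified(0.2)


def coverage_fraction(
    boundary,
    path_xy: np.ndarray,
    tool_radius: float,
    grid: float = 0.05,
) -> float:
    """Fraction of the tool-reachable pocket area within the tool radius of
    the path.

    The reachable region is the morphological opening of the boundary with
    the tool radius (a cylindrical cutter cannot reach sharper corners).
    """
    boundary = np.asarray(boundary, dtype=float)
    poly = Polygon(boundary[:, :2])
    if not poly.is_valid:
        poly = poly.buffer(0)
    reachable = poly.buffer(-tool_radius).buffer(tool_radius)
    if reachable.is_empty:
        return 1.0
    minx, miny, maxx, maxy = reachable.bounds
    xs = np.arange(minx, maxx + grid / 2, grid)
    ys = np.arange(miny, maxy + grid / 2, grid)
    xx, yy = np.meshgrid(xs, ys)
    inside = contains_xy(reachable, xx.ravel(), yy.ravel())
    pts = np.column_stack([xx.ravel()[inside], yy.ravel()[inside]])
    if len(pts) == 0:
        return 1.0
    path_xy = np.asarray(path_xy, dtype=float)[:, :2]
    dense = _resample_closed(path_xy, 0.01) if len(path_xy) > 1 else path_xy
    tree = cKDTree(dense)
    d, _ = tree.query(pts)
    covered = d <= tool_radius + 0.006  # polyline sampling slack
    return float(np.mean(covered))


# ---------------------------------------------------------------------------
# implant bed
# ---------------------------------------------------------------------------


def implant_bed_path(
    outline,
    ramp_origin,
    ramp_axis,
    ramp_length: float,
    bed_depth: float = 2.3,
    tool_diameter: float = 1.2,
    pin_holes=None,
    pin_extra_depth: float = 1.0,
    feed: float = DEFAULT_FEED,
    spindle_rpm: float = DEFAULT_SPINDLE_RPM,
) -> ToolPath:
    """Spiral-fill the fantail outline with a linear depth ramp.

    Depth is ``bed_depth`` at the channel-end side (``ramp_origin``) and
    ramps linearly to zero ``ramp_length`` away along ``ramp_axis``.
    Optional pin holes are appended as single plunge waypoints.
    """
    spiral = spiral_fill(outline, tool_diameter=tool_diameter, feed=feed,
                         spindle_rpm=spindle_rpm)
    xy = spiral.positions[:, :2]
    ramp_origin = np.asarray(ramp_origin, dtype=float)[:2]
    ramp_axis = np.asarray(ramp_axis, dtype=float)[:2]
    ramp_axis = ramp_axis / np.linalg.norm(ramp_axis)
    t = np.clip((xy - ramp_origin) @ ramp_axis / ramp_length, 0.0, 1.0)
    z = -bed_depth * (1.0 - t)
    pos = np.column_stack([xy, z])
    phases = np.full(len(pos), "bed")
    feeds = np.full(len(pos), feed)
    axes = np.tile([0.0, 0.0, 1.0], (len(pos), 1))
    if pin_holes is not None and len(pin_holes):
        ph = np.atleast_2d(np.asarray(pin_holes, dtype=float))[:, :2]
        tp = np.clip((ph - ramp_origin) @ ramp_axis / ramp_length, 0.0, 1.0)
        zp = -(bed_depth * (1.0 - tp) + pin_extra_depth)
        pos = np.vstack([pos, np.column_stack([ph, zp])])
        axes = np.vstack([axes, np.tile([0.0, 0.0, 1.0], (len(ph), 1))])
        phases = np.concatenate([phases, np.full(len(ph), "bed")])
        feeds = np.concatenate([feeds, np.full(len(ph), feed)])
    return ToolPath(pos, axes, phases, feeds, tool_diameter, spindle_rpm)


# ---------------------------------------------------------------------------
# full-procedure assembly
# ---------------------------------------------------------------------------


def _lift_planar_toolpath(plan: ChannelPlan, site, local_path: ToolPath, phase: str,
                          caster=None) -> ToolPath:
    """Embed a z=0 planar toolpath into the world at channel depth below the
    outer surface (z offsets of the planar path add to the depth)."""
    from .geometry import RayCaster
    from .planner import _interpolated_normals

    frame = plan.frame
    xy = local_path.positions[:, :2]
    base = frame.to_world(xy)
    caster = caster or RayCaster(site.outer)
    origins = base + 30.0 * frame.n
    dirs = np.broadcast_to(-frame.n, origins.shape)
    d, surf, _, faces = caster.cast_batch(origins, dirs, max_distance=80.0)
    if np.any(~np.isfinite(d)):
        raise InfeasiblePlanError(f"{phase} region leaves the meshed surface")
    normals = _interpolated_normals(site.outer, surf, faces)
    depth = plan.params.channel_depth - local_path.positions[:, 2]  # planar z<=0 deepens
    pos = surf - depth[:, None] * normals
    n = len(pos)
    return ToolPath(pos, normals, np.full(n, phase), local_path.feeds,
                    plan.params.tool_diameter, local_path.spindle_rpm)


def build_full_toolpath(
    plan: ChannelPlan,
    site,
    prep_diameter: float = 1.8,
    widening_location: str = "curve1",
    bed: bool = True,
    transition_tunnel_depth: float = 2.0,
    feed: float = DEFAULT_FEED,
    spindle_rpm: float = DEFAULT_SPINDLE_RPM,
) -> ToolPath:
    """Assemble the full procedure toolpath.

    Phases in milling order: access_prep, transition, channel, widening,
    bed.  The widening boundary is attached to the plan if not present.
    """
    from .geometry import RayCaster

    caster = RayCaster(site.outer)
    td = plan.params.tool_diameter
    prep = access_prep_path(site.trajectory, prep_diameter, tool_diameter=td,
                            feed=feed, spindle_rpm=spindle_rpm)

    # tunnel-to-surface transition: from inside the access hole up to the
    # channel bottom a short way along the channel
    a = site.trajectory.axis
    p0 = site.trajectory.entry + a * transition_tunnel_depth
    t0 = -a
    i1 = int(np.searchsorted(plan.s, 1.0))
    tangents = plan.tangents()
    p1, t1 = plan.bottom_points[i1], tangents[i1]
    trans_curve = transition_path(p0, t0, p1, t1, tool_diameter=td)
    _, tpts, _ = trans_curve.sample_by_arclength(0.1)
    n_t = len(tpts)
    trans = ToolPath(tpts, np.tile(plan.tool_axes[0], (n_t, 1)),
                     np.full(n_t, "transition"), np.full(n_t, feed), td, spindle_rpm)

    channel = ToolPath(plan.bottom_points, plan.tool_axes,
                       np.full(len(plan.s), "channel"), np.full(len(plan.s), feed),
                       td, spindle_rpm)

    pieces = [prep, trans, channel]
    if widening_location:
        spec = plan.widening or widening_boundary(plan, widening_location)
        specs = spec if isinstance(spec, list) else [spec]
        for sp in specs:
            local = spiral_fill(sp.boundary2d, tool_diameter=td, feed=feed,
                                spindle_rpm=spindle_rpm)
            pieces.append(_lift_planar_toolpath(plan, site, local, "widening", caster))

    if bed:
        tri2d = plan.frame.to_plane(site.fantail_points)
        outline = np.asarray(Polygon(tri2d).buffer(1.2, quad_segs=12).exterior.coords)
        exit2d = plan.frame.to_plane(site.lead_exit[None, :])[0]
        centroid = tri2d.mean(axis=0)
        ramp_axis = centroid - exit2d
        ramp_len = float(np.linalg.norm(ramp_axis)) * 2.0
        local_bed = implant_bed_path(outline, exit2d, ramp_axis, ramp_len,
                                     bed_depth=plan.params.channel_depth,
                                     tool_diameter=td, feed=feed, spindle_rpm=spindle_rpm)
        local_bed = ToolPath(local_bed.positions, local_bed.axes,
                             np.full(len(local_bed), "bed"), local_bed.feeds,
                             td, spindle_rpm)
        lifted = _lift_planar_toolpath(plan, site, local_bed, "bed", caster)
        pieces.append(lifted)

    return ToolPath.concat(pieces).densified(0.2)
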