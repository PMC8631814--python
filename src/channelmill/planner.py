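"""Electrode-lead channel planning.

The surface channel is a composite of three cubic Bezier segments forming an
S (or mirrored-S) with two curves.  Its ends are pinned exactly to the drill
trajectory entry and to the fantail lead-exit point.  Slider parameters fix
the two curve control points (distance along the entry-to-receiver direction
and a common perpendicular offset); the remaining degrees of freedom are set
by minimizing the maximum curvature subject to an arc-length equality
constraint, so the planned channel reaches the required lead length with the
gentlest possible turns.  The path is planned in a local 2-D parameterization
(projection along the mean surface normal) and lifted onto the outer mesh;
the depth profile keeps the channel bottom at a uniform depth below the local
surface along the tool axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .geometry import BezierSegment, CompositePath, RayCaster, SurfaceMesh
from .site import SurgicalSite

__all__ = [
    "PlanParams",
    "ChannelPlan",
    "SafetyReport",
    "InfeasiblePlanError",
    "required_channel_length",
    "plan_channel",
    "depth_profile",
    "safety_check",
]


class InfeasiblePlanError(RuntimeError):
    """The requested channel cannot be realized; the message names the
    binding constraint."""


def required_channel_length(
    lead_length: float, tunnel_length: float, insertion_offset: float = 0.0
) -> float:
    """Surface-channel length needed to stow the surplus electrode lead.

    ``insertion_offset`` is the insertion depth relative to full insertion
    (mm): 0 for the default full-insertion assumption, negative when the
    array sits shallower than planned (more lead remains on the surface).
    """
    if lead_length <= tunnel_length:
        raise InfeasiblePlanError("electrode lead shorter than the drill tunnel")
    length = lead_length - tunnel_length - insertion_offset
    if length <= 0:
        raise InfeasiblePlanError("no surplus lead remains on the surface")
    return float(length)


@dataclass
class PlanParams:
    """User-facing planning parameters (defaults are the clinical values)."""

    target_length: float
    shape: str = "S"                 # "S" or "mirrored-S"
    slider_d1: float | None = None   # distance of curve-1 control point from entry (mm)
    slider_d2: float | None = None   # distance of curve-2 control point from entry (mm)
    slider_offset: float | None = None  # perpendicular offset of both control points (mm)
    tilt_angle_deg: float = 0.0      # cutter tilt about the entry-to-fantail axis
    curvature_radius_min: float = 5.0
    channel_depth: float = 2.3
    tool_diameter: float = 1.2
    safety_margin: float = 1.0
    waypoint_spacing: float = 0.1

    def __post_init__(self) -> None:
        if self.shape not in ("S", "mirrored-S"):
            raise ValueError("shape must be 'S' or 'mirrored-S'")
        if self.curvature_radius_min <= 0:
            raise ValueError("curvature_radius_min must be positive")

    def to_dict(self) -> dict:
        return dict(self.__dict__)

    @classmethod
    def from_dict(cls, d: dict) -> "PlanParams":
        return cls(**d)


@dataclass
class PlaneFrame:
    """Local 2-D planning frame: origin at the entry, u toward the fantail,
    v perpendicular in-plane, n the mean outward surface normal."""

    origin: np.ndarray
    u: np.ndarray
    v: np.ndarray
    n: np.ndarray

    def to_world(self, xy: np.ndarray) -> np.ndarray:
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        return self.origin + xy[:, :1] * self.u + xy[:, 1:2] * self.v

    def to_plane(self, pts: np.ndarray) -> np.ndarray:
        rel = np.atleast_2d(np.asarray(pts, dtype=float)) - self.origin
        return np.column_stack([rel @ self.u, rel @ self.v])

    def to_dict(self) -> dict:
        return {k: getattr(self, k).tolist() for k in ("origin", "u", "v", "n")}

    @classmethod
    def from_dict(cls, d: dict) -> "PlaneFrame":
        return cls(*(np.asarray(d[k]) for k in ("origin", "u", "v", "n")))


@dataclass
class SafetyReport:
    entries: list            # (structure name, closest distance to swept surface, intervals)
    total_violating_length: float
    margin: float

    @property
    def passed(self) -> bool:
        # a structure exactly at the margin passes: violation is strict
        return all(d >= self.margin for _, d, _ in self.entries)


@dataclass
class ChannelPlan:
    """Planned channel: planar spline, lifted surface path, depth profile."""

    frame: PlaneFrame
    path2d: CompositePath            # planar spline, coordinates (u, v, 0)
    s: np.ndarray                    # arc length along the surface path (mm)
    surface_points: np.ndarray       # (n, 3) waypoints on the outer surface
    bottom_points: np.ndarray        # (n, 3) waypoints at channel depth
    tool_axes: np.ndarray            # (n, 3) unit tool axes (out of the bone)
    params: PlanParams
    flags: dict = field(default_factory=dict)
    thin_intervals: list = field(default_factory=list)
    widening: object | None = None   # WideningSpec, attached by milling_path

    @property
    def length(self) -> float:
        return float(self.s[-1])

    @property
    def entry(self) -> np.ndarray:
        return self.surface_points[0].copy()

    @property
    def lead_exit(self) -> np.ndarray:
        return self.surface_points[-1].copy()

    def tangents(self) -> np.ndarray:
        t = np.gradient(self.surface_points, self.s, axis=0)
        n = np.linalg.norm(t, axis=1, keepdims=True)
        n[n == 0] = 1.0
        return t / n

    def transformed(self, t) -> "ChannelPlan":
        """The same plan expressed in a rigidly moved frame (the planar
        spline is frame-local and unchanged)."""
        frame = PlaneFrame(
            origin=t.apply(self.frame.origin),
            u=t.apply_vector(self.frame.u),
            v=t.apply_vector(self.frame.v),
            n=t.apply_vector(self.frame.n),
        )
        return ChannelPlan(
            frame=frame,
            path2d=self.path2d,
            s=self.s.copy(),
            surface_points=t.apply(self.surface_points),
            bottom_points=t.apply(self.bottom_points),
            tool_axes=t.apply_vector(self.tool_axes),
            params=self.params,
            flags=dict(self.flags),
            thin_intervals=list(self.thin_intervals),
            widening=self.widening,
        )


# ---------------------------------------------------------------------------
# spline construction and curvature-optimized completion
# ---------------------------------------------------------------------------


def _build_path2d(nodes: np.ndarray, angles: np.ndarray, mags: np.ndarray) -> CompositePath:
    """Three G1 cubic segments through 4 nodes with shared tangent angles."""
    dirs = np.column_stack([np.cos(angles), np.sin(angles), np.zeros(4)])
    nodes3 = np.column_stack([nodes, np.zeros(4)])
    segs = []
    for k in range(3):
        p0 = nodes3[k]
        p3 = nodes3[k + 1]
        p1 = p0 + mags[k, 0] * dirs[k]
        p2 = p3 - mags[k, 1] * dirs[k + 1]
        segs.append(BezierSegment(np.array([p0, p1, p2, p3])))
    return CompositePath(segs)


def _poly_length(path: CompositePath, n: int = 64) -> float:
    u = np.linspace(0.0, 3.0, 3 * n)
    pts = path.evaluate(u)
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def _soft_max_curvature(path: CompositePath, n: int = 40, p: float = 16.0) -> float:
    t = np.linspace(0.02, 0.98, n)
    k = np.concatenate([seg.curvature(t) for seg in path.segments])
    return float((np.mean(k**p)) ** (1.0 / p))


def _scale_offsets(path: CompositePath, alpha: float) -> CompositePath:
    segs = []
    for seg in path.segments:
        cp = seg.control_points.copy()
        cp[:, 1] *= alpha
        segs.append(BezierSegment(cp))
    return CompositePath(segs)


def _biarc_init(dist: float, target: float, sign: float):
    """Biarc S initialization: two mirrored circular arcs of total length
    exactly ``target`` joined with point symmetry at the midpoint.

    Each arc has chord dist/2 and length target/2; the arc half-angle theta
    solves sin(theta)/theta = dist/target and the radius target/(4*theta) is
    the minimax-curvature radius of any symmetric two-arc S, which makes
    this a near-optimal start for the polish step.
    """
    from scipy.optimize import brentq

    ratio = dist / target
    theta = brentq(lambda th: np.sin(th) / th - ratio, 1e-9, np.pi - 1e-9)
    radius = target / (4.0 * theta)

    def arc1_point(phi):
        # first arc: start (0, 0), tangent angle theta - phi, phi in [0, 2*theta]
        x = radius * (np.sin(theta) - np.sin(theta - phi))
        y = radius * (np.cos(theta - phi) - np.cos(theta))
        return np.array([x, y])

    # split the 4*theta of total turning evenly over the three cubics: the
    # internal nodes sit at 2/3 of arc 1 and (symmetrically) 1/3 of arc 2
    n1 = arc1_point(4.0 * theta / 3.0)
    n2 = np.array([dist - n1[0], -n1[1]])
    nodes = np.array([[0.0, 0.0], n1, n2, [dist, 0.0]])
    nodes[:, 1] *= sign
    angles = sign * np.array([theta, -theta / 3.0, -theta / 3.0, theta])
    m_outer = (4.0 / 3.0) * np.tan(theta / 3.0) * radius
    m_mid = (8.0 / 3.0) * np.tan(theta / 6.0) * radius
    mags = np.clip(
        np.array([[m_outer, m_outer], [m_mid, m_mid], [m_outer, m_outer]]), 0.3, None
    )

    # equalize the curvature peaks with a short coordinate search over the
    # shared outer and middle tangent magnitudes (symmetry is preserved)
    from scipy.optimize import minimize_scalar

    def kmax(mo, mm):
        m = np.array([[mo, mo], [mm, mm], [mo, mo]])
        return _build_path2d(nodes, angles, m).max_curvature(120)

    mo, mm = float(mags[0, 0]), float(mags[1, 0])
    for _ in range(3):
        r = minimize_scalar(lambda x: kmax(mo, x), bracket=None,
                            bounds=(0.3 * mm, 3.0 * mm), method="bounded",
                            options={"xatol": 1e-3})
        mm = float(r.x)
        r = minimize_scalar(lambda x: kmax(x, mm),
                            bounds=(0.3 * mo, 3.0 * mo), method="bounded",
                            options={"xatol": 1e-3})
        mo = float(r.x)
    mags = np.array([[mo, mo], [mm, mm], [mo, mo]])
    return nodes, angles, mags, theta


def _optimize_planar(
    dist: float,
    target: float,
    sign: float,
    sliders: tuple | None,
) -> CompositePath:
    nodes0, angles0, mags0, half_angle = _biarc_init(dist, target, sign)
    if sliders is not None:
        d1, d2, off = sliders
        nodes0 = np.array([[0.0, 0.0], [d1, sign * off], [d2, -sign * off], [dist, 0.0]])
        chords = np.linalg.norm(np.diff(nodes0, axis=0), axis=1)
        mags0 = np.column_stack([chords / 3.0, chords / 3.0])
        free_nodes = False
    else:
        free_nodes = True

    def unpack(theta):
        angles = theta[:4]
        mags = np.exp(theta[4:10]).reshape(3, 2)
        if free_nodes:
            d1, d2, off = theta[10], theta[11], theta[12]
            nodes = np.array(
                [[0.0, 0.0], [d1, sign * off], [d2, -sign * off], [dist, 0.0]]
            )
        else:
            nodes = nodes0
        return nodes, angles, mags

    def build(theta):
        return _build_path2d(*unpack(theta))

    theta0 = np.concatenate(
        [
            angles0,
            np.log(np.clip(mags0.ravel(), 1e-3, None)),
            [nodes0[1, 0], nodes0[2, 0], abs(nodes0[1, 1])] if free_nodes else [],
        ]
    )

    def objective(theta):
        return _soft_max_curvature(build(theta))

    def length_constraint(theta):
        return _poly_length(build(theta)) - target

    ang_bound = float(min(half_angle + 0.5, 3.0))
    bounds = [(-ang_bound, ang_bound)] * 4 + [(np.log(0.3), np.log(max(dist, 1.0)))] * 6
    if free_nodes:
        bounds += [
            (0.1 * dist, 0.6 * dist),
            (0.4 * dist, 0.9 * dist),
            (0.0, max(dist, target)),
        ]

    def finish(path):
        # exact arc-length correction: scale the perpendicular offsets (a
        # linear map, so G1 continuity survives) to the quadrature length
        lo, hi = 0.0, 4.0
        for _ in range(60):
            alpha = 0.5 * (lo + hi)
            if _scale_offsets(path, alpha).arc_length() < target:
                lo = alpha
            else:
                hi = alpha
        return _scale_offsets(path, 0.5 * (lo + hi))

    candidates = [finish(build(theta0))]
    try:
        res = minimize(
            objective,
            theta0,
            method="SLSQP",
            bounds=bounds,
            constraints=[{"type": "eq", "fun": length_constraint}],
            options={"maxiter": 80, "ftol": 1e-8},
        )
        if res.success and abs(_poly_length(build(res.x)) - target) < 0.5:
            candidates.append(finish(build(res.x)))
    except (ValueError, FloatingPointError):
        pass
    return min(candidates, key=lambda p: p.max_curvature(100))


# ---------------------------------------------------------------------------
# lifting, depth profile, safety
# ---------------------------------------------------------------------------


def _local_frame(site: SurgicalSite) -> PlaneFrame:
    a = site.trajectory.entry
    b = site.lead_exit
    vn = site.outer.vertex_normals
    verts = site.outer.vertices
    n = np.zeros(3)
    for p in (a, b):
        d = np.linalg.norm(verts - p, axis=1)
        n += vn[d < 4.0].mean(axis=0) if (d < 4.0).any() else vn[np.argmin(d)]
    n /= np.linalg.norm(n)
    ab = b - a
    u = ab - np.dot(ab, n) * n
    un = np.linalg.norm(u)
    if un < 1e-9:
        raise InfeasiblePlanError("entry and lead exit coincide in the surface plane")
    u /= un
    v = np.cross(n, u)
    return PlaneFrame(origin=a.copy(), u=u, v=v, n=n)


def _lift_to_surface(frame: PlaneFrame, xy: np.ndarray, outer: SurfaceMesh) -> np.ndarray:
    base = frame.to_world(xy)
    origins = base + 30.0 * frame.n
    dirs = np.broadcast_to(-frame.n, origins.shape)
    caster = RayCaster(outer)
    d, pts, _, faces = caster.cast_batch(origins, dirs, max_distance=80.0)
    if np.any(~np.isfinite(d)):
        raise InfeasiblePlanError(
            "channel path leaves the meshed surface (binding constraint: exposed area)"
        )
    return pts, faces, caster


def plan_channel(site: SurgicalSite, params: PlanParams) -> ChannelPlan:
    """Plan the channel on a site; see the module docstring for the model.

    Postconditions: the surface path starts exactly at the trajectory entry
    and ends exactly at the fantail lead-exit; the achieved arc length is
    within 0.5 mm of ``params.target_length``; a curvature warning flag is
    set when the minimum curvature radius falls below the configured limit.
    """
    frame = _local_frame(site)
    a, b = site.trajectory.entry, site.lead_exit
    straight = float(np.linalg.norm(b - a))
    if params.target_length <= straight:
        raise InfeasiblePlanError(
            f"target length {params.target_length:.1f} mm not greater than the "
            f"straight distance {straight:.1f} mm"
        )
    dist = float((b - a) @ frame.u)
    sign = 1.0 if params.shape == "S" else -1.0
    sliders = None
    if params.slider_d1 is not None and params.slider_d2 is not None and params.slider_offset is not None:
        sliders = (params.slider_d1, params.slider_d2, params.slider_offset)

    # iterate planar target so the lifted (surface) length hits the target
    planar_target = params.target_length
    for _ in range(3):
        path2d = _optimize_planar(dist, planar_target, sign, sliders)
        s2, xy3, _ = path2d.sample_by_arclength(params.waypoint_spacing)
        surf, faces, caster = _lift_to_surface(frame, xy3[:, :2], site.outer)
        surf[0], surf[-1] = a, b
        seglen = np.linalg.norm(np.diff(surf, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seglen)])
        achieved = float(s[-1])
        if abs(achieved - params.target_length) <= 0.2:
            break
        planar_target *= params.target_length / achieved

    if abs(achieved - params.target_length) > 0.5:
        raise InfeasiblePlanError(
            f"could not meet target length (achieved {achieved:.2f} mm, binding "
            "constraint: length within the exposed surface)"
        )

    # curvature of the planar design path
    kmax = path2d.max_curvature(samples_per_segment=400)
    min_radius = float("inf") if kmax < 1e-12 else 1.0 / kmax

    # planar self-intersection check with tool-width inflation
    from shapely.geometry import LineString

    line = LineString(np.asarray(path2d.evaluate(np.linspace(0, 3, 400))[:, :2]))
    self_intersecting = not line.is_simple

    # bounds check against the meshed area
    vmin = site.outer.vertices.min(axis=0)
    vmax = site.outer.vertices.max(axis=0)
    if np.any(surf[:, :2] < vmin[:2] - 1e-6) or np.any(surf[:, :2] > vmax[:2] + 1e-6):
        raise InfeasiblePlanError("planned path leaves the meshed surface extent")

    plan = ChannelPlan(
        frame=frame,
        path2d=path2d,
        s=s,
        surface_points=surf,
        bottom_points=np.empty_like(surf),
        tool_axes=np.empty_like(surf),
        params=params,
        flags={
            "curvature_warning": bool(min_radius < params.curvature_radius_min),
            "min_curvature_radius": min_radius,
            "self_intersecting": bool(self_intersecting),
            "achieved_length": achieved,
        },
    )
    depth_profile(plan, site, caster=caster, faces=faces)
    return plan


def _interpolated_normals(mesh: SurfaceMesh, points: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Barycentric interpolation of vertex normals at on-surface points."""
    vn = mesh.vertex_normals
    tris = mesh.faces[faces]
    v = mesh.vertices[tris]  # (n, 3, 3)
    e1 = v[:, 1] - v[:, 0]
    e2 = v[:, 2] - v[:, 0]
    rel = points - v[:, 0]
    d11 = np.einsum("ij,ij->i", e1, e1)
    d12 = np.einsum("ij,ij->i", e1, e2)
    d22 = np.einsum("ij,ij->i", e2, e2)
    r1 = np.einsum("ij,ij->i", rel, e1)
    r2 = np.einsum("ij,ij->i", rel, e2)
    det = d11 * d22 - d12**2
    det[det == 0] = 1.0
    w1 = (d22 * r1 - d12 * r2) / det
    w2 = (d11 * r2 - d12 * r1) / det
    w0 = 1.0 - w1 - w2
    n = w0[:, None] * vn[tris[:, 0]] + w1[:, None] * vn[tris[:, 1]] + w2[:, None] * vn[tris[:, 2]]
    return n / np.linalg.norm(n, axis=1, keepdims=True)


def _rodrigues(vectors: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    c, sfac = np.cos(angle), np.sin(angle)
    return (
        vectors * c
        + np.cross(axis, vectors) * sfac
        + axis[None, :] * (vectors @ axis)[:, None] * (1 - c)
    )


def depth_profile(plan: ChannelPlan, site: SurgicalSite, caster=None, faces=None) -> ChannelPlan:
    """Fill in the bottom path and per-waypoint tool axes.

    The tool axis at each waypoint is the local outer-surface normal rotated
    by the tilt angle about the entry-to-fantail axis; every bottom waypoint
    lies ``channel_depth`` below the surface waypoint along that axis.
    Waypoint intervals where the local bone thickness is below
    depth + margin are recorded in ``plan.thin_intervals``.
    """
    surf = plan.surface_points
    if caster is None or faces is None:
        caster = RayCaster(site.outer)
        origins = surf + 30.0 * plan.frame.n
        dirs = np.broadcast_to(-plan.frame.n, origins.shape)
        _, _, _, faces = caster.cast_batch(origins, dirs, max_distance=80.0)
        faces = np.where(faces < 0, 0, faces)
    normals = _interpolated_normals(site.outer, surf, faces)
    tilt = np.deg2rad(plan.params.tilt_angle_deg)
    if abs(tilt) > 1e-12:
        axis_ab = site.lead_exit - site.trajectory.entry
        normals = _rodrigues(normals, axis_ab, tilt)
        normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    plan.tool_axes = normals
    plan.bottom_points = surf - plan.params.channel_depth * normals

    # thin-bone flagging along the tool axis
    inner_caster = RayCaster(site.inner)
    d, _, _, _ = inner_caster.cast_batch(surf, -normals, max_distance=60.0)
    need = plan.params.channel_depth + plan.params.safety_margin
    thin = np.isfinite(d) & (d < need)
    plan.thin_intervals = _mask_to_intervals(plan.s, thin)
    plan.flags["thin_bone"] = bool(thin.any())
    return plan


def _mask_to_intervals(s: np.ndarray, mask: np.ndarray) -> list:
    out = []
    start = None
    for i, m in enumerate(mask):
        if m and start is None:
            start = s[i]
        elif not m and start is not None:
            out.append((float(start), float(s[i - 1])))
            start = None
    if start is not None:
        out.append((float(start), float(s[-1])))
    return out


def safety_check(plan: ChannelPlan, site: SurgicalSite) -> SafetyReport:
    """Distance from the margin-inflated swept tool volume to each forbidden
    structure.

    The swept volume is approximated by spheres of the tool radius centered
    on the dense surface and bottom waypoints.  A structure passes when its
    closest distance to the swept surface is strictly greater than the
    margin (a tie at exactly the margin passes).
    """
    r_tool = plan.params.tool_diameter / 2.0
    margin = plan.params.safety_margin
    samples = np.vstack([plan.surface_points, plan.bottom_points])
    s_both = np.concatenate([plan.s, plan.s])
    from scipy.spatial import cKDTree

    tree = cKDTree(samples)
    entries = []
    total_mask = np.zeros(len(plan.s), dtype=bool)
    for structure in site.forbidden:
        d, idx = tree.query(structure.points)
        d_surface = d - r_tool - structure.radius
        closest = float(d_surface.min())
        # violating arc-length intervals: waypoints whose sphere comes within
        # margin of the structure
        dw, _ = cKDTree(structure.points).query(plan.surface_points)
        dwb, _ = cKDTree(structure.points).query(plan.bottom_points)
        viol = (np.minimum(dw, dwb) - r_tool - structure.radius) < margin
        intervals = _mask_to_intervals(plan.s, viol)
        total_mask |= viol
        entries.append((structure.name, closest, intervals))
    spacing = np.diff(plan.s, prepend=plan.s[0])
    total = float(spacing[total_mask].sum())
    return SafetyReport(entries=entries, total_violating_length=total, margin=margin)
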