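"""Postoperative channel metrology.

Mirrors a micro-CT analysis pipeline: co-register the postoperative surface
via the fiducial screws, estimate the resulting channel center line starting
from the planned one, sample cross sections perpendicular to the path with a
radial ray fan, classify the hit points into the five wall groups (top left,
left, bottom, right, top right) from their normals and positions, and reduce
each section to the four metrics:

* LD — signed lateral displacement of the resulting center line versus the
  plan; negative means displaced to the LEFT of the milling direction.
* DD — signed depth displacement; negative means DEEPER than planned.
* CW — channel width, right-wall minus left-wall lateral position.
* CD — channel depth, mean top-left/top-right surface height minus bottom.

Cross sections with too few hits in any essential wall group (air-cell
voids) are flagged missing and excluded from every statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .geometry import RayCaster, RigidTransform, SurfaceMesh, rigid_register
from .planner import ChannelPlan
from .riskstats import summarize

__all__ = [
    "CrossSection",
    "ChannelMeasurement",
    "MeasurementError",
    "coregister",
    "estimate_centerline",
    "sample_cross_sections",
    "classify_walls",
    "measure",
    "measure_channel",
    "margin_violation_length",
]

WALL_GROUPS = ("top_left", "left", "bottom", "right", "top_right")

_COS45 = np.cos(np.deg2rad(45.0))


class MeasurementError(RuntimeError):
    pass


def coregister(plan_fiducials, postop_fiducials) -> RigidTransform:
    """Paired-point rigid co-registration of the postoperative frame onto
    the planning frame via the fiducial screws (>= 3 points)."""
    transform, _ = rigid_register(np.asarray(postop_fiducials), np.asarray(plan_fiducials))
    return transform


@dataclass
class SectionFrame:
    """Planned local frame of one cross section."""

    s: float
    surface: np.ndarray    # planned surface point
    bottom: np.ndarray     # planned bottom point
    tangent: np.ndarray
    right: np.ndarray      # e1: lateral, positive to the right of milling
    up: np.ndarray         # e2: along the planned tool axis, out of the bone


@dataclass
class CrossSection:
    frame: SectionFrame
    points: np.ndarray          # (k, 3) hit points
    normals: np.ndarray         # (k, 3) hit normals, oriented toward the fan origin
    labels: np.ndarray          # (k,) strings from WALL_GROUPS, or "" if unclassified
    missing: bool = True

    def group(self, name: str) -> np.ndarray:
        return self.points[self.labels == name]

    def lateral(self, name: str) -> np.ndarray:
        pts = self.group(name)
        return (pts - self.frame.surface) @ self.frame.right

    def height(self, name: str) -> np.ndarray:
        pts = self.group(name)
        return (pts - self.frame.surface) @ self.frame.up


@dataclass
class ChannelMeasurement:
    s: np.ndarray
    ld: np.ndarray
    dd: np.ndarray
    cw: np.ndarray
    cd: np.ndarray
    missing: np.ndarray
    centerline: np.ndarray
    spacing: float
    tool_diameter: float
    channel_depth: float
    summary: dict = field(default_factory=dict)
    widening: dict | None = None

    @property
    def cwe(self) -> np.ndarray:
        return self.cw - self.tool_diameter

    @property
    def cde(self) -> np.ndarray:
        return self.cd - self.channel_depth

    @property
    def measured_length(self) -> float:
        return float(np.count_nonzero(~self.missing) * self.spacing)

    @property
    def missing_fraction(self) -> float:
        return float(np.mean(self.missing)) if len(self.missing) else 1.0

    def summarize(self, independence_spacing: float = 1.2) -> dict:
        """Per-metric summary in the shape of the study's endpoint table."""
        out = {}
        ok = ~self.missing
        for name, series in (
            ("lateral_displacement", self.ld),
            ("depth_displacement", self.dd),
            ("channel_width_error", self.cwe),
            ("channel_depth_error", self.cde),
        ):
            vals = series[ok]
            out[name] = summarize(vals, spacing=self.spacing,
                                  independence_spacing=independence_spacing)
        out["measured_length_mm"] = self.measured_length
        out["missing_fraction"] = self.missing_fraction
        self.summary = out
        return out


# ---------------------------------------------------------------------------
# section frames and sampling
# ---------------------------------------------------------------------------


def _section_frames(plan: ChannelPlan, s_values: np.ndarray) -> list:
    s = plan.s
    tangents = plan.tangents()

    def interp_rows(arr):
        return np.column_stack([np.interp(s_values, s, arr[:, k]) for k in range(3)])

    surf = interp_rows(plan.surface_points)
    bott = interp_rows(plan.bottom_points)
    axes = interp_rows(plan.tool_axes)
    tang = interp_rows(tangents)
    frames = []
    for i, sv in enumerate(s_values):
        t = tang[i] / np.linalg.norm(tang[i])
        a = axes[i] / np.linalg.norm(axes[i])
        right = np.cross(t, a)
        right /= np.linalg.norm(right)
        up = np.cross(right, t)  # exactly perpendicular to the tangent
        frames.append(SectionFrame(float(sv), surf[i], bott[i], t, right, up))
    return frames


def sample_cross_sections(
    postop: SurfaceMesh,
    plan: ChannelPlan,
    s_values: np.ndarray,
    lateral_offsets: np.ndarray | None = None,
    spacing: float = 0.1,
    rays: int = 360,
    max_distance: float | None = None,
    origin_height: float = 0.8,
    caster: RayCaster | None = None,
    min_hits: int = 2,
) -> list:
    """Radial ray-fan sampling of the channel walls.

    At each arc length a fan of ``rays`` directions in the plane exactly
    perpendicular to the local path tangent is cast from a point
    ``origin_height`` above the planned surface (optionally recentered
    laterally by ``lateral_offsets``); hits beyond ``max_distance`` count as
    misses.  Sections whose essential wall groups have fewer than
    ``min_hits`` points are flagged missing.
    """
    caster = caster or RayCaster(postop)
    if max_distance is None:
        # must reach the channel bottom from the fan origin with slack for
        # depth errors, and the adjacent top surface out to the rim
        max_distance = plan.params.channel_depth + origin_height + 1.5
    frames = _section_frames(plan, np.asarray(s_values, dtype=float))
    if lateral_offsets is None:
        lateral_offsets = np.zeros(len(frames))
    th = np.linspace(0.0, 2 * np.pi, rays, endpoint=False)
    cos_t, sin_t = np.cos(th), np.sin(th)
    origins = np.array(
        [
            f.surface + off * f.right + origin_height * f.up
            for f, off in zip(frames, lateral_offsets)
        ]
    )
    sections = []
    # prune triangles per window of consecutive sections (one KD-tree ball
    # query per window, then an exact fan-plane slab test per section)
    window = 20
    tri_r = caster.triangle_radius
    for w0 in range(0, len(frames), window):
        w1 = min(len(frames), w0 + window)
        center = origins[w0:w1].mean(axis=0)
        span = float(np.max(np.linalg.norm(origins[w0:w1] - center, axis=1)))
        cand = caster.candidates_near(center, span + max_distance + tri_r)
        cand_c = caster.triangle_centroids[cand] if len(cand) else None
        cand_r = caster.triangle_radii[cand] if len(cand) else None
        for i in range(w0, w1):
            frame = frames[i]
            origin = origins[i]
            if cand_c is not None and len(cand):
                slab = np.abs((cand_c - origin) @ frame.tangent) <= cand_r + 1e-9
                local = cand[slab]
            else:
                local = cand
            dirs = cos_t[:, None] * frame.right + sin_t[:, None] * frame.up
            d, pts, nrm, _ = caster.cast_batch(
                np.broadcast_to(origin, dirs.shape).copy(), dirs,
                max_distance=max_distance, candidates=local,
            )
            hit = np.isfinite(d)
            pts, nrm = pts[hit], nrm[hit]
            # orient normals toward the fan origin (into the channel air)
            flip = np.einsum("ij,ij->i", origin - pts, nrm) < 0
            nrm[flip] *= -1.0
            section = CrossSection(frame, pts, nrm, np.full(len(pts), "", dtype="<U10"))
            classify_walls(section, plan, min_hits=min_hits)
            sections.append(section)
    return sections


def classify_walls(section: CrossSection, plan: ChannelPlan, min_hits: int = 2) -> CrossSection:
    """Label hit points as top_left / left / bottom / right / top_right.

    Up-facing normals (within 45 degrees of the planned tool axis) split
    into bottom versus adjacent top surface by height; side-facing normals
    split left/right by the sign of their lateral component.  A section
    whose essential groups are underpopulated, or whose walls scatter wider
    than a gap-free channel allows, is marked missing.
    """
    f = section.frame
    depth = plan.params.channel_depth
    r_tool = plan.params.tool_diameter / 2.0
    if len(section.points) == 0:
        section.missing = True
        return section
    rel = section.points - f.surface
    lam = rel @ f.right
    h = rel @ f.up
    n_up = section.normals @ f.up
    n_lat = section.normals @ f.right
    labels = np.full(len(lam), "", dtype="<U10")

    upfacing = n_up >= _COS45
    bottom = upfacing & (h < -depth / 2.0) & (np.abs(lam) < r_tool + 1.3)
    top = upfacing & (h >= -depth / 2.0) & (np.abs(lam) >= 0.5 * r_tool) & (np.abs(lam) <= 2.5)
    side = (~upfacing) & (np.abs(n_up) < _COS45) & (h > -depth - 1.3) & (np.abs(lam) < r_tool + 1.3)
    labels[bottom] = "bottom"
    labels[top & (lam < 0)] = "top_left"
    labels[top & (lam >= 0)] = "top_right"
    labels[side & (n_lat > 0)] = "left"
    labels[side & (n_lat <= 0)] = "right"
    section.labels = labels

    def spread(v):
        return float(v.max() - v.min()) if len(v) else 0.0

    counts = {g: int(np.count_nonzero(labels == g)) for g in WALL_GROUPS}
    essential_ok = (
        counts["bottom"] >= min_hits
        and counts["left"] >= min_hits
        and counts["right"] >= min_hits
        and counts["top_left"] >= 1
        and counts["top_right"] >= 1
    )
    # walls of a gap-free channel are tight planes; scattered hits betray a
    # ray fan escaping through an air-cell void
    tight = (
        spread(lam[labels == "left"]) <= 0.45
        and spread(lam[labels == "right"]) <= 0.45
        and spread(h[labels == "bottom"]) <= 0.45
    )
    section.missing = not (essential_ok and tight)
    return section


def estimate_centerline(
    postop: SurfaceMesh,
    plan: ChannelPlan,
    spacing: float = 0.1,
    rays: int = 360,
    s_values: np.ndarray | None = None,
    caster: RayCaster | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Estimate the resulting center line (mid-point between the left and
    right wall on the bottom), starting from the planned center line.

    Returns (s_values, centerline points, missing mask); missing stretches
    are linearly interpolated from their neighbors.
    """
    if s_values is None:
        s_values = np.arange(0.0, plan.length + spacing / 2, spacing)
    caster = caster or RayCaster(postop)
    sections = sample_cross_sections(postop, plan, s_values, spacing=spacing,
                                     rays=rays, caster=caster)
    offsets = np.zeros(len(sections))
    heights = np.full(len(sections), -plan.params.channel_depth)
    missing = np.ones(len(sections), dtype=bool)
    for i, sec in enumerate(sections):
        if sec.missing:
            continue
        lam_l = sec.lateral("left").mean()
        lam_r = sec.lateral("right").mean()
        offsets[i] = 0.5 * (lam_l + lam_r)
        heights[i] = sec.height("bottom").mean()
        missing[i] = False
    if missing.all():
        raise MeasurementError("channel not found near the planned center line")
    ok = ~missing
    idx = np.arange(len(sections))
    offsets[missing] = np.interp(idx[missing], idx[ok], offsets[ok])
    heights[missing] = np.interp(idx[missing], idx[ok], heights[ok])
    frames = _section_frames(plan, np.asarray(s_values, dtype=float))
    center = np.array(
        [f.surface + o * f.right + h * f.up for f, o, h in zip(frames, offsets, heights)]
    )
    return np.asarray(s_values, dtype=float), center, missing, offsets


def measure(sections: list, plan: ChannelPlan, spacing: float) -> ChannelMeasurement:
    """Reduce classified cross sections to the per-arc-length metric series."""
    depth = plan.params.channel_depth
    n = len(sections)
    ld = np.full(n, np.nan)
    dd = np.full(n, np.nan)
    cw = np.full(n, np.nan)
    cd = np.full(n, np.nan)
    missing = np.ones(n, dtype=bool)
    center = np.zeros((n, 3))
    s_out = np.array([sec.frame.s for sec in sections])
    for i, sec in enumerate(sections):
        center[i] = sec.frame.bottom
        if sec.missing:
            continue
        lam_l = sec.lateral("left").mean()
        lam_r = sec.lateral("right").mean()
        h_bottom = sec.height("bottom").mean()
        h_top = 0.5 * (sec.height("top_left").mean() + sec.height("top_right").mean())
        ld[i] = 0.5 * (lam_l + lam_r)          # negative = left of milling direction
        dd[i] = h_bottom + depth               # negative = deeper than planned
        cw[i] = lam_r - lam_l
        cd[i] = h_top - h_bottom
        center[i] = sec.frame.surface + ld[i] * sec.frame.right + h_bottom * sec.frame.up
        missing[i] = False
    meas = ChannelMeasurement(
        s=s_out, ld=ld, dd=dd, cw=cw, cd=cd, missing=missing, centerline=center,
        spacing=spacing, tool_diameter=plan.params.tool_diameter, channel_depth=depth,
    )
    meas.summarize()
    return meas


def measure_channel(
    postop: SurfaceMesh,
    plan: ChannelPlan,
    spacing: float = 0.1,
    rays: int = 360,
    s_range: tuple | None = None,
    exclude_intervals: list | None = None,
) -> ChannelMeasurement:
    """Full measurement pass: centerline estimation, recentered sampling,
    classification and metric reduction.

    ``s_range`` restricts the measured arc-length window (the access-point
    preparation and the implant bed disturb the channel geometry near its
    ends); ``exclude_intervals`` removes further windows (the widening is
    analyzed separately against its own boundary).
    """
    s_lo, s_hi = s_range if s_range else (0.0, plan.length)
    s_values = np.arange(s_lo, s_hi + spacing / 2, spacing)
    if exclude_intervals:
        keep = np.ones(len(s_values), dtype=bool)
        for a, b in exclude_intervals:
            keep &= ~((s_values >= a) & (s_values <= b))
        s_values = s_values[keep]
    if len(s_values) == 0:
        raise MeasurementError("empty measurement window")
    caster = RayCaster(postop)
    sv, _, _, offsets = estimate_centerline(
        postop, plan, spacing=spacing, rays=rays, s_values=s_values, caster=caster
    )
    sections = sample_cross_sections(
        postop, plan, sv, lateral_offsets=offsets, spacing=spacing, rays=rays,
        caster=caster,
    )
    return measure(sections, plan, spacing)


def margin_violation_length(meas: ChannelMeasurement, margin: float = 1.0) -> float:
    """Total measured arc length where the resulting channel lies outside
    the safety margin (missing sections excluded)."""
    ok = ~meas.missing
    if not ok.any():
        warnings.warn("all sections missing; margin violation length is 0 by convention")
        return 0.0
    viol = ok & (np.maximum(np.abs(meas.ld), np.abs(meas.dd)) > margin)
    return float(np.count_nonzero(viol) * meas.spacing)
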