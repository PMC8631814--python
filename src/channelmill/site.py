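"""Virtualization of the surgical site and synthetic anatomy generation.

The planning substrate is a curved, slab-like bone surface.  Real sites are
virtualized from recorded points (fantail triangle, tripod legs, incision
trace, fiducial screws); for testing and study runs a synthetic generator
emulates a temporal-bone-like slab: a gently domed outer surface with smooth
bumps, an inner (dura-side) surface at spatially varying thickness, spherical
air-cell voids in the interior, a fiducial constellation around the drill
trajectory entry, and the fantail / tripod / incision structures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .geometry import (
    DegenerateConfigurationError,
    RayCaster,
    RigidTransform,
    SurfaceMesh,
    Trajectory,
)

__all__ = [
    "Pose",
    "Polyline",
    "ForbiddenStructure",
    "SurgicalSite",
    "SynthParams",
    "fantail_pose_from_points",
    "tripod_pose_from_points",
    "virtualize_incision",
    "thickness_map",
    "synth_temporal_bone",
    "FANTAIL_TEMPLATE",
]

# Canonical fantail triangle (mm) in the pose frame: lead-exit at the origin,
# the flared end toward +x.  fantail_pose_from_points maps this template to
# the identity pose.
FANTAIL_TEMPLATE = np.array(
    [
        [0.0, 0.0, 0.0],   # lead-exit point (pose origin)
        [6.0, -4.0, 0.0],  # second recorded corner
        [6.0, 4.0, 0.0],   # third recorded corner (counter-clockwise)
    ]
)


@dataclass
class Pose:
    """Origin plus right-handed orthonormal frame (axes are the columns)."""

    origin: np.ndarray
    rotation: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-8):
            raise ValueError("pose axes must be orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("pose frame must be right-handed")

    @property
    def x_axis(self) -> np.ndarray:
        return self.rotation[:, 0].copy()

    @property
    def normal(self) -> np.ndarray:
        return self.rotation[:, 2].copy()

    def transformed(self, t: RigidTransform) -> "Pose":
        return Pose(t.apply(self.origin), t.rotation @ self.rotation)

    def to_dict(self) -> dict:
        return {"origin": self.origin.tolist(), "rotation": self.rotation.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "Pose":
        return cls(np.asarray(d["origin"]), np.asarray(d["rotation"]))


def _orthonormalize(e1: np.ndarray, n: np.ndarray) -> np.ndarray:
    n = n / np.linalg.norm(n)
    e1 = e1 - np.dot(e1, n) * n
    e1 = e1 / np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    return np.column_stack([e1, e2, n])


def fantail_pose_from_points(p_exit, p_a, p_b) -> Pose:
    """Pose of the receiver-stimulator fantail from its three recorded points.

    The lead-exit point is recorded first and becomes the pose origin; the
    remaining two corners are recorded counter-clockwise, which fixes the
    normal; the in-plane x axis points toward the triangle centroid.
    """
    p_exit = np.asarray(p_exit, dtype=float)
    p_a = np.asarray(p_a, dtype=float)
    p_b = np.asarray(p_b, dtype=float)
    n = np.cross(p_a - p_exit, p_b - p_exit)
    scale = max(np.linalg.norm(p_a - p_exit), np.linalg.norm(p_b - p_exit), 1e-9)
    if np.linalg.norm(n) < 1e-9 * scale**2:
        raise DegenerateConfigurationError("fantail points are collinear")
    centroid = (p_exit + p_a + p_b) / 3.0
    return Pose(p_exit, _orthonormalize(centroid - p_exit, n))


def tripod_pose_from_points(legs) -> Pose:
    """Pose of the patient-marker tripod from its three leg contact points."""
    legs = np.asarray(legs, dtype=float).reshape(3, 3)
    n = np.cross(legs[1] - legs[0], legs[2] - legs[0])
    scale = max(np.linalg.norm(legs[1] - legs[0]), np.linalg.norm(legs[2] - legs[0]), 1e-9)
    if np.linalg.norm(n) < 1e-9 * scale**2:
        raise DegenerateConfigurationError("tripod legs are collinear")
    centroid = legs.mean(axis=0)
    return Pose(centroid, _orthonormalize(legs[0] - centroid, n))


@dataclass
class Polyline:
    """Ordered 3-D polyline (incision border and similar traced structures)."""

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        # collapse duplicate consecutive points
        keep = np.ones(len(pts), dtype=bool)
        keep[1:] = np.linalg.norm(np.diff(pts, axis=0), axis=1) > 1e-9
        pts = pts[keep]
        if len(pts) < 2:
            raise ValueError("polyline needs at least 2 distinct points")
        self.points = pts

    @property
    def length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    def sample(self, spacing: float) -> np.ndarray:
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        n = max(2, int(np.ceil(s[-1] / spacing)) + 1)
        si = np.linspace(0.0, s[-1], n)
        return np.column_stack([np.interp(si, s, self.points[:, k]) for k in range(3)])

    def distance(self, query) -> np.ndarray:
        """Min distance from each query point to the polyline segments."""
        q = np.atleast_2d(np.asarray(query, dtype=float))
        a = self.points[:-1]
        d = self.points[1:] - a
        dd = np.einsum("ij,ij->i", d, d)
        dd[dd == 0] = 1.0
        # (q, seg) projection parameter
        t = np.einsum("qik,ik->qi", q[:, None, :] - a[None, :, :], d) / dd
        t = np.clip(t, 0.0, 1.0)
        closest = a[None, :, :] + t[..., None] * d[None, :, :]
        dist = np.linalg.norm(q[:, None, :] - closest, axis=2)
        return dist.min(axis=1)

    def side_of(self, point, reference) -> bool:
        """True if ``point`` lies on the same (xy-projected) side of the
        polyline as ``reference`` — the exposed region contains the
        trajectory entry by definition."""
        def signed(p):
            p = np.asarray(p, dtype=float)
            d2 = self.distance(p[None, :])
            a, b = self.points[:-1, :2], self.points[1:, :2]
            seg = b - a
            rel = p[None, :2] - a
            cross = seg[:, 0] * rel[:, 1] - seg[:, 1] * rel[:, 0]
            dd = np.einsum("ij,ij->i", seg, seg)
            dd[dd == 0] = 1.0
            t = np.clip(np.einsum("ij,ij->i", rel, seg) / dd, 0.0, 1.0)
            closest = a + t[:, None] * seg
            i = int(np.argmin(np.linalg.norm(p[None, :2] - closest, axis=1)))
            return np.sign(cross[i]), d2
        sp, _ = signed(point)
        sr, _ = signed(reference)
        return bool(sp == sr or sp == 0)

    def to_dict(self) -> dict:
        return {"points": self.points.tolist()}


@dataclass
class ForbiddenStructure:
    """Named structure the channel must keep a safety margin from.

    ``points`` are representative surface points; ``radius`` inflates each
    point to a sphere (e.g. the tracked-marker volume)."""

    name: str
    points: np.ndarray
    radius: float = 0.0

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.radius = float(self.radius)

    def to_dict(self) -> dict:
        return {"name": self.name, "points": self.points.tolist(), "radius": self.radius}


@dataclass
class SurgicalSite:
    """Everything the planner needs, in one metric frame (mm)."""

    outer: SurfaceMesh
    inner: SurfaceMesh
    fiducials: np.ndarray
    tripod_pose: Pose
    fantail_pose: Pose
    fantail_points: np.ndarray
    incision: Polyline
    trajectory: Trajectory
    forbidden: list
    air_cells: np.ndarray = field(default_factory=lambda: np.zeros((0, 4)))
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.fiducials = np.asarray(self.fiducials, dtype=float).reshape(-1, 3)
        self.air_cells = np.asarray(self.air_cells, dtype=float).reshape(-1, 4)

    @property
    def lead_exit(self) -> np.ndarray:
        return self.fantail_pose.origin.copy()

    def validate(self, tol: float = 1.0) -> None:
        """Check the site invariants (fiducials near outer surface, trajectory
        entry on the outer surface)."""
        tree = cKDTree(self.outer.vertices)
        d_fid, _ = tree.query(self.fiducials)
        if np.any(d_fid > tol):
            raise ValueError(f"fiducials farther than {tol} mm from outer surface")
        d_entry, _ = tree.query(self.trajectory.entry)
        if d_entry > tol:
            raise ValueError("trajectory entry not on outer surface")

    def transformed(self, t: RigidTransform) -> "SurgicalSite":
        return SurgicalSite(
            outer=self.outer.transformed(t),
            inner=self.inner.transformed(t),
            fiducials=t.apply(self.fiducials),
            tripod_pose=self.tripod_pose.transformed(t),
            fantail_pose=self.fantail_pose.transformed(t),
            fantail_points=t.apply(self.fantail_points),
            incision=Polyline(t.apply(self.incision.points)),
            trajectory=Trajectory(
                t.apply(self.trajectory.entry),
                t.apply_vector(self.trajectory.axis),
                self.trajectory.tunnel_length,
            ),
            forbidden=[
                ForbiddenStructure(f.name, t.apply(f.points), f.radius)
                for f in self.forbidden
            ],
            air_cells=np.column_stack([t.apply(self.air_cells[:, :3]), self.air_cells[:, 3]])
            if len(self.air_cells)
            else self.air_cells,
            meta=dict(self.meta),
        )


def virtualize_incision(points) -> Polyline:
    """Build the incision-border polyline from traced points."""
    return Polyline(points)


# ---------------------------------------------------------------------------
# thickness map
# ---------------------------------------------------------------------------


def thickness_map(
    outer: SurfaceMesh,
    inner: SurfaceMesh,
    required: float = 3.3,
    max_thickness: float = 50.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-outer-vertex bone thickness along the inward vertex normal.

    Thickness is the ray distance from each outer vertex along its inward
    normal to the inner (dura-side) surface; vertices with no inner hit get
    infinite thickness.  ``required`` defaults to channel depth 2.3 mm plus
    the 1.0 mm safety margin.  Returns (thickness, sufficient) arrays.
    """
    normals = outer.vertex_normals
    origins = outer.vertices
    caster = RayCaster(inner)
    caster._ensure_tree()
    tri = inner.vertices[inner.faces]
    tri_r = caster._radius
    thickness = np.full(len(origins), np.inf)

    # tile the queries spatially so each batch tests few triangles
    tile = max(4.0, max_thickness / 8.0)
    keys = np.floor(origins[:, :2] / tile).astype(np.int64)
    order = np.lexsort((keys[:, 1], keys[:, 0]))
    groups: dict[tuple, list] = {}
    for i in order:
        groups.setdefault((keys[i, 0], keys[i, 1]), []).append(i)
    for idx in groups.values():
        idx = np.asarray(idx)
        center = origins[idx].mean(axis=0)
        spread = float(np.max(np.linalg.norm(origins[idx] - center, axis=1))) if len(idx) else 0.0
        cand = caster._tree.query_ball_point(center, spread + max_thickness + tri_r)
        d, _, _, _ = caster.cast_batch(
            origins[idx], -normals[idx], max_distance=max_thickness,
            candidates=np.asarray(cand, dtype=np.int64),
        )
        thickness[idx] = d
    sufficient = thickness >= required
    return thickness, sufficient


# ---------------------------------------------------------------------------
# synthetic anatomy
# ---------------------------------------------------------------------------


@dataclass
class SynthParams:
    """Parameters of the synthetic temporal-bone slab.

    Defaults are full (clinical) scale: a 60 x 40 mm slab, the fantail
    lead-exit >= 40 mm from the drill entry so a ~60 mm surface channel
    fits, slab thickness comfortably above the 3.3 mm (2.3 mm depth + 1.0 mm
    margin) requirement, and a handful of mastoid-like air cells.
    """

    extent: tuple = (60.0, 40.0)
    grid_spacing: float = 0.5
    base_thickness: float = 6.0
    thickness_variation: float = 1.5
    bump_amplitude: float = 0.3
    bump_wavelength: float = 15.0
    dome_sag: float = 2.0
    n_air_cells: int = 8
    air_cell_radius: tuple = (0.3, 1.0)
    entry_xy: tuple = (10.0, 20.0)
    fantail_xy: tuple = (52.0, 20.0)
    tunnel_length: float = 25.0
    trajectory_tilt_deg: float = 8.0
    seed: int = 0

    def scaled(self, **overrides) -> "SynthParams":
        d = self.__dict__ | overrides
        return SynthParams(**d)


class _HeightField:
    """Analytic outer/inner surface pair used only inside the generator."""

    def __init__(self, p: SynthParams, rng: np.random.Generator):
        self.p = p
        lx, ly = p.extent
        self.phases = rng.uniform(0, 2 * np.pi, size=4)
        self.cx, self.cy = lx / 2.0, ly / 2.0

    def outer_z(self, x, y):
        p = self.p
        lx, ly = p.extent
        dome = -p.dome_sag * (((x - self.cx) / (lx / 2)) ** 2 + ((y - self.cy) / (ly / 2)) ** 2)
        k = 2 * np.pi / p.bump_wavelength
        bumps = p.bump_amplitude * np.sin(k * x + self.phases[0]) * np.sin(k * y + self.phases[1])
        return dome + bumps

    def thickness(self, x, y):
        p = self.p
        k = 2 * np.pi / (p.bump_wavelength * 1.7)
        var = p.thickness_variation * np.sin(k * x + self.phases[2]) * np.cos(k * y + self.phases[3])
        return p.base_thickness + var

    def inner_z(self, x, y):
        return self.outer_z(x, y) - self.thickness(x, y)

    def normal(self, x, y, h=1e-4):
        gx = (self.outer_z(x + h, y) - self.outer_z(x - h, y)) / (2 * h)
        gy = (self.outer_z(x, y + h) - self.outer_z(x, y - h)) / (2 * h)
        n = np.stack(np.broadcast_arrays(-gx, -gy, np.ones_like(gx)), axis=-1)
        return n / np.linalg.norm(n, axis=-1, keepdims=True)


def _grid_mesh(xs, ys, z, flip: bool = False) -> SurfaceMesh:
    nx, ny = len(xs), len(ys)
    xx, yy = np.meshgrid(xs, ys, indexing="ij")
    verts = np.column_stack([xx.ravel(), yy.ravel(), z.ravel()])
    i, j = np.meshgrid(np.arange(nx - 1), np.arange(ny - 1), indexing="ij")
    v00 = (i * ny + j).ravel()
    v10 = ((i + 1) * ny + j).ravel()
    v01 = (i * ny + j + 1).ravel()
    v11 = ((i + 1) * ny + j + 1).ravel()
    # CCW seen from +z -> normals point up (outward for the outer surface)
    f1 = np.column_stack([v00, v10, v11])
    f2 = np.column_stack([v00, v11, v01])
    faces = np.vstack([f1, f2])
    if flip:
        faces = faces[:, ::-1]
    return SurfaceMesh(verts, faces)


def synth_temporal_bone(params: SynthParams | None = None) -> SurgicalSite:
    """Generate a reproducible synthetic surgical site.

    The same ``params`` (including seed) always produce bit-identical
    meshes and point sets.
    """
    p = params or SynthParams()
    rng = np.random.default_rng(p.seed)
    field_ = _HeightField(p, rng)
    lx, ly = p.extent
    min_thick = p.base_thickness - abs(p.thickness_variation)
    if min_thick <= 0:
        raise ValueError("thickness variation would make the slab vanish")
    if p.n_air_cells and p.air_cell_radius[1] * 2.0 >= min_thick:
        raise ValueError("air cells larger than the minimum slab thickness")

    xs = np.arange(0.0, lx + p.grid_spacing / 2, p.grid_spacing)
    ys = np.arange(0.0, ly + p.grid_spacing / 2, p.grid_spacing)
    xx, yy = np.meshgrid(xs, ys, indexing="ij")
    outer = _grid_mesh(xs, ys, field_.outer_z(xx, yy))
    inner = _grid_mesh(xs, ys, field_.inner_z(xx, yy), flip=True)

    def on_surface(xy):
        x, y = float(xy[0]), float(xy[1])
        # snap to the vertex grid so the point lies exactly on the mesh
        x = xs[int(np.argmin(np.abs(xs - x)))]
        y = ys[int(np.argmin(np.abs(ys - y)))]
        return np.array([x, y, float(field_.outer_z(x, y))])

    entry = on_surface(p.entry_xy)
    exit_pt = on_surface(p.fantail_xy)

    # trajectory: inward, tilted slightly off the surface normal
    n_entry = field_.normal(entry[0], entry[1]).reshape(3)
    tilt = np.deg2rad(p.trajectory_tilt_deg)
    toward = exit_pt - entry
    toward = toward - np.dot(toward, n_entry) * n_entry
    toward /= max(np.linalg.norm(toward), 1e-9)
    axis = -np.cos(tilt) * n_entry + np.sin(tilt) * toward
    trajectory = Trajectory(entry, axis / np.linalg.norm(axis), p.tunnel_length)

    # fiducial screws around the entry, proud of the surface by 0.5 mm;
    # placed nearly perpendicular to the entry-to-fantail corridor so the
    # channel passes between them with margin, as a surgeon would plan
    fid = []
    r_fid = min(7.0, 0.35 * np.linalg.norm(exit_pt[:2] - entry[:2]))
    corridor = np.arctan2(exit_pt[1] - entry[1], exit_pt[0] - entry[0])
    for ang in corridor + np.deg2rad([70.0, 110.0, 250.0, 290.0]):
        xy = entry[:2] + r_fid * np.array([np.cos(ang), np.sin(ang)])
        xy = np.clip(xy, [1.0, 1.0], [lx - 1.0, ly - 1.0])
        fid.append([xy[0], xy[1], float(field_.outer_z(*xy)) + 0.5])
    fiducials = np.asarray(fid)

    # fantail pose: lead exit at exit_pt, flare pointing away from the entry
    n_exit = field_.normal(exit_pt[0], exit_pt[1]).reshape(3)
    away = exit_pt - entry
    away = away - np.dot(away, n_exit) * n_exit
    away /= max(np.linalg.norm(away), 1e-9)
    rot = np.column_stack([away, np.cross(n_exit, away), n_exit])
    fantail_points = exit_pt + FANTAIL_TEMPLATE @ rot.T
    fantail_pose = fantail_pose_from_points(*fantail_points)

    # tripod well off the entry-exit corridor
    mid = 0.5 * (entry[:2] + exit_pt[:2])
    perp = np.array([-(exit_pt[1] - entry[1]), exit_pt[0] - entry[0]])
    perp /= max(np.linalg.norm(perp), 1e-9)
    tri_c = np.clip(mid - perp * (0.38 * ly), [4.0, 4.0], [lx - 4.0, ly - 4.0])
    legs = []
    for ang in np.deg2rad([90.0, 210.0, 330.0]):
        xy = tri_c + 4.0 * np.array([np.cos(ang), np.sin(ang)])
        legs.append([xy[0], xy[1], float(field_.outer_z(*xy))])
    legs = np.asarray(legs)
    tripod_pose = tripod_pose_from_points(legs)
    marker_center = tripod_pose.origin + tripod_pose.normal * 8.0

    # lazy-S incision trace on the opposite side of the corridor
    inc_y = np.clip(mid[1] + perp[1] * 0.42 * ly + 0.0, 2.0, ly - 2.0)
    tx = np.linspace(2.0, lx - 2.0, 12)
    ty = np.clip(inc_y + 1.5 * np.sin(2 * np.pi * tx / (0.6 * lx)), 1.0, ly - 1.0)
    incision = Polyline(np.column_stack([tx, ty, field_.outer_z(tx, ty)]))

    # air-cell voids in the slab interior
    cells = []
    tries = 0
    while len(cells) < p.n_air_cells and tries < 1000:
        tries += 1
        r = rng.uniform(*p.air_cell_radius)
        x = rng.uniform(3.0, lx - 3.0)
        y = rng.uniform(3.0, ly - 3.0)
        zo = float(field_.outer_z(x, y))
        zi = float(field_.inner_z(x, y))
        lo, hi = zi + r + 0.2, zo - r - 0.2
        if hi <= lo:
            continue
        z = rng.uniform(lo, hi)
        cells.append([x, y, z, r])
    air_cells = np.asarray(cells).reshape(-1, 4)

    forbidden = [
        ForbiddenStructure("fiducials", fiducials, radius=0.8),
        ForbiddenStructure("tripod_legs", legs, radius=1.0),
        ForbiddenStructure("marker", marker_center[None, :], radius=3.0),
        ForbiddenStructure("incision", incision.sample(1.0), radius=0.0),
    ]

    site = SurgicalSite(
        outer=outer,
        inner=inner,
        fiducials=fiducials,
        tripod_pose=tripod_pose,
        fantail_pose=fantail_pose,
        fantail_points=fantail_points,
        incision=incision,
        trajectory=trajectory,
        forbidden=forbidden,
        air_cells=air_cells,
        meta={"params": {k: (list(v) if isinstance(v, tuple) else v) for k, v in p.__dict__.items()}},
    )
    site.validate()
    return site
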