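"""Shared geometric primitives.

Everything downstream of the planner works in a single right-handed metric
frame (millimetres): rigid transforms, cubic Bezier segments and composite
G1 paths, triangle-mesh ray casting, and paired-point (fiducial) rigid
registration.  Meshes are thin wrappers around vertex/face arrays backed by
:mod:`trimesh` for I/O and derived quantities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.spatial import cKDTree

__all__ = [
    "SurfaceMesh",
    "RigidTransform",
    "BezierSegment",
    "CompositePath",
    "Trajectory",
    "RayHit",
    "RayCaster",
    "rigid_register",
    "ray_intersect",
    "DegenerateConfigurationError",
]

_EPS = 1e-12


class DegenerateConfigurationError(ValueError):
    """Raised when a point configuration is too degenerate for the operation."""


# ---------------------------------------------------------------------------
# meshes
# ---------------------------------------------------------------------------


@dataclass
class SurfaceMesh:
    """Triangulated surface in mm with outward-pointing face normals.

    Parameters
    ----------
    vertices : (n, 3) float array
    faces : (m, 3) int array
        Vertex-index triples with consistent winding (right-hand rule gives
        the outward normal).
    """

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=float)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (m, 3)")
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise ValueError("face indices out of range")

    # derived quantities ----------------------------------------------------
    @property
    def face_normals(self) -> np.ndarray:
        tri = self.vertices[self.faces]
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        norm = np.linalg.norm(n, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        return n / norm

    @property
    def vertex_normals(self) -> np.ndarray:
        return self.to_trimesh().vertex_normals.copy()

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)

    @classmethod
    def from_trimesh(cls, mesh: trimesh.Trimesh) -> "SurfaceMesh":
        return cls(np.asarray(mesh.vertices, dtype=float), np.asarray(mesh.faces, dtype=np.int64))

    def save(self, path) -> None:
        self.to_trimesh().export(str(path))

    @classmethod
    def load(cls, path) -> "SurfaceMesh":
        try:
            # merge the duplicated vertices of triangle-soup formats (STL)
            mesh = trimesh.load_mesh(str(path), process=True)
        except Exception as exc:  # corrupt/truncated files fail loudly
            raise ValueError(f"could not parse mesh file {path!r}: {exc}") from exc
        if not isinstance(mesh, trimesh.Trimesh) or len(mesh.faces) == 0:
            raise ValueError(f"could not read a triangle mesh from {path!r}")
        return cls.from_trimesh(mesh)

    def transformed(self, transform: "RigidTransform") -> "SurfaceMesh":
        return SurfaceMesh(transform.apply(self.vertices), self.faces.copy())


# ---------------------------------------------------------------------------
# rigid transforms
# ---------------------------------------------------------------------------


@dataclass
class RigidTransform:
    """Proper rigid motion x -> R @ x + t (rotation orthonormal, det +1)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthonormal within 1e-9")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation must be proper (det +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_axis_angle(cls, axis, angle: float, translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        axis = np.asarray(axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        k = np.array(
            [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
        )
        rot = np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)
        return cls(rot, np.asarray(translation, dtype=float))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def apply_vector(self, vectors: np.ndarray) -> np.ndarray:
        return np.asarray(vectors, dtype=float) @ self.rotation.T

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self o other: first apply ``other``, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def to_dict(self) -> dict:
        return {"rotation": self.rotation.tolist(), "translation": self.translation.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(np.asarray(d["rotation"]), np.asarray(d["translation"]))


def rigid_register(src: np.ndarray, dst: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares rigid transform mapping ``src`` onto ``dst`` (Kabsch).

    Returns the optimal :class:`RigidTransform` and the RMS residual in mm.
    Requires at least three non-collinear paired points.
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 3:
        raise ValueError("src and dst must be matching (n, 3) arrays")
    if len(src) < 3:
        raise DegenerateConfigurationError("need at least 3 paired points")
    sc, dc = src.mean(axis=0), dst.mean(axis=0)
    a, b = src - sc, dst - dc
    if np.linalg.matrix_rank(a, tol=1e-9 * max(1.0, np.abs(a).max())) < 2:
        raise DegenerateConfigurationError("points are collinear")
    h = a.T @ b
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = dc - rot @ sc
    transform = RigidTransform(rot, t)
    residual = float(np.sqrt(np.mean(np.sum((transform.apply(src) - dst) ** 2, axis=1))))
    return transform, residual


# ---------------------------------------------------------------------------
# Bezier curves
# ---------------------------------------------------------------------------


@dataclass
class BezierSegment:
    """Cubic Bezier segment with four control points (mm)."""

    control_points: np.ndarray

    def __post_init__(self) -> None:
        self.control_points = np.asarray(self.control_points, dtype=float)
        if self.control_points.shape != (4, 3):
            raise ValueError("cubic segment needs (4, 3) control points")

    def evaluate(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)[..., None]
        p = self.control_points
        mt = 1.0 - t
        return (
            mt**3 * p[0]
            + 3 * mt**2 * t * p[1]
            + 3 * mt * t**2 * p[2]
            + t**3 * p[3]
        )

    def derivative(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)[..., None]
        p = self.control_points
        mt = 1.0 - t
        return 3 * (
            mt**2 * (p[1] - p[0]) + 2 * mt * t * (p[2] - p[1]) + t**2 * (p[3] - p[2])
        )

    def second_derivative(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)[..., None]
        p = self.control_points
        return 6 * ((1.0 - t) * (p[2] - 2 * p[1] + p[0]) + t * (p[3] - 2 * p[2] + p[1]))

    def curvature(self, t) -> np.ndarray:
        """Unsigned curvature |c' x c''| / |c'|^3 in 1/mm.

        At a zero-velocity parameterization point the curvature is reported
        as 0 (degenerate tangent; flagged by callers that care).
        """
        d1 = self.derivative(t)
        d2 = self.second_derivative(t)
        cross = np.cross(d1, d2)
        speed = np.linalg.norm(d1, axis=-1)
        num = np.linalg.norm(cross, axis=-1)
        out = np.zeros_like(speed)
        ok = speed > 1e-9
        out[ok] = num[ok] / speed[ok] ** 3
        return out

    def arc_length(self, t0: float = 0.0, t1: float = 1.0, panels: int = 8) -> float:
        """Arc length by composite Gauss-Legendre quadrature (16 nodes per
        panel), accurate far beyond 1e-4 relative for cubic speed profiles."""
        nodes, weights = np.polynomial.legendre.leggauss(16)
        edges = np.linspace(t0, t1, panels + 1)
        mid = 0.5 * (edges[:-1] + edges[1:])
        half = 0.5 * np.diff(edges)
        t = (mid[:, None] + half[:, None] * nodes[None, :]).ravel()
        speed = np.linalg.norm(self.derivative(t), axis=-1).reshape(panels, -1)
        return float(np.sum(speed @ weights * half))

    def transformed(self, transform: RigidTransform) -> "BezierSegment":
        return BezierSegment(transform.apply(self.control_points))


@dataclass
class CompositePath:
    """Ordered cubic Bezier segments, C0 by construction and G1 at joins."""

    segments: list

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("path needs at least one segment")
        for a, b in zip(self.segments[:-1], self.segments[1:]):
            if not np.allclose(a.control_points[3], b.control_points[0], atol=1e-9):
                raise ValueError("segments are not C0-continuous")

    @property
    def start(self) -> np.ndarray:
        return self.segments[0].control_points[0].copy()

    @property
    def end(self) -> np.ndarray:
        return self.segments[-1].control_points[3].copy()

    def is_g1(self, atol: float = 1e-6) -> bool:
        for a, b in zip(self.segments[:-1], self.segments[1:]):
            ta = a.derivative(1.0)
            tb = b.derivative(0.0)
            na, nb = np.linalg.norm(ta), np.linalg.norm(tb)
            if na < 1e-9 or nb < 1e-9:
                continue
            if np.linalg.norm(np.cross(ta / na, tb / nb)) > atol or np.dot(ta, tb) < 0:
                return False
        return True

    def evaluate(self, u) -> np.ndarray:
        """Evaluate at global parameter u in [0, n_segments]."""
        u = np.atleast_1d(np.asarray(u, dtype=float))
        n = len(self.segments)
        idx = np.clip(np.floor(u).astype(int), 0, n - 1)
        local = u - idx
        out = np.empty((len(u), 3))
        for i in range(n):
            sel = idx == i
            if sel.any():
                out[sel] = self.segments[i].evaluate(local[sel])
        return out

    def arc_length(self) -> float:
        return float(sum(seg.arc_length() for seg in self.segments))

    def max_curvature(self, samples_per_segment: int = 200) -> float:
        t = np.linspace(0.0, 1.0, samples_per_segment)
        return float(max(seg.curvature(t).max() for seg in self.segments))

    def sample_by_arclength(self, spacing: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Uniform-arclength samples: (s, points, unit tangents).

        The path is first oversampled, then re-parameterized by cumulative
        chord length; accuracy is far below any milling tolerance for the
        smooth paths produced here.
        """
        dense = max(64, int(np.ceil(self.arc_length() / max(spacing, 1e-3) * 8)))
        u = np.linspace(0.0, len(self.segments), dense)
        pts = self.evaluate(u)
        seg_len = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        s_dense = np.concatenate([[0.0], np.cumsum(seg_len)])
        total = s_dense[-1]
        n = max(2, int(np.round(total / spacing)) + 1)
        s = np.linspace(0.0, total, n)
        out = np.column_stack([np.interp(s, s_dense, pts[:, k]) for k in range(3)])
        tang = np.gradient(out, s, axis=0)
        norm = np.linalg.norm(tang, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        return s, out, tang / norm

    def transformed(self, transform: RigidTransform) -> "CompositePath":
        return CompositePath([seg.transformed(transform) for seg in self.segments])

    def to_dict(self) -> dict:
        return {"segments": [seg.control_points.tolist() for seg in self.segments]}

    @classmethod
    def from_dict(cls, d: dict) -> "CompositePath":
        return cls([BezierSegment(np.asarray(cp)) for cp in d["segments"]])


@dataclass
class Trajectory:
    """Drill trajectory: entry point on the bone surface, unit axis pointing
    into the bone, and tunnel length (mm)."""

    entry: np.ndarray
    axis: np.ndarray
    tunnel_length: float

    def __post_init__(self) -> None:
        self.entry = np.asarray(self.entry, dtype=float).reshape(3)
        self.axis = np.asarray(self.axis, dtype=float).reshape(3)
        n = np.linalg.norm(self.axis)
        if abs(n - 1.0) > 1e-6:
            raise ValueError("trajectory axis must be unit-norm")
        self.axis = self.axis / n
        self.tunnel_length = float(self.tunnel_length)

    def to_dict(self) -> dict:
        return {
            "entry": self.entry.tolist(),
            "axis": self.axis.tolist(),
            "tunnel_length": self.tunnel_length,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Trajectory":
        return cls(np.asarray(d["entry"]), np.asarray(d["axis"]), d["tunnel_length"])


# ---------------------------------------------------------------------------
# ray casting
# ---------------------------------------------------------------------------


@dataclass
class RayHit:
    point: np.ndarray
    normal: np.ndarray
    distance: float
    face_index: int


def _moller_trumbore(origins, directions, v0, e1, e2):
    """Vectorized ray/triangle intersection.

    origins, directions: (r, 3); v0, e1, e2: (m, 3).  Returns (r, m) hit
    distance array with inf where there is no positive-distance hit.
    """
    # broadcast to (r, m, 3)
    d = directions[:, None, :]
    o = origins[:, None, :]
    pvec = np.cross(d, e2[None, :, :])
    det = np.einsum("rmk,mk->rm", pvec, e1)
    inv_det = np.where(np.abs(det) > 1e-14, 1.0 / np.where(det == 0, 1.0, det), np.nan)
    tvec = o - v0[None, :, :]
    u = np.einsum("rmk,rmk->rm", tvec, pvec) * inv_det
    qvec = np.cross(tvec, e1[None, :, :])
    v = np.einsum("rmk,rmk->rm", qvec, d) * inv_det
    t = np.einsum("rmk,mk->rm", qvec, e2) * inv_det
    eps = 1e-10
    ok = (
        np.isfinite(t)
        & (u >= -eps)
        & (v >= -eps)
        & (u + v <= 1.0 + eps)
        & (t > 1e-9)
    )
    return np.where(ok, t, np.inf)


class RayCaster:
    """First-positive-hit ray casting against a triangle mesh.

    Ties at shared edges are resolved by the smallest face index (the
    distance comparison uses a strict ``argmin`` over faces in index order).
    For large meshes, fan queries prune candidate triangles with a KD-tree
    on triangle centroids plus an exact plane-slab test.
    """

    def __init__(self, mesh: SurfaceMesh):
        self.mesh = mesh
        tri = mesh.vertices[mesh.faces]
        self._v0 = np.ascontiguousarray(tri[:, 0])
        self._e1 = np.ascontiguousarray(tri[:, 1] - tri[:, 0])
        self._e2 = np.ascontiguousarray(tri[:, 2] - tri[:, 0])
        self._centroids = tri.mean(axis=1)
        if len(tri):
            self._radii = np.sqrt(np.max(np.sum((tri - self._centroids[:, None, :]) ** 2, axis=2), axis=1))
            self._radius = float(self._radii.max())
        else:
            self._radii = np.zeros(0)
            self._radius = 0.0
        self._tree: cKDTree | None = None
        self._normals = mesh.face_normals

    def _ensure_tree(self) -> None:
        if self._tree is None:
            self._tree = cKDTree(self._centroids)

    def cast(self, origin, direction, max_distance: float = np.inf) -> RayHit | None:
        """Nearest positive-distance hit of a single ray, or None."""
        origin = np.asarray(origin, dtype=float).reshape(1, 3)
        direction = np.asarray(direction, dtype=float).reshape(1, 3)
        n = np.linalg.norm(direction)
        if abs(n - 1.0) > 1e-6:
            raise ValueError("ray direction must be unit-norm")
        t = _moller_trumbore(origin, direction / n, self._v0, self._e1, self._e2)[0]
        idx = int(np.argmin(t))
        if not np.isfinite(t[idx]) or t[idx] > max_distance:
            return None
        dist = float(t[idx])
        return RayHit(
            point=origin[0] + dist * direction[0],
            normal=self._normals[idx].copy(),
            distance=dist,
            face_index=idx,
        )

    def cast_batch(self, origins, directions, max_distance=np.inf, candidates=None,
                   chunk=4_000_000):
        """Nearest hits for many rays.

        Returns (distances, points, normals, face_indices); misses get
        inf / nan / -1.  ``candidates`` optionally restricts the triangle
        set (indices into faces).
        """
        origins = np.atleast_2d(np.asarray(origins, dtype=float))
        directions = np.atleast_2d(np.asarray(directions, dtype=float))
        if candidates is None:
            v0, e1, e2 = self._v0, self._e1, self._e2
            cand_idx = None
        else:
            cand_idx = np.asarray(candidates, dtype=np.int64)
            cand_idx.sort()  # keep smallest-face-index tie rule
            v0, e1, e2 = self._v0[cand_idx], self._e1[cand_idx], self._e2[cand_idx]
        r = len(origins)
        m = len(v0)
        dist = np.full(r, np.inf)
        face = np.full(r, -1, dtype=np.int64)
        if m == 0:
            pts = np.full((r, 3), np.nan)
            return dist, pts, pts.copy(), face
        rows = max(1, int(chunk // max(m, 1)))
        for lo in range(0, r, rows):
            hi = min(r, lo + rows)
            t = _moller_trumbore(origins[lo:hi], directions[lo:hi], v0, e1, e2)
            j = np.argmin(t, axis=1)
            d = t[np.arange(hi - lo), j]
            dist[lo:hi] = d
            face[lo:hi] = np.where(np.isfinite(d), j, -1)
        if cand_idx is not None:
            hitmask = face >= 0
            face[hitmask] = cand_idx[face[hitmask]]
        miss = ~np.isfinite(dist) | (dist > max_distance)
        dist[miss] = np.inf
        face[miss] = -1
        pts = np.full((r, 3), np.nan)
        nrm = np.full((r, 3), np.nan)
        hit = ~miss
        pts[hit] = origins[hit] + dist[hit, None] * directions[hit]
        nrm[hit] = self._normals[face[hit]]
        return dist, pts, nrm, face

    @property
    def triangle_centroids(self) -> np.ndarray:
        return self._centroids

    @property
    def triangle_radius(self) -> float:
        """Largest triangle circumscribed radius (pruning slack)."""
        return self._radius

    @property
    def triangle_radii(self) -> np.ndarray:
        """Per-triangle circumscribed radii (exact pruning slack)."""
        return self._radii

    def candidates_near(self, point, radius: float) -> np.ndarray:
        """Indices of triangles whose centroid lies within ``radius``."""
        self._ensure_tree()
        return np.asarray(
            self._tree.query_ball_point(np.asarray(point, dtype=float), radius),
            dtype=np.int64,
        )

    def cast_fan(self, origin, directions, max_distance: float):
        """Coplanar fan of short rays from a common origin (cross sections).

        Candidate triangles are those whose centroid lies within
        ``max_distance`` (+ triangle radius) of the origin *and* whose
        vertices straddle the fan plane; then exact intersection.
        """
        origin = np.asarray(origin, dtype=float).reshape(3)
        directions = np.atleast_2d(np.asarray(directions, dtype=float))
        self._ensure_tree()
        cand = np.asarray(
            self._tree.query_ball_point(origin, max_distance + self._radius),
            dtype=np.int64,
        )
        if len(cand) and len(directions) >= 3:
            # fan plane normal from two non-parallel directions
            normal = np.cross(directions[0], directions[len(directions) // 3])
            nn = np.linalg.norm(normal)
            if nn > 1e-9:
                normal = normal / nn
                d0 = (self._centroids[cand] - origin) @ normal
                cand = cand[np.abs(d0) <= self._radius * 2.0 + 1e-9]
        origins = np.broadcast_to(origin, directions.shape).copy()
        return self.cast_batch(origins, directions, max_distance, candidates=cand)


def ray_intersect(mesh: SurfaceMesh, origin, direction, max_distance: float = np.inf):
    """Nearest intersection of one ray with a mesh (None on a miss)."""
    return RayCaster(mesh).cast(origin, direction, max_distance)
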