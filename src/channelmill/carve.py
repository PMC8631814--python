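"""In-silico milling: carve a toolpath into the bone volume.

The carve stands in for robotic execution followed by micro-CT surface
reconstruction: the bone slab (between the outer and inner surfaces, minus
spherical air-cell voids) is voxelized as a signed-distance field, the
swept flat-ended cylindrical tool volume is subtracted along the
(optionally error-perturbed) toolpath, and the resulting bone/air interface
is extracted with marching cubes at the micro-CT-like voxel size
(default 0.05 mm).

Execution error has two parts mirroring how an image-guided system errs: a
per-case rigid bias (registration error) and a slowly varying zero-mean
Gaussian jitter of the tool position (navigation noise), modelled as a
correlated process along the path rather than white noise per waypoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import numba
from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator
from skimage.measure import marching_cubes

from .geometry import RigidTransform, SurfaceMesh
from .site import SurgicalSite
from .toolpath import ToolPath

__all__ = ["ExecutionError", "CarveResult", "inject_error", "carve"]


@dataclass
class ExecutionError:
    """Execution error applied to a toolpath before carving."""

    bias: RigidTransform
    jitter_sigma_lateral: float = 0.0
    jitter_sigma_depth: float = 0.0
    jitter_corr_length: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.jitter_sigma_lateral < 0 or self.jitter_sigma_depth < 0:
            raise ValueError("jitter sigmas must be >= 0")

    @classmethod
    def none(cls) -> "ExecutionError":
        return cls(RigidTransform.identity())

    def to_dict(self) -> dict:
        return {
            "bias": self.bias.to_dict(),
            "jitter_sigma_lateral": self.jitter_sigma_lateral,
            "jitter_sigma_depth": self.jitter_sigma_depth,
            "jitter_corr_length": self.jitter_corr_length,
            "seed": self.seed,
        }


def inject_error(
    seed: int,
    bias_translation_sigma: float = 0.0,
    bias_rotation_sigma: float = 0.0,
    jitter_sigma_lateral: float = 0.0,
    jitter_sigma_depth: float = 0.0,
    jitter_corr_length: float = 3.0,
) -> ExecutionError:
    """Sample a reproducible execution error.

    The rigid bias translation is drawn i.i.d. normal per axis and the
    rotation is a small random-axis rotation, so over many seeds the biases
    average to zero.
    """
    rng = np.random.default_rng(seed)
    t = rng.normal(0.0, bias_translation_sigma, size=3) if bias_translation_sigma > 0 else np.zeros(3)
    if bias_rotation_sigma > 0:
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = rng.normal(0.0, bias_rotation_sigma)
        bias = RigidTransform.from_axis_angle(axis, angle, t)
    else:
        bias = RigidTransform(np.eye(3), t)
    return ExecutionError(
        bias=bias,
        jitter_sigma_lateral=jitter_sigma_lateral,
        jitter_sigma_depth=jitter_sigma_depth,
        jitter_corr_length=jitter_corr_length,
        seed=seed,
    )


@dataclass
class CarveResult:
    postop: SurfaceMesh
    voxel: float
    error: dict = field(default_factory=dict)
    origin: np.ndarray | None = None
    bone_voxels_pre: int = 0
    bone_voxels_post: int = 0


def _height_interp(mesh: SurfaceMesh):
    xy = mesh.vertices[:, :2]
    z = mesh.vertices[:, 2]
    lin = LinearNDInterpolator(xy, z)
    near = NearestNDInterpolator(xy, z)

    def f(px, py):
        v = lin(px, py)
        bad = np.isnan(v)
        if np.any(bad):
            v[bad] = near(px[bad], py[bad])
        return v

    return f


def _apply_error(path: ToolPath, err: ExecutionError) -> ToolPath:
    pos = err.bias.apply(path.positions)
    axes = err.bias.apply_vector(path.axes)
    if err.jitter_sigma_lateral > 0 or err.jitter_sigma_depth > 0:
        rng = np.random.default_rng(err.seed)
        seg = np.linalg.norm(np.diff(pos, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        # squared-exponential Gaussian process along the path: the marginal
        # sigma is preserved everywhere (unlike knot interpolation) and the
        # sample paths are smooth at the correlation length scale
        ell = err.jitter_corr_length
        knots = np.arange(0.0, s[-1] + ell / 3.0, ell / 3.0)
        cov = np.exp(-0.5 * ((knots[:, None] - knots[None, :]) / ell) ** 2)
        chol = np.linalg.cholesky(cov + 1e-10 * np.eye(len(knots)))
        lat_k = err.jitter_sigma_lateral * (chol @ rng.standard_normal(len(knots)))
        dep_k = err.jitter_sigma_depth * (chol @ rng.standard_normal(len(knots)))
        lat = np.interp(s, knots, lat_k)
        dep = np.interp(s, knots, dep_k)
        tang = np.gradient(pos, axis=0)
        nt = np.linalg.norm(tang, axis=1, keepdims=True)
        nt[nt == 0] = 1.0
        tang = tang / nt
        lateral = np.cross(tang, axes)
        nl = np.linalg.norm(lateral, axis=1, keepdims=True)
        nl[nl == 0] = 1.0
        lateral = lateral / nl
        pos = pos + lat[:, None] * lateral - dep[:, None] * axes
    return ToolPath(pos, axes, path.phases, path.feeds, path.tool_diameter, path.spindle_rpm)


def carve(
    site: SurgicalSite,
    path: ToolPath,
    err: ExecutionError | None = None,
    voxel: float = 0.05,
    pad: float = 2.5,
) -> CarveResult:
    """Carve the toolpath into the site and extract the postop surface.

    The returned surface covers a band around the toolpath (the analysis
    pipeline, like a cropped micro-CT reconstruction, only needs the channel
    and its surroundings).  Air-cell voids intersected by the channel show
    up as wall gaps.
    """
    err = err or ExecutionError.none()
    r_tool = path.tool_diameter / 2.0
    if voxel > r_tool:
        raise ValueError("voxel size coarser than the tool radius")
    if len(path) == 0 or (
        len(path) > 1
        and float(np.linalg.norm(np.diff(path.positions, axis=0), axis=1).sum()) < 1e-12
    ) or len(path) == 1:
        return CarveResult(
            postop=SurfaceMesh(site.outer.vertices.copy(), site.outer.faces.copy()),
            voxel=voxel,
            error=err.to_dict(),
        )

    wp = _apply_error(path.densified(max(voxel, 0.05)), err)
    pos, axes = wp.positions, wp.axes

    f_outer = _height_interp(site.outer)
    f_inner = _height_interp(site.inner)

    lo = pos.min(axis=0) - (pad + r_tool)
    hi = pos.max(axis=0) + (pad + r_tool)
    xs = np.arange(lo[0], hi[0] + voxel, voxel, dtype=np.float32)
    ys = np.arange(lo[1], hi[1] + voxel, voxel, dtype=np.float32)
    xx, yy = np.meshgrid(xs.astype(float), ys.astype(float), indexing="ij")
    f_top = f_outer(xx.ravel(), yy.ravel()).reshape(xx.shape)
    f_bot = f_inner(xx.ravel(), yy.ravel()).reshape(xx.shape)
    z_lo = float(pos[:, 2].min() - 1.0)
    z_hi = float(np.nanmax(f_top) + 0.5)
    zs = np.arange(z_lo, z_hi + voxel, voxel, dtype=np.float32)
    nz = len(zs)

    # vertical signed distance to the slab (negative inside bone)
    sdf = np.empty((len(xs), len(ys), nz), dtype=np.float32)
    np.subtract(zs[None, None, :], f_top[:, :, None].astype(np.float32), out=sdf)
    np.maximum(sdf, f_bot[:, :, None].astype(np.float32) - zs[None, None, :], out=sdf)

    # subtract air cells
    for cx, cy, cz, r in site.air_cells:
        if (
            cx < lo[0] - r or cx > hi[0] + r
            or cy < lo[1] - r or cy > hi[1] + r
            or cz < z_lo - r or cz > z_hi + r
        ):
            continue
        dx = (xs.astype(float) - cx)[:, None, None]
        dy = (ys.astype(float) - cy)[None, :, None]
        dz = (zs.astype(float) - cz)[None, None, :]
        cell = (r - np.sqrt(dx * dx + dy * dy + dz * dz)).astype(np.float32)
        np.maximum(sdf, cell, out=sdf)

    bone_pre = int(np.count_nonzero(sdf < 0))

    # swept flat-ended cylindrical tool (tip at the waypoint, extending up
    # the tool axis); per-waypoint local SDF updates
    tool = np.full(sdf.shape, np.inf, dtype=np.float32)
    m = 2.0 * voxel
    f_at_wp = f_outer(pos[:, 0], pos[:, 1])
    heights = np.clip(f_at_wp - pos[:, 2], 0.0, None) + 0.5
    sin_tilt = np.sqrt(np.clip(1.0 - axes[:, 2] ** 2, 0.0, None))
    half_w = r_tool + heights * sin_tilt + m
    origin_g = np.array([xs[0], ys[0], zs[0]], dtype=np.float64)
    _sweep_tool_sdf(
        tool, pos.astype(np.float64), axes.astype(np.float64),
        half_w.astype(np.float64), heights.astype(np.float64),
        origin_g, float(voxel), float(r_tool), float(m),
    )

    np.negative(tool, out=tool)
    np.maximum(sdf, tool, out=sdf)
    post = sdf
    del tool
    bone_post = int(np.count_nonzero(post < 0))

    if not (post.min() < 0 < post.max()):
        raise RuntimeError("carve produced no bone/air interface in the band")
    verts, faces, _, _ = marching_cubes(post, level=0.0, spacing=(voxel, voxel, voxel))
    origin = origin_g.copy()
    mesh = SurfaceMesh(verts + origin, faces.astype(np.int64))
    mesh = _orient_outward(mesh, post, origin, voxel)
    return CarveResult(
        postop=mesh,
        voxel=voxel,
        error=err.to_dict(),
        origin=origin,
        bone_voxels_pre=bone_pre,
        bone_voxels_post=bone_post,
    )


@numba.njit(cache=True, fastmath=True)
def _sweep_tool_sdf(tool, pos, axes, half_w, heights, origin, voxel, r_tool, m):
    """Min-combine per-waypoint flat-cylinder SDFs into ``tool`` in place."""
    nx, ny, nz = tool.shape
    for i in range(pos.shape[0]):
        px, py, pz = pos[i, 0], pos[i, 1], pos[i, 2]
        ax, ay, az = axes[i, 0], axes[i, 1], axes[i, 2]
        hw = half_w[i]
        ix0 = max(0, int((px - hw - origin[0]) / voxel))
        ix1 = min(nx, int((px + hw - origin[0]) / voxel) + 2)
        iy0 = max(0, int((py - hw - origin[1]) / voxel))
        iy1 = min(ny, int((py + hw - origin[1]) / voxel) + 2)
        iz0 = max(0, int((pz - m - origin[2]) / voxel))
        iz1 = min(nz, int((pz + heights[i] + m - origin[2]) / voxel) + 2)
        for ix in range(ix0, ix1):
            dx = origin[0] + ix * voxel - px
            for iy in range(iy0, iy1):
                dy = origin[1] + iy * voxel - py
                for iz in range(iz0, iz1):
                    dz = origin[2] + iz * voxel - pz
                    dax = dx * ax + dy * ay + dz * az
                    dlat2 = dx * dx + dy * dy + dz * dz - dax * dax
                    if dlat2 < 0.0:
                        dlat2 = 0.0
                    val = np.sqrt(dlat2) - r_tool
                    if -dax > val:
                        val = -dax
                    if val < tool[ix, iy, iz]:
                        tool[ix, iy, iz] = val


def _orient_outward(mesh: SurfaceMesh, sdf: np.ndarray, origin: np.ndarray, voxel: float) -> SurfaceMesh:
    """Flip face winding if normals point into the bone (negative SDF)."""
    rng = np.random.default_rng(0)
    k = min(200, len(mesh.faces))
    idx = rng.choice(len(mesh.faces), size=k, replace=False)
    tri = mesh.vertices[mesh.faces[idx]]
    centroids = tri.mean(axis=1)
    normals = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    normals /= np.maximum(np.linalg.norm(normals, axis=1, keepdims=True), 1e-30)
    probe = centroids + normals * (1.5 * voxel)
    ijk = np.round((probe - origin) / voxel).astype(int)
    ijk = np.clip(ijk, 0, np.array(sdf.shape) - 1)
    vals = sdf[ijk[:, 0], ijk[:, 1], ijk[:, 2]]
    if np.mean(vals > 0) < 0.5:
        return SurfaceMesh(mesh.vertices, mesh.faces[:, ::-1])
    return mesh
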