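"""Procedural triangle meshes for every organ of the tuber-root system.

The seed potato is a semi-ellipsoid (flat face up — the spent seed tuber),
the underground stem a stack of laterally jittered cone frusta (a rough,
irregular column), tubers are ellipsoids in three shape classes set by their
aspect ratio, and roots are tapering tubes swept along their growth-unit
axis with parallel-transport frames so the cross-section never twists at a
bend.

Meshes are lightweight (vertices, faces) records convertible to
``trimesh.Trimesh`` for validity checks, volume measurement, and OBJ/PLY
export.  The z-down world frame of the growth module is used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
import trimesh

from .growth import RootAxis

__all__ = [
    "Mesh",
    "TuberShapeClass",
    "seed_potato_mesh",
    "underground_stem_mesh",
    "classify_tuber",
    "tuber_mesh",
    "root_tube_mesh",
    "plant_scene",
]

#: aspect-ratio cutoffs separating spherical / ellipsoid / elongated tubers
SPHERICAL_MAX_RATIO = 1.15
ELLIPSOID_MAX_RATIO = 1.8


class TuberShapeClass(str, Enum):
    SPHERICAL = "spherical"
    ELLIPSOID = "ellipsoid"
    ELONGATED = "elongated"


@dataclass
class Mesh:
    vertices: np.ndarray  # (n, 3) mm
    faces: np.ndarray     # (m, 3) vertex indices

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, float)
        self.faces = np.asarray(self.faces, int)
        if not np.all(np.isfinite(self.vertices)):
            raise ValueError("mesh has non-finite vertices")
        if self.faces.size and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise ValueError("mesh face indices out of bounds")

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices, faces=self.faces, process=False
        )

    def volume(self) -> float:
        return float(abs(self.as_trimesh().volume))

    def export(self, path: str | Path) -> None:
        self.as_trimesh().export(str(path))


def _signed_volume(verts: np.ndarray, faces: np.ndarray) -> float:
    v = verts[faces]
    return float(np.einsum("ij,ij->", v[:, 0],
                           np.cross(v[:, 1], v[:, 2])) / 6.0)


def _outward(verts: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Flip a consistently wound closed surface to face outward."""
    if _signed_volume(verts, faces) < 0:
        return faces[:, ::-1]
    return faces


def _drop_degenerate(verts: np.ndarray, faces: np.ndarray,
                     tol: float = 1e-12) -> np.ndarray:
    v = verts[faces]
    areas = 0.5 * np.linalg.norm(
        np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]), axis=1
    )
    return faces[areas > tol]


def _lathe(profile_r: np.ndarray, profile_z: np.ndarray, resolution: int,
           centers: np.ndarray | None = None) -> Mesh:
    """Surface of revolution: rings of radius r_k at height z_k, stitched.

    ``centers`` optionally offsets each ring's center in (x, y).  Rings with
    zero radius collapse to an apex vertex; flat end rings are capped with a
    triangle fan.
    """
    resolution = int(resolution)
    if resolution < 3:
        raise ValueError("resolution must be >= 3")
    ang = np.linspace(0, 2 * np.pi, resolution, endpoint=False)
    cos_a, sin_a = np.cos(ang), np.sin(ang)
    if centers is None:
        centers = np.zeros((len(profile_r), 2))

    verts: list[np.ndarray] = []
    starts: list[int] = []
    apex: list[bool] = []  # True where a ring collapses to a point
    count = 0
    for r, z, (cx, cy) in zip(profile_r, profile_z, centers):
        starts.append(count)
        if r <= 0:
            verts.append(np.array([[cx, cy, z]]))
            apex.append(True)
            count += 1
        else:
            verts.append(
                np.column_stack([cx + r * cos_a, cy + r * sin_a,
                                 np.full(resolution, z)])
            )
            apex.append(False)
            count += resolution
    V = np.concatenate(verts)

    faces = []
    for k in range(len(starts) - 1):
        a, b = starts[k], starts[k + 1]
        if apex[k] and apex[k + 1]:
            continue
        if apex[k]:
            for j in range(resolution):
                faces.append([a, b + j, b + (j + 1) % resolution])
        elif apex[k + 1]:
            for j in range(resolution):
                faces.append([a + j, b, a + (j + 1) % resolution])
        else:
            for j in range(resolution):
                j2 = (j + 1) % resolution
                faces.append([a + j, b + j, b + j2])
                faces.append([a + j, b + j2, a + j2])
    # cap flat ends (wound to match the shell, which is built facing inward)
    if not apex[0]:
        c0 = len(V)
        V = np.vstack([V, [centers[0][0], centers[0][1], profile_z[0]]])
        for j in range(resolution):
            faces.append([c0, starts[0] + j,
                          starts[0] + (j + 1) % resolution])
    if not apex[-1]:
        c1 = len(V)
        V = np.vstack([V, [centers[-1][0], centers[-1][1], profile_z[-1]]])
        a = starts[-1]
        for j in range(resolution):
            faces.append([c1, a + (j + 1) % resolution, a + j])
    F = _outward(V, _drop_degenerate(V, np.asarray(faces, int)))
    return Mesh(vertices=V, faces=F)


def seed_potato_mesh(LS: float, WS: float, HS: float,
                     resolution: int = 32) -> Mesh:
    """Semi-ellipsoid seed potato: semi-axes LS/2, WS/2 and full height HS.

    The flat elliptical face sits at the top (local z = 0); the dome extends
    downward to z = HS in the z-down frame.  The surface is closed.
    """
    if LS <= 0 or WS <= 0 or HS <= 0:
        raise ValueError(f"seed potato dims must be > 0, got {LS}, {WS}, {HS}")
    n_rings = max(2, resolution // 2)
    phi = np.linspace(0, np.pi / 2, n_rings + 1)  # equator -> pole
    ring_r = np.cos(phi)          # unit profile, scaled per-axis below
    ring_r[np.abs(ring_r) < 1e-12] = 0.0  # exact apex at the pole
    ring_z = HS * np.sin(phi)
    mesh = _lathe(ring_r, ring_z, resolution)
    # anisotropic scale of the unit circle into the (LS/2, WS/2) ellipse
    V = mesh.vertices.copy()
    V[:, 0] *= LS / 2
    V[:, 1] *= WS / 2
    return Mesh(vertices=V, faces=mesh.faces)


def underground_stem_mesh(
    HD: float,
    RD: float,
    rD: float,
    n_segments: int = 8,
    jitter: float | None = None,
    rng: np.random.Generator | None = None,
    resolution: int = 24,
    base=(0.0, 0.0, 0.0),
) -> Mesh:
    """Stack of cone frusta rising from ``base``: a rough tapering stem.

    Ring ``k`` of ``n_segments + 1`` has radius ``RD * (1 - rD * k /
    n_segments)`` (global linear taper from RD down to RD*(1-rD)); interior
    ring centers are offset laterally by a uniform jitter in
    [-jitter, +jitter]^2 so the frustum centers are not collinear.  The stem
    grows upward, i.e. toward decreasing z in the z-down frame.
    """
    if HD <= 0 or RD <= 0:
        raise ValueError(f"stem height/radius must be > 0, got {HD}, {RD}")
    if rD >= 1:
        raise ValueError(f"radius change rate {rD} >= 1 gives radius <= 0")
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    if jitter is None:
        jitter = 0.05 * RD
    k = np.arange(n_segments + 1)
    radii = RD * (1 - rD * k / n_segments)
    z = -HD * k / n_segments  # upward
    centers = np.zeros((n_segments + 1, 2))
    if jitter > 0:
        if rng is None:
            rng = np.random.default_rng()
        centers[1:-1] = rng.uniform(-jitter, jitter, size=(n_segments - 1, 2))
    mesh = _lathe(radii, z, resolution, centers=centers)
    return Mesh(vertices=mesh.vertices + np.asarray(base, float),
                faces=mesh.faces)


def classify_tuber(L: float, W: float, H: float) -> TuberShapeClass:
    """Shape class from the aspect ratio of the two largest dimensions.

    With dimensions sorted L >= W >= H, the ratio L/W classifies the tuber:
    below 1.15 spherical, below 1.8 ellipsoid, else elongated.
    """
    if min(L, W, H) <= 0:
        raise ValueError(f"tuber dims must be > 0, got {L}, {W}, {H}")
    if not (L >= W >= H):
        L, W, H = sorted((L, W, H), reverse=True)
    ratio = L / W
    if ratio < SPHERICAL_MAX_RATIO:
        return TuberShapeClass.SPHERICAL
    if ratio < ELLIPSOID_MAX_RATIO:
        return TuberShapeClass.ELLIPSOID
    return TuberShapeClass.ELONGATED


def tuber_mesh(PK, LK: float, WK: float, HK: float,
               resolution: int = 32, horizontal: bool = True) -> Mesh:
    """Ellipsoid tuber centered at PK with semi-axes LK/2, WK/2, HK/2.

    By default the longest dimension lies along the horizontal x axis (the
    natural lie of a stolon-end tuber); pass ``horizontal=False`` to keep the
    raw (L, W, H) -> (x, y, z) assignment.
    """
    if min(LK, WK, HK) <= 0:
        raise ValueError(f"tuber dims must be > 0, got {LK}, {WK}, {HK}")
    if horizontal:
        LK, WK, HK = sorted((LK, WK, HK), reverse=True)
    n_rings = max(3, resolution // 2)
    phi = np.linspace(-np.pi / 2, np.pi / 2, n_rings + 1)
    ring_r = np.cos(phi)
    ring_r[np.abs(ring_r) < 1e-12] = 0.0  # exact apexes at both poles
    ring_z = np.sin(phi)
    mesh = _lathe(ring_r, ring_z, resolution)
    V = mesh.vertices.copy()
    V[:, 0] *= LK / 2
    V[:, 1] *= WK / 2
    V[:, 2] *= HK / 2
    return Mesh(vertices=V + np.asarray(PK, float), faces=mesh.faces)


def _parallel_transport_frames(points: np.ndarray) -> np.ndarray:
    """One orthonormal (normal, binormal) pair per vertex, twist-minimized."""
    tangents = np.diff(points, axis=0)
    tangents = tangents / np.linalg.norm(tangents, axis=1, keepdims=True)
    # vertex tangents: average of adjacent segment tangents
    vt = np.vstack([tangents[:1], tangents[:-1] + tangents[1:], tangents[-1:]])
    vt = vt / np.linalg.norm(vt, axis=1, keepdims=True)

    frames = np.zeros((len(points), 2, 3))
    seedvec = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(seedvec, vt[0])) > 0.9:
        seedvec = np.array([0.0, 0.0, 1.0])
    n = seedvec - np.dot(seedvec, vt[0]) * vt[0]
    n /= np.linalg.norm(n)
    frames[0, 0] = n
    frames[0, 1] = np.cross(vt[0], n)
    for i in range(1, len(points)):
        axis = np.cross(vt[i - 1], vt[i])
        s = np.linalg.norm(axis)
        c = np.clip(np.dot(vt[i - 1], vt[i]), -1.0, 1.0)
        n = frames[i - 1, 0]
        if s > 1e-12:
            axis = axis / s
            ang = np.arctan2(s, c)
            n = (n * np.cos(ang) + np.cross(axis, n) * np.sin(ang)
                 + axis * np.dot(axis, n) * (1 - np.cos(ang)))
        n = n - np.dot(n, vt[i]) * vt[i]
        n /= np.linalg.norm(n)
        frames[i, 0] = n
        frames[i, 1] = np.cross(vt[i], n)
    return frames


def root_tube_mesh(axis: RootAxis, resolution: int = 12) -> Mesh:
    """Sweep a linearly tapering circle along a root axis; capped ends.

    Cross-section radius runs from ``axis.r0`` at the rooting point to
    ``axis.r_tip`` at the tip; a zero tip radius closes the tube into a cone
    point without emitting degenerate faces.
    """
    pts = np.asarray(axis.points, float)
    if len(pts) < 2:
        raise ValueError("root tube needs an axis with >= 2 points")
    r0, r_tip = float(axis.r0), float(axis.r_tip)
    if not (r0 >= r_tip >= 0) or r0 <= 0:
        raise ValueError(f"need r0 >= r_tip >= 0 and r0 > 0, "
                         f"got r0={r0}, r_tip={r_tip}")
    arc = np.concatenate(
        [[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))]
    )
    radii = r0 + (r_tip - r0) * arc / arc[-1]
    frames = _parallel_transport_frames(pts)
    ang = np.linspace(0, 2 * np.pi, resolution, endpoint=False)
    cos_a, sin_a = np.cos(ang)[:, None], np.sin(ang)[:, None]

    verts = []
    starts, apex = [], []
    count = 0
    for p, r, (n, b) in zip(pts, radii, frames):
        starts.append(count)
        if r <= 0:
            verts.append(p[None, :])
            apex.append(True)
            count += 1
        else:
            verts.append(p + r * (cos_a * n + sin_a * b))
            apex.append(False)
            count += resolution
    V = np.concatenate(verts)

    faces = []
    for k in range(len(pts) - 1):
        a, b = starts[k], starts[k + 1]
        if apex[k + 1]:
            for j in range(resolution):
                faces.append([a + j, b, a + (j + 1) % resolution])
        else:
            for j in range(resolution):
                j2 = (j + 1) % resolution
                faces.append([a + j, b + j, b + j2])
                faces.append([a + j, b + j2, a + j2])
    # start cap (fan around the rooting point), wound to match the shell
    c0 = len(V)
    V = np.vstack([V, pts[0]])
    for j in range(resolution):
        faces.append([c0, starts[0] + j, starts[0] + (j + 1) % resolution])
    # tip cap if the tube stays open
    if not apex[-1]:
        c1 = len(V)
        V = np.vstack([V, pts[-1]])
        a = starts[-1]
        for j in range(resolution):
            faces.append([c1, a + (j + 1) % resolution, a + j])
    F = _outward(V, _drop_degenerate(V, np.asarray(faces, int)))
    return Mesh(vertices=V, faces=F)


def plant_scene(plant, resolution: int = 24,
                rng: np.random.Generator | None = None) -> trimesh.Scene:
    """Assemble one mesh per organ of a built plant into a named scene."""
    from .topology import PlantModel  # local import avoids a cycle

    assert isinstance(plant, PlantModel)
    scene = trimesh.Scene()
    if rng is None:
        rng = np.random.default_rng(plant.seed)
    for node in plant.nodes():
        name = f"{node.organ_class}_{node.node_id}"
        if node.organ_class == "seed_potato":
            m = seed_potato_mesh(
                node.params["length_mm"], node.params["width_mm"],
                node.params["height_mm"], resolution=resolution,
            )
            m = Mesh(m.vertices + node.position, m.faces)
        elif node.organ_class == "underground_stem":
            rd0 = node.params["bottom_radius_mm"]
            rd1 = node.params["top_radius_mm"]
            m = underground_stem_mesh(
                HD=node.params["height_mm"], RD=rd0,
                rD=1 - rd1 / rd0 if rd0 > 0 else 0.0,
                rng=rng, resolution=resolution, base=node.position,
            )
        elif node.organ_class == "tuber":
            m = tuber_mesh(
                node.position, node.params["length_mm"],
                node.params["width_mm"], node.params["height_mm"],
                resolution=resolution,
            )
        else:  # a root or creeping stem: swept tube
            if node.axis is None or node.axis.r0 <= 0:
                continue
            m = root_tube_mesh(node.axis, resolution=max(8, resolution // 2))
        scene.add_geometry(m.as_trimesh(), geom_name=name)
    return scene
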