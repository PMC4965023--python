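"""Voxelization of synthetic spines and contour recovery from label maps.

``rasterize`` sweeps each vertebra as the convex blend of its two endplate
ellipse rings (plus a posterior canal tube and an S1 block) into an integer
label volume; ``extract_contours`` recovers, per vertebra label, the
cranial-most and caudal-most voxel layers, fits trimmed least-squares planes
and rebuilds boundary contours, emulating a segmentation round trip.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull

from .levels import ALL_LEVELS, level_index
from .spine_model import DegenerateGeometryError, EndplateContour, SubjectContours, fit_endplate_plane

__all__ = ["LabeledVolume", "ResolutionError", "rasterize", "extract_contours", "CANAL_LABEL", "level_label"]

CANAL_LABEL = 100
CANAL_RADIUS_MM = 5.0
S1_DEPTH_MM = 30.0


class ResolutionError(ValueError):
    """Raised when voxel spacing is too coarse for the requested geometry."""


def level_label(level: str) -> int:
    """Integer label of a vertebra (T1 = 1 ... L5 = 17, S1 = 18)."""
    return level_index(level) + 1


LABEL_TO_LEVEL = {level_label(lv): lv for lv in ALL_LEVELS}


@dataclass
class LabeledVolume:
    """Integer label map: 0 background, per-vertebra labels, canal label."""

    data: np.ndarray  # (nx, ny, nz) int16
    spacing: np.ndarray  # (3,) mm
    origin: np.ndarray  # (3,) mm, world position of voxel (0, 0, 0) center
    orientation: str = "RAS"

    def __post_init__(self) -> None:
        self.spacing = np.broadcast_to(np.asarray(self.spacing, dtype=float), (3,)).copy()
        self.origin = np.asarray(self.origin, dtype=float)
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacing must be > 0")

    def world_coords(self, idx: np.ndarray) -> np.ndarray:
        return self.origin + np.asarray(idx, dtype=float) * self.spacing

    @property
    def labels(self) -> list[int]:
        return sorted(int(v) for v in np.unique(self.data) if v != 0)


def _fill_convex(data: np.ndarray, origin: np.ndarray, spacing: np.ndarray, vertices: np.ndarray, label: int) -> None:
    """Set ``label`` on all voxels whose centers lie inside the convex hull of
    ``vertices`` (only where the voxel is still background or canal)."""
    try:
        hull = ConvexHull(vertices)
    except Exception as exc:  # pragma: no cover - degenerate input
        raise DegenerateGeometryError(f"cannot hull label {label}: {exc}") from exc
    lo = np.maximum(np.floor((vertices.min(axis=0) - origin) / spacing).astype(int), 0)
    hi = np.minimum(np.ceil((vertices.max(axis=0) - origin) / spacing).astype(int) + 1, data.shape)
    if np.any(hi <= lo):
        return
    ii, jj, kk = np.meshgrid(*(np.arange(a, b) for a, b in zip(lo, hi)), indexing="ij")
    pts = origin + np.stack([ii, jj, kk], axis=-1) * spacing
    # hull.equations: A x + b <= 0 inside
    inside = (pts @ hull.equations[:, :3].T + hull.equations[:, 3]).max(axis=-1) <= 1e-9
    sub = data[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    sub[inside & (sub == 0)] = label


def rasterize(subject: SubjectContours, spacing: float | np.ndarray = 0.6, margin_mm: float = 8.0) -> LabeledVolume:
    """Voxelize a contour subject into a label map.

    Vertebra solids are the convex blend of the two endplate rings; the canal
    is a tube through the canal centroids; S1 is a block extruded caudally
    from the sacral plate.
    """
    spacing = np.broadcast_to(np.asarray(spacing, dtype=float), (3,)).copy()
    if np.any(spacing < 0.3):
        raise ResolutionError("voxel spacing must be >= 0.3 mm")
    if np.any(spacing > 3.0):
        raise ResolutionError("voxel spacing too coarse to separate adjacent vertebrae")

    by_level: dict[str, dict[str, EndplateContour]] = {}
    for c in subject.contours:
        by_level.setdefault(c.level, {})[c.side] = c

    all_pts = np.vstack([c.points for c in subject.contours])
    origin = all_pts.min(axis=0) - margin_mm
    extent = all_pts.max(axis=0) + margin_mm - origin
    shape = tuple(np.ceil(extent / spacing).astype(int) + 1)
    data = np.zeros(shape, dtype=np.int16)

    for level, sides in by_level.items():
        if level == "S1":
            plate = sides["superior"]
            _, normal = fit_endplate_plane(plate.points, "S1")
            verts = np.vstack([plate.points, plate.points - S1_DEPTH_MM * normal])
        else:
            if "superior" not in sides or "inferior" not in sides:
                continue
            verts = np.vstack([sides["superior"].points, sides["inferior"].points])
        _fill_convex(data, origin, spacing, verts, level_label(level))

    # canal tube through the canal centroids, caudal to cranial
    centroids = sorted((c.canal_centroid for c in subject.contours), key=lambda p: p[2])
    theta = np.linspace(0.0, 2.0 * np.pi, 16, endpoint=False)
    for a, b in zip(centroids, centroids[1:]):
        axis = b - a
        nax = np.linalg.norm(axis)
        if nax < 1e-6:
            continue
        axis = axis / nax
        seed = np.zeros(3)
        seed[int(np.argmin(np.abs(axis)))] = 1.0
        u = np.cross(seed, axis)
        u /= np.linalg.norm(u)
        v = np.cross(axis, u)
        ring = CANAL_RADIUS_MM * (np.outer(np.cos(theta), u) + np.outer(np.sin(theta), v))
        _fill_convex(data, origin, spacing, np.vstack([a + ring, b + ring]), CANAL_LABEL)

    return LabeledVolume(data=data, spacing=spacing, origin=origin)


def _label_points(volume: LabeledVolume, label: int) -> np.ndarray:
    idx = np.stack(np.nonzero(volume.data == label), axis=1)
    if len(idx) == 0:
        raise DegenerateGeometryError(f"label {label} absent from volume")
    return volume.world_coords(idx)


def _top_layer_points(volume: LabeledVolume, label: int, top: bool, axis: np.ndarray) -> np.ndarray:
    """Outermost voxel layer of a label along ``axis`` (the vertebra's local
    cranial direction): per column perpendicular to the axis, the voxel with
    extremal axial coordinate."""
    pts = _label_points(volume, label)
    axis = axis / np.linalg.norm(axis)
    seed = np.zeros(3)
    seed[int(np.argmin(np.abs(axis)))] = 1.0
    u = np.cross(seed, axis)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    h = float(volume.spacing.max())
    ia = np.round(pts @ u / h).astype(int)
    ib = np.round(pts @ v / h).astype(int)
    s = pts @ axis
    order = np.lexsort((s if top else -s, ib, ia))
    ia_o, ib_o = ia[order], ib[order]
    last = np.ones(len(order), dtype=bool)
    last[:-1] = (ia_o[1:] != ia_o[:-1]) | (ib_o[1:] != ib_o[:-1])
    return pts[order[last]]


def _layer_contour(volume: LabeledVolume, label: int, level: str, side: str, axis: np.ndarray) -> EndplateContour:
    pts = _top_layer_points(volume, label, top=(side == "superior"), axis=axis)
    band = 1.2 * float(np.linalg.norm(volume.spacing))
    # trimmed plane fit: the layer contains the planar endplate face plus rim
    # points from the lateral wall; iterating the fit on in-band points
    # converges onto the face
    center, normal = fit_endplate_plane(pts, f"{level} {side}")
    face = pts
    for _ in range(4):
        resid = (pts - center) @ normal
        inliers = pts[np.abs(resid) <= band]
        if len(inliers) < 12:
            break
        face = inliers
        center, normal = fit_endplate_plane(face, f"{level} {side}")
    flat = face - np.outer((face - center) @ normal, normal)
    seed = np.zeros(3)
    seed[int(np.argmin(np.abs(normal)))] = 1.0
    u = np.cross(seed, normal)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    xy = np.stack([(flat - center) @ u, (flat - center) @ v], axis=1)
    hull = ConvexHull(xy)
    boundary = flat[hull.vertices]
    if len(boundary) < 12:
        raise ResolutionError(f"{level} {side}: voxel spacing too coarse, endplate hull has {len(boundary)} vertices")

    canal_mask = volume.data == CANAL_LABEL
    ci = np.stack(np.nonzero(canal_mask), axis=1)
    cw = volume.world_coords(ci)
    slab = 2.0 * float(np.linalg.norm(volume.spacing))
    near = cw[np.abs((cw - center) @ normal) <= slab]
    if len(near) == 0:
        near = cw[np.abs((cw - center) @ normal) <= 2 * slab]
    if len(near) == 0:
        raise DegenerateGeometryError(f"{level} {side}: no canal voxels near endplate plane")
    return EndplateContour(level=level, side=side, points=boundary, canal_centroid=near.mean(axis=0))


def extract_contours(volume: LabeledVolume, subject_id: str = "extracted") -> SubjectContours:
    """Rebuild endplate contours from a label volume (inverse of ``rasterize``
    up to voxel resolution).

    Each vertebra's local cranial axis is estimated from the centroids of the
    neighbouring labels, so endplate layers are taken along the (possibly
    strongly tilted) local spine direction rather than the global z axis.
    """
    vert_labels = [lb for lb in volume.labels if lb != CANAL_LABEL]
    levels = {}
    for lb in vert_labels:
        level = LABEL_TO_LEVEL.get(lb)
        if level is None:
            raise DegenerateGeometryError(f"unknown vertebra label {lb}")
        levels[lb] = level
    centroids = {lb: _label_points(volume, lb).mean(axis=0) for lb in vert_labels}
    ordered = sorted(vert_labels, key=lambda lb: level_index(levels[lb]))

    def local_axis(i: int) -> np.ndarray:
        above = centroids[ordered[i - 1]] if i > 0 else centroids[ordered[i]]
        below = centroids[ordered[i + 1]] if i + 1 < len(ordered) else centroids[ordered[i]]
        axis = above - below
        if np.linalg.norm(axis) < 1e-6:
            axis = np.array([0.0, 0.0, 1.0])
        return axis

    contours: list[EndplateContour] = []
    for i, lb in enumerate(ordered):
        level = levels[lb]
        axis = local_axis(i)
        if level == "S1":
            contours.append(_layer_contour(volume, lb, level, "superior", axis))
        else:
            contours.append(_layer_contour(volume, lb, level, "superior", axis))
            contours.append(_layer_contour(volume, lb, level, "inferior", axis))
    return SubjectContours(subject_id=subject_id, contours=contours)
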