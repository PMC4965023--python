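"""Domain types and per-endplate geometric primitives.

World frame convention (all coordinates, all types, in mm):

* ``+x`` patient left -> right
* ``+y`` posterior -> anterior
* ``+z`` caudal -> cranial (right-handed)

The transverse plane is normal to ``+z`` and the coronal plane is normal to
``+y``.  Canonically-posed subjects satisfy this exactly; for subjects that
have undergone an unknown rigid motion every projection-based quantity can be
anchored to the sacral plate instead (see :class:`AnatomicalFrame`), which
makes all derived metrics rigid-motion invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .levels import level_index

__all__ = [
    "DegenerateGeometryError",
    "DegenerateProjectionError",
    "IncompleteSubjectError",
    "EndplateContour",
    "EndplateGeometry",
    "Vertebra",
    "SpineModel",
    "SubjectContours",
    "ElementHeights",
    "AnatomicalFrame",
    "fit_endplate_plane",
    "contour_centroid",
    "ap_axis",
    "extreme_points",
    "axial_rotation",
    "coronal_cobb",
    "coronal_tilt",
    "endplate_geometry",
    "build_spine_model",
]


class DegenerateGeometryError(ValueError):
    """Raised when contour geometry is degenerate (collinear, zero area...)."""


class DegenerateProjectionError(DegenerateGeometryError):
    """Raised when a projection collapses a direction to (near) zero length."""


class IncompleteSubjectError(ValueError):
    """Raised when a subject is missing required endplates."""


def _unit(v: np.ndarray, err: str | None = None) -> np.ndarray:
    n = float(np.linalg.norm(v))
    if n < 1e-9:
        raise DegenerateProjectionError(err or "zero-length direction")
    return np.asarray(v, dtype=float) / n


# ---------------------------------------------------------------------------
# elementary operations


def fit_endplate_plane(points: np.ndarray, label: str = "contour") -> tuple[np.ndarray, np.ndarray]:
    """Least-squares plane through a 3-D point set.

    Returns ``(plane_point, unit_normal)`` where ``plane_point`` is the vertex
    mean and the normal minimises the sum of squared point-plane distances
    (smallest right singular vector of the centred points).  The normal is
    oriented into the ``+z`` hemisphere for determinism.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise DegenerateGeometryError(f"{label}: need >=3 points, got shape {pts.shape}")
    center = pts.mean(axis=0)
    centered = pts - center
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    # collinear / duplicated input: no second spread direction
    if s[1] <= max(1e-9, 1e-9 * s[0]):
        raise DegenerateGeometryError(f"{label}: degenerate geometry (collinear or duplicate points)")
    normal = vt[2]
    zdot = normal[2]
    if zdot < 0 or (zdot == 0 and (normal[0] < 0 or (normal[0] == 0 and normal[1] < 0))):
        normal = -normal
    return center, normal


def _plane_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic orthonormal in-plane basis ``(u, v)`` with ``u x v = n``."""
    seed = np.zeros(3)
    seed[int(np.argmin(np.abs(normal)))] = 1.0
    u = _unit(np.cross(seed, normal))
    v = np.cross(normal, u)
    return u, v


def contour_centroid(points: np.ndarray, label: str = "contour") -> np.ndarray:
    """Area-weighted centroid of the closed contour polygon in its fitted
    plane (shoelace formula on the in-plane projection, not the vertex mean).
    """
    pts = np.asarray(points, dtype=float)
    center, normal = fit_endplate_plane(pts, label)
    u, v = _plane_basis(normal)
    rel = pts - center
    x, y = rel @ u, rel @ v
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    area2 = float(cross.sum())
    if abs(area2) < 1e-9:
        raise DegenerateGeometryError(f"{label}: zero-area polygon")
    cx = float(((x + xn) * cross).sum() / (3.0 * area2))
    cy = float(((y + yn) * cross).sum() / (3.0 * area2))
    return center + cx * u + cy * v


def ap_axis(endplate_centroid: np.ndarray, canal_centroid: np.ndarray, plane_normal: np.ndarray) -> np.ndarray:
    """Unit anterior-posterior axis of one endplate.

    Direction from the spinal-canal centroid toward the endplate centroid,
    projected into the endplate plane and normalised; points anteriorly.
    """
    d = np.asarray(endplate_centroid, dtype=float) - np.asarray(canal_centroid, dtype=float)
    if np.linalg.norm(d) < 1e-9:
        raise DegenerateGeometryError("canal and endplate centroids coincide")
    n = _unit(plane_normal)
    in_plane = d - (d @ n) * n
    return _unit(in_plane, "canal-centroid direction is perpendicular to the endplate plane")


def extreme_points(points: np.ndarray, axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Most anterior and most posterior contour vertices.

    The anterior (posterior) point maximises (minimises) the scalar projection
    on ``axis``; ties are broken by the lowest vertex index.
    """
    pts = np.asarray(points, dtype=float)
    proj = pts @ np.asarray(axis, dtype=float)
    return pts[int(np.argmax(proj))].copy(), pts[int(np.argmin(proj))].copy()


def axial_rotation(ap: np.ndarray, sacral_ap: np.ndarray, up: np.ndarray = (0.0, 0.0, 1.0)) -> float:
    """Signed transverse-plane angle (degrees) between an endplate AP axis and
    the sacral-plate AP axis.

    Both axes are projected into the plane normal to ``up`` (the transverse
    plane).  Right-sided rotation — the anterior tip swung toward patient
    right — is positive.  Range ``(-180, 180]``.
    """
    upv = _unit(np.asarray(up, dtype=float))
    a = np.asarray(ap, dtype=float)
    s = np.asarray(sacral_ap, dtype=float)
    a = a - (a @ upv) * upv
    s = s - (s @ upv) * upv
    if np.linalg.norm(a) < 1e-6 or np.linalg.norm(s) < 1e-6:
        raise DegenerateProjectionError("AP axis degenerate after transverse projection")
    ccw = float(np.arctan2(upv @ np.cross(s, a), s @ a))
    deg = -np.degrees(ccw)  # clockwise seen from cranial = toward patient right = positive
    if deg <= -180.0:
        deg += 360.0
    return float(deg)


def _coronal_tangent(plane_normal: np.ndarray, coronal_normal: np.ndarray) -> np.ndarray:
    t = np.cross(np.asarray(plane_normal, dtype=float), _unit(np.asarray(coronal_normal, dtype=float)))
    if np.linalg.norm(t) < 1e-6:
        raise DegenerateProjectionError("endplate plane is parallel to the coronal plane")
    return _unit(t)


def coronal_cobb(upper: "EndplateGeometry", lower: "EndplateGeometry", coronal_normal: np.ndarray = (0.0, 1.0, 0.0)) -> float:
    """Cobb angle (degrees, unsigned, ``[0, 180)``) between two endplates.

    Each endplate contributes its medio-lateral tangent, the intersection line
    of its plane with the coronal plane; the returned value is the angle
    between the two tangents.  Endplate normals are oriented cranially, which
    makes the tangent orientations consistent.
    """
    t1 = _coronal_tangent(upper.plane_normal, coronal_normal)
    t2 = _coronal_tangent(lower.plane_normal, coronal_normal)
    return float(np.degrees(np.arccos(np.clip(t1 @ t2, -1.0, 1.0))))


def coronal_tilt(plane_normal: np.ndarray, frame: "AnatomicalFrame | None" = None) -> float:
    """Signed coronal inclination (degrees) of an endplate: positive when the
    endplate normal tips toward patient right."""
    f = frame or AnatomicalFrame.identity()
    n = np.asarray(plane_normal, dtype=float)
    return float(np.degrees(np.arctan2(n @ f.x, n @ f.z)))


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class AnatomicalFrame:
    """Right-handed reference frame: x = right, y = anterior, z = cranial."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray

    @classmethod
    def identity(cls) -> "AnatomicalFrame":
        return cls(np.array([1.0, 0, 0]), np.array([0, 1.0, 0]), np.array([0, 0, 1.0]))

    @classmethod
    def from_sacral_plate(cls, sacral: "EndplateGeometry") -> "AnatomicalFrame":
        """Anchor the patient frame to the sacral plate: z = plate normal,
        y = plate AP axis, x = y cross z.  Equals the identity frame for a
        canonically posed subject and follows the subject under rigid motion.
        """
        z = _unit(sacral.plane_normal)
        y = _unit(sacral.ap_axis - (sacral.ap_axis @ z) * z)
        return cls(np.cross(y, z), y, z)


@dataclass
class EndplateContour:
    """Closed endplate boundary loop plus the matching canal centroid."""

    level: str
    side: str  # "superior" | "inferior"
    points: np.ndarray  # (n, 3) mm, ordered loop
    canal_centroid: np.ndarray  # (3,) mm

    MAX_PLANE_RESIDUAL_MM = 1.5

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.canal_centroid = np.asarray(self.canal_centroid, dtype=float)
        level_index(self.level)
        if self.side not in ("superior", "inferior"):
            raise ValueError(f"{self.level}: invalid endplate side {self.side!r}")
        if self.points.ndim != 2 or self.points.shape[1] != 3 or self.points.shape[0] < 12:
            raise DegenerateGeometryError(f"{self.level} {self.side}: contour needs >=12 3-D points")

    @property
    def label(self) -> str:
        return f"{self.level} {self.side}"

    def validate(self) -> None:
        """Check planarity and canal placement invariants."""
        center, normal = fit_endplate_plane(self.points, self.label)
        resid = np.abs((self.points - center) @ normal)
        if resid.max() > self.MAX_PLANE_RESIDUAL_MM:
            raise DegenerateGeometryError(
                f"{self.label}: max point-to-plane residual {resid.max():.2f} mm exceeds "
                f"{self.MAX_PLANE_RESIDUAL_MM} mm"
            )
        centroid = contour_centroid(self.points, self.label)
        axis = ap_axis(centroid, self.canal_centroid, normal)
        # the AP axis is derived from the canal, so "canal posterior of the
        # centroid" holds by construction; the detectable failure mode is a
        # canal centroid inside the endplate outline
        posterior_rim = float((self.points @ axis).min())
        if float(self.canal_centroid @ axis) >= posterior_rim:
            raise DegenerateGeometryError(
                f"{self.label}: canal centroid lies inside the endplate outline instead of posterior of it"
            )


@dataclass
class EndplateGeometry:
    """Fitted plane, centroids, AP axis and extreme landmarks of one endplate."""

    level: str
    side: str
    plane_point: np.ndarray
    plane_normal: np.ndarray  # unit, +z hemisphere
    endplate_centroid: np.ndarray
    canal_centroid: np.ndarray
    ap_axis: np.ndarray  # unit, in-plane, anterior
    anterior_point: np.ndarray
    posterior_point: np.ndarray
    axial_rotation_deg: float = float("nan")  # vs sacral plate; set on model assembly

    @property
    def label(self) -> str:
        return f"{self.level} {self.side}"


def endplate_geometry(contour: EndplateContour) -> EndplateGeometry:
    """Full per-endplate geometric readout for one contour."""
    plane_point, normal = fit_endplate_plane(contour.points, contour.label)
    centroid = contour_centroid(contour.points, contour.label)
    axis = ap_axis(centroid, contour.canal_centroid, normal)
    if float(contour.canal_centroid @ axis) >= float((contour.points @ axis).min()):
        raise DegenerateGeometryError(f"{contour.label}: canal centroid lies inside the endplate outline")
    ant, post = extreme_points(contour.points, axis)
    if (ant - post) @ axis <= 0:
        raise DegenerateGeometryError(f"{contour.label}: anterior/posterior landmarks are inverted")
    return EndplateGeometry(
        level=contour.level,
        side=contour.side,
        plane_point=plane_point,
        plane_normal=normal,
        endplate_centroid=centroid,
        canal_centroid=contour.canal_centroid.copy(),
        ap_axis=axis,
        anterior_point=ant,
        posterior_point=post,
    )


@dataclass
class Vertebra:
    level: str
    superior: EndplateGeometry
    inferior: EndplateGeometry

    @property
    def centroid(self) -> np.ndarray:
        return 0.5 * (self.superior.endplate_centroid + self.inferior.endplate_centroid)

    @property
    def axial_rotation_deg(self) -> float:
        return 0.5 * (self.superior.axial_rotation_deg + self.inferior.axial_rotation_deg)


@dataclass
class SpineModel:
    """Ordered per-level endplate geometries plus the S1 sacral plate."""

    vertebrae: list[Vertebra]  # craniocaudal
    sacral_plate: EndplateGeometry
    subject_id: str = "subject"

    def __post_init__(self) -> None:
        self._by_level = {v.level: v for v in self.vertebrae}

    @property
    def levels(self) -> list[str]:
        return [v.level for v in self.vertebrae]

    def vertebra(self, level: str) -> Vertebra:
        try:
            return self._by_level[level]
        except KeyError:
            raise IncompleteSubjectError(f"{self.subject_id}: level {level} not present") from None

    @property
    def frame(self) -> AnatomicalFrame:
        return AnatomicalFrame.from_sacral_plate(self.sacral_plate)

    def validate(self) -> None:
        idx = [level_index(v.level) for v in self.vertebrae]
        if idx != sorted(idx) or len(set(idx)) != len(idx):
            raise IncompleteSubjectError(f"{self.subject_id}: levels not strictly ordered craniocaudally")
        if idx and idx != list(range(idx[0], idx[0] + len(idx))):
            raise IncompleteSubjectError(f"{self.subject_id}: vertebral levels are not contiguous")
        if self.vertebrae and self.vertebrae[-1].level != "L5":
            raise IncompleteSubjectError(f"{self.subject_id}: model must extend through L5")
        z = self.frame.z
        heights = []
        for v in self.vertebrae:
            heights.append(float(v.superior.endplate_centroid @ z))
            heights.append(float(v.inferior.endplate_centroid @ z))
        heights.append(float(self.sacral_plate.endplate_centroid @ z))
        if any(b >= a for a, b in zip(heights, heights[1:])):
            raise IncompleteSubjectError(f"{self.subject_id}: endplate centroids not monotone craniocaudally")


@dataclass
class SubjectContours:
    """Raw contour representation of one subject (the interchange object)."""

    subject_id: str
    contours: list[EndplateContour]
    group: str = "unknown"
    meta: dict = field(default_factory=dict)

    def copy(self) -> "SubjectContours":
        return SubjectContours(
            subject_id=self.subject_id,
            contours=[
                replace(c, points=c.points.copy(), canal_centroid=c.canal_centroid.copy()) for c in self.contours
            ],
            group=self.group,
            meta=dict(self.meta),
        )


@dataclass(frozen=True)
class ElementHeights:
    """Anterior and posterior height of one vertebra or disc."""

    element_id: str
    anterior_mm: float
    posterior_mm: float


def build_spine_model(subject: SubjectContours, validate_contours: bool = False) -> SpineModel:
    """Assemble a :class:`SpineModel` from raw contours.

    Computes every per-endplate geometry, anchors the anatomical frame to the
    sacral plate and fills in axial rotations (signed vs the sacral AP axis in
    the sacral transverse plane).
    """
    sacral_contour = None
    per_level: dict[str, dict[str, EndplateGeometry]] = {}
    for c in subject.contours:
        if validate_contours:
            c.validate()
        if c.level == "S1":
            if c.side != "superior":
                raise IncompleteSubjectError(f"{subject.subject_id}: S1 contributes only its superior plate")
            sacral_contour = c
            continue
        per_level.setdefault(c.level, {})[c.side] = endplate_geometry(c)
    if sacral_contour is None:
        raise IncompleteSubjectError(f"{subject.subject_id}: missing S1 sacral plate")
    sacral = endplate_geometry(sacral_contour)

    vertebrae = []
    for level in sorted(per_level, key=level_index):
        sides = per_level[level]
        for side in ("superior", "inferior"):
            if side not in sides:
                raise IncompleteSubjectError(f"{subject.subject_id}: level {level} missing {side} endplate")
        vertebrae.append(Vertebra(level=level, superior=sides["superior"], inferior=sides["inferior"]))

    model = SpineModel(vertebrae=vertebrae, sacral_plate=sacral, subject_id=subject.subject_id)
    frame = model.frame
    sacral.axial_rotation_deg = 0.0
    for v in vertebrae:
        for g in (v.superior, v.inferior):
            g.axial_rotation_deg = axial_rotation(g.ap_axis, sacral.ap_axis, up=frame.z)
    model.validate()
    return model
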