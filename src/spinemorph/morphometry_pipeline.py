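"""Measurement pipeline: endplate geometry -> element heights -> curve and
region decomposition -> per-region metrics.

All projection-based quantities (coronal tilt, Cobb, axial rotation) are
referenced to the anatomical frame anchored on the sacral plate, which makes
every metric invariant under a rigid motion of the whole subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .levels import is_vertebra, level_index, neighbor, span_elements
from .spine_model import (
    AnatomicalFrame,
    ElementHeights,
    IncompleteSubjectError,
    SpineModel,
    SubjectContours,
    Vertebra,
    build_spine_model,
    coronal_cobb,
    coronal_tilt,
)

__all__ = [
    "PipelineConfig",
    "RegionSpec",
    "RegionMetrics",
    "Curve",
    "element_heights",
    "region_lengths",
    "delta_ap",
    "detect_curves",
    "define_regions",
    "measure_subject",
    "measure_contours",
    "measure_cohort",
    "COHORT_COLUMNS",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable thresholds of the measurement stage."""

    cobb_floor_deg: float = 10.0  # curves below this Cobb are discarded
    tilt_smoothing_window: int = 1  # moving-average window on the endplate tilt sequence (1 = off)
    curve_overrides: tuple = ()  # optional (upper, apex, lower, convexity) tuples replacing detection


@dataclass(frozen=True)
class RegionSpec:
    """A named contiguous span of vertebrae and discs."""

    name: str
    elements: tuple[str, ...]
    end_vertebrae: tuple[str, str] | None = None  # curves only
    apex: str | None = None  # curves and apical zones

    def __post_init__(self) -> None:
        verts = [e for e in self.elements if is_vertebra(e)]
        expected = tuple(span_elements(verts[0], verts[-1]))
        if expected != tuple(self.elements):
            raise ValueError(f"region {self.name}: elements are not a contiguous vertebra/disc span")
        if self.name in ("proximal_junctional", "distal_junctional") and len(self.elements) != 3:
            raise ValueError(f"region {self.name}: junctional segments are 2 vertebrae + 1 disc")
        if self.name.startswith("apical") and len(self.elements) != 5:
            raise ValueError(f"region {self.name}: apical zones are 3 vertebrae + 2 discs")

    @property
    def vertebrae(self) -> list[str]:
        return [e for e in self.elements if is_vertebra(e)]


@dataclass(frozen=True)
class RegionMetrics:
    region: str
    cobb_deg: float
    axial_rotation_deg: float
    anterior_mm: float
    posterior_mm: float
    delta_ap_percent: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "delta_ap_percent", delta_ap(self.anterior_mm, self.posterior_mm))


@dataclass(frozen=True)
class Curve:
    upper_end: str
    apex: str
    lower_end: str
    convexity: str  # "right" | "left"
    cobb_deg: float


def delta_ap(anterior_mm: float, posterior_mm: float) -> float:
    """Relative anterior-posterior length discrepancy in percent:
    ``(anterior - posterior) / posterior * 100``.  Positive values indicate
    greater anterior length."""
    if posterior_mm <= 0:
        raise ValueError(f"posterior length must be > 0, got {posterior_mm}")
    return (anterior_mm - posterior_mm) / posterior_mm * 100.0


def element_heights(spine: SpineModel) -> list[ElementHeights]:
    """Anterior and posterior heights of every vertebra and disc.

    A vertebra's anterior height is the Euclidean distance between the
    anterior landmarks of its superior and inferior endplates; disc heights
    span the facing endplates of adjacent vertebrae (the disc below the most
    caudal vertebra reaches the sacral plate).  Posterior elements are not
    part of any height.
    """
    out: list[ElementHeights] = []

    def dist(a: np.ndarray, b: np.ndarray) -> float:
        return float(np.linalg.norm(a - b))

    verts = spine.vertebrae
    for i, v in enumerate(verts):
        out.append(
            ElementHeights(
                element_id=v.level,
                anterior_mm=dist(v.superior.anterior_point, v.inferior.anterior_point),
                posterior_mm=dist(v.superior.posterior_point, v.inferior.posterior_point),
            )
        )
        below = verts[i + 1].superior if i + 1 < len(verts) else spine.sacral_plate
        below_level = verts[i + 1].level if i + 1 < len(verts) else "S1"
        if level_index(below_level) != level_index(v.level) + 1:
            raise IncompleteSubjectError(f"{spine.subject_id}: gap between {v.level} and {below_level}")
        out.append(
            ElementHeights(
                element_id=f"{v.level}-{below_level}",
                anterior_mm=dist(v.inferior.anterior_point, below.anterior_point),
                posterior_mm=dist(v.inferior.posterior_point, below.posterior_point),
            )
        )
    return out


def region_lengths(heights: list[ElementHeights], region: RegionSpec) -> tuple[float, float]:
    """Summed anterior and posterior lengths over a region's elements."""
    if not region.elements:
        raise ValueError(f"region {region.name}: empty element list")
    by_id = {h.element_id: h for h in heights}
    missing = [e for e in region.elements if e not in by_id]
    if missing:
        raise IncompleteSubjectError(f"region {region.name}: missing heights for {missing}")
    anterior = sum(by_id[e].anterior_mm for e in region.elements)
    posterior = sum(by_id[e].posterior_mm for e in region.elements)
    return float(anterior), float(posterior)


# ---------------------------------------------------------------------------
# curve detection


def _endplate_sequence(spine: SpineModel) -> list[tuple[Vertebra, str]]:
    seq = []
    for v in spine.vertebrae:
        seq.append((v, "superior"))
        seq.append((v, "inferior"))
    return seq


def _local_extrema(values: np.ndarray) -> list[int]:
    d = np.diff(values)
    signs = np.sign(d)
    # carry the previous sign through exact plateaus
    for i in range(1, len(signs)):
        if signs[i] == 0:
            signs[i] = signs[i - 1]
    out = []
    for i in range(1, len(signs)):
        if signs[i] != 0 and signs[i - 1] != 0 and signs[i] != signs[i - 1]:
            out.append(i)
    return out


def detect_curves(spine: SpineModel, config: PipelineConfig = PipelineConfig()) -> list[Curve]:
    """Scan the coronal tilt sequence of all endplates for curves.

    End vertebrae own the endplates of locally extremal coronal tilt; the
    apex is the vertebra with maximal perpendicular coronal-plane distance
    from the end-vertebra chord (ties broken cranially).  Curves below the
    Cobb floor are discarded; a straight spine yields an empty list.
    """
    if config.curve_overrides:
        return [
            Curve(
                upper_end=u,
                apex=a,
                lower_end=lo,
                convexity=conv,
                cobb_deg=coronal_cobb(
                    spine.vertebra(u).superior, spine.vertebra(lo).inferior, coronal_normal=spine.frame.y
                ),
            )
            for (u, a, lo, conv) in config.curve_overrides
        ]
    if len(spine.vertebrae) < 5:
        raise IncompleteSubjectError(f"{spine.subject_id}: need >= 5 vertebrae for curve detection")
    frame = spine.frame
    seq = _endplate_sequence(spine)
    tilts = np.array([coronal_tilt(getattr(v, side).plane_normal, frame) for v, side in seq])
    w = max(1, int(config.tilt_smoothing_window))
    if w > 1:
        kernel = np.ones(w) / w
        tilts = np.convolve(np.pad(tilts, w // 2, mode="edge"), kernel, mode="valid")[: len(seq)]

    boundaries = [0] + _local_extrema(tilts) + [len(seq) - 1]
    curves: list[Curve] = []
    for b1, b2 in zip(boundaries, boundaries[1:]):
        upper_v = seq[b1][0]
        lower_v = seq[b2][0]
        iu, il = level_index(upper_v.level), level_index(lower_v.level)
        if il - iu < 2:
            continue
        cobb = coronal_cobb(upper_v.superior, lower_v.inferior, coronal_normal=frame.y)
        if cobb < config.cobb_floor_deg:
            continue
        # apex: max perpendicular coronal deviation from the end-vertebra chord
        span = [v for v in spine.vertebrae if iu <= level_index(v.level) <= il]
        xz = np.array([[v.centroid @ frame.x, v.centroid @ frame.z] for v in span])
        chord = xz[-1] - xz[0]
        chord = chord / np.linalg.norm(chord)
        signed = (xz - xz[0]) @ np.array([-chord[1], chord[0]])  # +x side positive for a craniocaudal chord
        inner = signed[1:-1]
        if len(inner) == 0:
            continue
        k = 1 + int(np.argmax(np.abs(inner)))
        curves.append(
            Curve(
                upper_end=upper_v.level,
                apex=span[k].level,
                lower_end=lower_v.level,
                convexity="right" if signed[k] > 0 else "left",
                cobb_deg=cobb,
            )
        )
    return curves


# ---------------------------------------------------------------------------
# region construction


def _classify_curves(curves: list[Curve]) -> dict[str, Curve]:
    """Pick the main thoracic and (thoraco)lumbar curves by apex location and
    Cobb magnitude; additional minor curves are ignored."""
    named: dict[str, Curve] = {}
    for c in curves:
        ai = level_index(c.apex)
        if level_index("T2") <= ai <= level_index("T11"):
            if "main_thoracic" not in named or c.cobb_deg > named["main_thoracic"].cobb_deg:
                named["main_thoracic"] = c
        elif level_index("T12") <= ai <= level_index("L4"):
            if "thoracolumbar" not in named or c.cobb_deg > named["thoracolumbar"].cobb_deg:
                named["thoracolumbar"] = c
    return named


def define_regions(spine: SpineModel, curves: list[Curve]) -> list[RegionSpec]:
    """Emit the measured regions for one subject.

    Scoliotic subjects get curve spans, apical zones (apex +- 1 vertebra and
    the intervening discs) and the junctional segments of the thoracic curve;
    curve-free subjects get the representative control spans T4-T12 and
    L1-L5 instead.
    """
    present = set(spine.levels)
    if not curves:
        for lv in ("T4", "T12", "L1", "L5"):
            if lv not in present:
                raise IncompleteSubjectError(f"{spine.subject_id}: control span level {lv} absent")
        return [
            RegionSpec(name="thoracic_T4T12", elements=tuple(span_elements("T4", "T12"))),
            RegionSpec(name="lumbar_L1L5", elements=tuple(span_elements("L1", "L5"))),
        ]

    named = _classify_curves(curves)
    regions: list[RegionSpec] = []

    def apical_zone(name: str, apex: str) -> RegionSpec:
        try:
            top, bottom = neighbor(apex, -1), neighbor(apex, +1)
        except ValueError:
            raise IncompleteSubjectError(f"{spine.subject_id}: apex {apex} at spine boundary, apical zone truncated")
        if top not in present or (bottom not in present and bottom != "S1"):
            raise IncompleteSubjectError(f"{spine.subject_id}: apex {apex} at spine boundary, apical zone truncated")
        return RegionSpec(name=name, elements=tuple(span_elements(top, bottom)), apex=apex)

    for name, suffix in (("main_thoracic", "thoracic"), ("thoracolumbar", "lumbar")):
        if name not in named:
            continue
        c = named[name]
        regions.append(
            RegionSpec(
                name=name,
                elements=tuple(span_elements(c.upper_end, c.lower_end)),
                end_vertebrae=(c.upper_end, c.lower_end),
                apex=c.apex,
            )
        )
        regions.append(apical_zone(f"apical_{suffix}", c.apex))

    if "main_thoracic" in named:
        c = named["main_thoracic"]
        above = neighbor(c.upper_end, -1)
        below = neighbor(c.lower_end, +1)
        if above not in present:
            raise IncompleteSubjectError(f"{spine.subject_id}: no vertebra above {c.upper_end} for the proximal junctional segment")
        if below not in present:
            raise IncompleteSubjectError(f"{spine.subject_id}: no vertebra below {c.lower_end} for the distal junctional segment")
        regions.append(RegionSpec(name="proximal_junctional", elements=tuple(span_elements(above, c.upper_end))))
        regions.append(RegionSpec(name="distal_junctional", elements=tuple(span_elements(c.lower_end, below))))
    return regions


# ---------------------------------------------------------------------------
# measurement


def _region_rotation(spine: SpineModel, region: RegionSpec) -> float:
    if region.apex is not None:
        return float(spine.vertebra(region.apex).axial_rotation_deg)
    return float(np.mean([spine.vertebra(v).axial_rotation_deg for v in region.vertebrae]))


def measure_subject(spine: SpineModel, regions: list[RegionSpec]) -> list[RegionMetrics]:
    """Deterministic per-region readout: Cobb from the conventional end
    vertebra endplates, apex rotation for curves and apical zones (mean
    endplate rotation elsewhere), summed lengths and the exact Delta(A-P)
    formula."""
    heights = element_heights(spine)
    frame = spine.frame
    out = []
    for region in regions:
        verts = region.vertebrae
        upper, lower = (region.end_vertebrae or (verts[0], verts[-1]))
        try:
            cobb = coronal_cobb(spine.vertebra(upper).superior, spine.vertebra(lower).inferior, coronal_normal=frame.y)
            anterior, posterior = region_lengths(heights, region)
            out.append(
                RegionMetrics(
                    region=region.name,
                    cobb_deg=cobb,
                    axial_rotation_deg=_region_rotation(spine, region),
                    anterior_mm=anterior,
                    posterior_mm=posterior,
                )
            )
        except (ValueError, IncompleteSubjectError) as exc:
            raise type(exc)(f"{spine.subject_id}: {exc}") from exc
    return out


def measure_contours(
    subject: SubjectContours, config: PipelineConfig = PipelineConfig(), validate_contours: bool = False
) -> tuple[SpineModel, list[RegionSpec], list[RegionMetrics]]:
    """Contours -> model -> regions -> metrics in one call."""
    spine = build_spine_model(subject, validate_contours=validate_contours)
    curves = detect_curves(spine, config)
    regions = define_regions(spine, curves)
    return spine, regions, measure_subject(spine, regions)


COHORT_COLUMNS = [
    "subject_id",
    "group",
    "curve_pattern",
    "region",
    "cobb_deg",
    "axial_rotation_deg",
    "anterior_mm",
    "posterior_mm",
    "delta_ap_percent",
    "standing_cobb_deg",
]


def measure_cohort(subjects: list[SubjectContours], config: PipelineConfig = PipelineConfig()) -> pd.DataFrame:
    """Measure a list of contour subjects into the cohort table (one row per
    subject x region, unique keys, no missing metric cells)."""
    rows = []
    for subject in subjects:
        _, regions, metrics = measure_contours(subject, config)
        standing = subject.meta.get("standing_cobb_deg", {})
        for m in metrics:
            rows.append(
                {
                    "subject_id": subject.subject_id,
                    "group": subject.group,
                    "curve_pattern": subject.meta.get("curve_pattern", "none"),
                    "region": m.region,
                    "cobb_deg": m.cobb_deg,
                    "axial_rotation_deg": m.axial_rotation_deg,
                    "anterior_mm": m.anterior_mm,
                    "posterior_mm": m.posterior_mm,
                    "delta_ap_percent": m.delta_ap_percent,
                    "standing_cobb_deg": float(standing.get(m.region, float("nan"))),
                }
            )
    table = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    if table.duplicated(subset=["subject_id", "region"]).any():
        raise ValueError("duplicate (subject, region) keys in cohort table")
    return table
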