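"""Parametric generator of scoliotic and control spines with exact ground truth.

A subject is a chain of wedge elements (vertebrae and discs) stacked from the
sacral plate upward.  Each element carries a height and three wedge angles
(sagittal, coronal, axial twist); the running frame is advanced by

    M[k+1] = M[k] @ R_k          p[k+1] = p[k] + M[k] @ sqrt(R_k) @ (0, 0, h_k)

where ``R_k = exp(rotvec)`` with rotation-vector components
``(sagittal, -coronal, -twist)`` in the element's lower-interface frame (the
symmetric square-root split makes a pure sagittal wedge produce the exact
closed form ``anterior - posterior = 2 (a_low + a_up) sin(wedge / 2)``).
Every interface between elements is one vertebral endplate, emitted as an
elliptical contour with a posteriorly offset canal centroid.

Ground-truth region metrics are recomputed analytically from the same frame
chain (positions and orientations, no contours, no plane fitting), which
keeps the truth route independent of the measurement route.

Cohort generation draws per-subject targets from group- and curve-pattern-
level distributions, then calibrates each subject's wedge profile by a small
fixed-point iteration until the chain reproduces its drawn targets (Cobb,
apex rotation, and the regional anterior-excess values).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .levels import VERTEBRA_LEVELS, disc_id, is_vertebra, level_index, neighbor, span_elements
from .spine_model import EndplateContour, SubjectContours, axial_rotation

__all__ = [
    "InvalidParameterError",
    "ElementParams",
    "CurveLayout",
    "SubjectSpec",
    "SubjectTruth",
    "CohortConfig",
    "default_anatomy",
    "straight_subject_spec",
    "generate_subject",
    "generate_cohort",
    "perturb_observer",
    "truth_table",
]


class InvalidParameterError(ValueError):
    """Raised for generator parameters that cannot produce a valid spine."""


MAX_WEDGE_DEG = 20.0  # per-element cap; transitional vertebrae in double curves need >15
N_CONTOUR_POINTS = 36

THORACIC_PATTERN = "thoracic"
LUMBAR_PATTERN = "lumbar"
DOUBLE_PATTERN = "double"


# ---------------------------------------------------------------------------
# anatomy defaults


def default_anatomy() -> dict[str, dict[str, float]]:
    """Per-element baseline sizes (mm): vertebra/disc heights, endplate
    ellipse semi-axes and posterior canal offset, keyed by element id."""
    table: dict[str, dict[str, float]] = {}
    vh = {**{f"T{i + 1}": h for i, h in enumerate(np.linspace(16.0, 22.0, 12))},
          **{f"L{i + 1}": h for i, h in enumerate(np.linspace(23.5, 26.5, 5))}}
    ax = {**{f"T{i + 1}": a for i, a in enumerate(np.linspace(12.0, 18.0, 12))},
          **{f"L{i + 1}": a for i, a in enumerate(np.linspace(21.0, 25.0, 5))}, "S1": 26.0}
    ay = {**{f"T{i + 1}": a for i, a in enumerate(np.linspace(9.5, 14.0, 12))},
          **{f"L{i + 1}": a for i, a in enumerate(np.linspace(15.0, 17.5, 5))}, "S1": 18.0}
    dh = {**{disc_id(f"T{i + 1}", f"T{i + 2}"): h for i, h in enumerate(np.linspace(4.0, 5.5, 11))},
          "T12-L1": 6.5,
          **{disc_id(f"L{i + 1}", f"L{i + 2}"): h for i, h in enumerate(np.linspace(8.0, 10.0, 4))},
          "L5-S1": 10.0}
    for lv in VERTEBRA_LEVELS + ["S1"]:
        table[lv] = {"height": vh.get(lv, 0.0), "ax": ax[lv], "ay": ay[lv], "canal": ay[lv] + 7.0}
    for d, h in dh.items():
        table[d] = {"height": h}
    return table


# ---------------------------------------------------------------------------
# domain types


@dataclass
class ElementParams:
    """Wedge parameters of one vertebra or disc.

    Signs follow clinical convention: coronal wedge right-convex positive,
    sagittal wedge anterior-taller positive, axial twist right positive.
    """

    element_id: str
    base_height_mm: float
    coronal_wedge_deg: float = 0.0
    sagittal_wedge_deg: float = 0.0
    axial_twist_deg: float = 0.0
    semi_axis_lr_mm: float = 15.0
    semi_axis_ap_mm: float = 12.0
    canal_offset_mm: float = 19.0

    def __post_init__(self) -> None:
        if self.base_height_mm <= 0:
            raise InvalidParameterError(f"{self.element_id}: base_height must be > 0")
        if self.semi_axis_lr_mm <= 0 or self.semi_axis_ap_mm <= 0:
            raise InvalidParameterError(f"{self.element_id}: ellipse semi-axes must be > 0")
        for name in ("coronal_wedge_deg", "sagittal_wedge_deg", "axial_twist_deg"):
            if abs(getattr(self, name)) > MAX_WEDGE_DEG:
                raise InvalidParameterError(
                    f"{self.element_id}: |{name}| = {abs(getattr(self, name)):.1f} exceeds {MAX_WEDGE_DEG} deg"
                )


@dataclass(frozen=True)
class CurveLayout:
    """End vertebrae and apices of the two modelled curves.  The thoracic
    lower end vertebra is shared with the (thoraco)lumbar curve, as is common
    for transitional vertebrae."""

    t_upper: str = "T5"
    t_apex: str = "T8"
    t_lower: str = "T11"
    l_apex: str = "L2"
    l_lower: str = "L4"

    @property
    def l_upper(self) -> str:
        return self.t_lower

    def region_elements(self) -> dict[str, list[str]]:
        return {
            "main_thoracic": span_elements(self.t_upper, self.t_lower),
            "thoracolumbar": span_elements(self.l_upper, self.l_lower),
            "apical_thoracic": span_elements(neighbor(self.t_apex, -1), neighbor(self.t_apex, +1)),
            "apical_lumbar": span_elements(neighbor(self.l_apex, -1), neighbor(self.l_apex, +1)),
            "proximal_junctional": span_elements(neighbor(self.t_upper, -1), self.t_upper),
            "distal_junctional": span_elements(self.t_lower, neighbor(self.t_lower, +1)),
        }


CONTROL_REGIONS = {
    "thoracic_T4T12": span_elements("T4", "T12"),
    "lumbar_L1L5": span_elements("L1", "L5"),
}


@dataclass
class SubjectSpec:
    """Drawn targets and scaling that fully determine one synthetic subject."""

    subject_id: str
    group: str  # "ais" | "control"
    curve_pattern: str = "none"
    layout: CurveLayout | None = None
    targets: dict[str, float] = field(default_factory=dict)
    standing_cobb: dict[str, float] = field(default_factory=dict)
    size_scale: float = 1.0
    noise_seed: int = 0
    wedge_noise_deg: float = 0.0
    twist_noise_deg: float = 0.0


@dataclass
class SubjectTruth:
    """Generator-side ground truth: element parameters plus region metrics
    recomputed analytically from the frame chain."""

    subject_id: str
    group: str
    curve_pattern: str
    layout: CurveLayout | None
    elements: list[ElementParams]  # ascending from the sacral plate
    region_truth: dict[str, dict[str, float]]
    standing_cobb: dict[str, float]
    targets: dict[str, float]


@dataclass
class CohortConfig:
    """Distribution parameters for one generated cohort.

    Defaults are calibrated so that the measurement pipeline, run on the
    generated contours, reproduces the reference cohort summaries (thoracic
    curve anterior excess +3.8%, apex rotation +24 deg, etc.).
    """

    group: str = "ais"
    n_subjects: int = 77
    seed: int = 0
    # curve-pattern mix: primary thoracic / primary (thoraco)lumbar / double
    pattern_probs: tuple[float, float, float] = (0.69, 0.08, 0.23)
    # standing thoracic Cobb per pattern (mean, sd), degrees
    standing_cobb_t: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {THORACIC_PATTERN: (65.2, 16.0), LUMBAR_PATTERN: (43.5, 14.0), DOUBLE_PATTERN: (66.3, 16.0)}
    )
    ct_cobb_gain: float = 0.92  # prone/internal Cobb per standing degree
    ct_cobb_noise_sd: float = 4.0
    rot_per_standing_deg: float = 0.5  # apex rotation slope: 5 deg per 10 deg Cobb
    rot_noise_sd: float = 2.6
    rot_t_mean: float = 24.0
    dap_per_standing_deg: float = 0.12  # curve anterior excess: 1.2% per 10 deg Cobb
    dap_noise_sd: float = 1.87
    dap_t_mean: float = 3.8
    # (thoraco)lumbar curve per pattern (mean, sd)
    cobb_l: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {THORACIC_PATTERN: (28.0, 10.0), LUMBAR_PATTERN: (57.0, 12.0), DOUBLE_PATTERN: (55.0, 12.0)}
    )
    rot_l: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {THORACIC_PATTERN: (-4.0, 5.0), LUMBAR_PATTERN: (-20.0, 6.0), DOUBLE_PATTERN: (-19.0, 8.0)}
    )
    rot_l_mean: float = -9.0
    dap_l: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {THORACIC_PATTERN: (8.6, 2.2), LUMBAR_PATTERN: (10.8, 2.3), DOUBLE_PATTERN: (11.4, 2.2)}
    )
    dap_l_mean: float = 9.4
    # regional anterior excess (mean, sd)
    apical_thoracic: tuple[float, float] = (7.1, 4.8)
    apical_lumbar: tuple[float, float] = (11.2, 4.1)
    proximal_junctional: tuple[float, float] = (-1.3, 4.7)
    distal_junctional: tuple[float, float] = (1.0, 2.7)
    junctional_margin: float = 0.85  # |junctional| clipped below margin * min(apical)
    # control spans
    control_thoracic: tuple[float, float] = (-4.1, 1.8)
    control_lumbar: tuple[float, float] = (7.8, 3.6)
    # structural noise and reliability
    wedge_noise_deg: float = 0.05
    twist_noise_deg: float = 0.1
    control_twist_noise_deg: float = 0.2
    observer_jitter_mm: float = 0.05  # calibrated observer-replicate jitter
    moment_match: bool = True

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise InvalidParameterError("n_subjects must be >= 2")
        if abs(sum(self.pattern_probs) - 1.0) > 1e-9 or min(self.pattern_probs) < 0:
            raise InvalidParameterError("pattern_probs must be a probability vector")
        if self.group not in ("ais", "control"):
            raise InvalidParameterError(f"unknown group {self.group!r}")


# ---------------------------------------------------------------------------
# frame chain


def _element_sequence() -> tuple[list[str], list[tuple[str, str]]]:
    """Ascending element ids and the (level, side) owner of every interface."""
    elements: list[str] = []
    interfaces: list[tuple[str, str]] = [("S1", "superior")]
    below = "S1"
    for lv in reversed(VERTEBRA_LEVELS):
        elements.append(disc_id(lv, below))
        interfaces.append((lv, "inferior"))
        elements.append(lv)
        interfaces.append((lv, "superior"))
        below = lv
    return elements, interfaces


ELEMENTS_ASC, INTERFACES_ASC = _element_sequence()
ELEMENT_INDEX = {e: i for i, e in enumerate(ELEMENTS_ASC)}
INTERFACE_INDEX = {io: i for i, io in enumerate(INTERFACES_ASC)}


def default_elements(anatomy: dict | None = None, size_scale: float = 1.0) -> list[ElementParams]:
    """Straight (wedge-free) element chain with baseline anatomy."""
    anatomy = anatomy or default_anatomy()
    out = []
    for eid in ELEMENTS_ASC:
        if is_vertebra(eid):
            a = anatomy[eid]
            out.append(
                ElementParams(
                    element_id=eid,
                    base_height_mm=a["height"] * size_scale,
                    semi_axis_lr_mm=a["ax"] * size_scale,
                    semi_axis_ap_mm=a["ay"] * size_scale,
                    canal_offset_mm=a["canal"] * size_scale,
                )
            )
        else:
            out.append(ElementParams(element_id=eid, base_height_mm=anatomy[eid]["height"] * size_scale))
    return out


@dataclass
class _Chain:
    M: np.ndarray  # (K, 3, 3) interface orientations
    p: np.ndarray  # (K, 3) interface positions
    ay: np.ndarray  # (K,) AP semi-axis per interface
    ax: np.ndarray  # (K,)
    canal: np.ndarray  # (K,) posterior canal offset


def build_chain(elements: list[ElementParams], anatomy: dict | None = None, size_scale: float = 1.0) -> _Chain:
    if [e.element_id for e in elements] != ELEMENTS_ASC:
        raise InvalidParameterError("element chain must cover T1..L5 plus all discs, ascending from the sacral plate")
    anatomy = anatomy or default_anatomy()
    K = len(elements) + 1
    M = np.empty((K, 3, 3))
    p = np.empty((K, 3))
    M[0] = np.eye(3)
    p[0] = 0.0
    for j, e in enumerate(elements):
        rv = np.radians([e.sagittal_wedge_deg, -e.coronal_wedge_deg, -e.axial_twist_deg])
        R = Rotation.from_rotvec(rv).as_matrix()
        Rh = Rotation.from_rotvec(0.5 * rv).as_matrix()
        p[j + 1] = p[j] + M[j] @ (Rh @ np.array([0.0, 0.0, e.base_height_mm]))
        M[j + 1] = M[j] @ R
    if np.any(np.diff(p[:, 2]) <= 0):
        raise InvalidParameterError("frame composition produced non-monotone cranial coordinates")
    ay = np.empty(K)
    ax = np.empty(K)
    canal = np.empty(K)
    by_level = {e.element_id: e for e in elements if is_vertebra(e.element_id)}
    for k, (lv, _) in enumerate(INTERFACES_ASC):
        if lv == "S1":
            a = anatomy["S1"]
            ax[k], ay[k], canal[k] = a["ax"] * size_scale, a["ay"] * size_scale, a["canal"] * size_scale
        else:
            e = by_level[lv]
            ax[k], ay[k], canal[k] = e.semi_axis_lr_mm, e.semi_axis_ap_mm, e.canal_offset_mm
    return _Chain(M=M, p=p, ay=ay, ax=ax, canal=canal)


def _chain_contours(chain: _Chain) -> list[EndplateContour]:
    theta = np.radians(np.arange(N_CONTOUR_POINTS) * (360.0 / N_CONTOUR_POINTS))
    out = []
    for k, (lv, side) in enumerate(INTERFACES_ASC):
        local = np.stack([chain.ax[k] * np.cos(theta), chain.ay[k] * np.sin(theta), np.zeros_like(theta)], axis=1)
        pts = chain.p[k] + local @ chain.M[k].T
        canal = chain.p[k] + chain.M[k] @ np.array([0.0, -chain.canal[k], 0.0])
        out.append(EndplateContour(level=lv, side=side, points=pts, canal_centroid=canal))
    return out


# --- analytic (truth-route) measurements on the chain ----------------------


def _chain_anterior_posterior(chain: _Chain) -> tuple[np.ndarray, np.ndarray]:
    ant = chain.p + chain.ay[:, None] * chain.M[:, :, 1]
    post = chain.p - chain.ay[:, None] * chain.M[:, :, 1]
    return ant, post


def _chain_element_heights(chain: _Chain) -> tuple[np.ndarray, np.ndarray]:
    ant, post = _chain_anterior_posterior(chain)
    return np.linalg.norm(np.diff(ant, axis=0), axis=1), np.linalg.norm(np.diff(post, axis=0), axis=1)


def _chain_rotation(chain: _Chain, k: int) -> float:
    return axial_rotation(chain.M[k][:, 1], chain.M[0][:, 1], up=chain.M[0][:, 2])


def _chain_cobb(chain: _Chain, k_upper: int, k_lower: int) -> float:
    y0 = chain.M[0][:, 1]
    t1 = np.cross(chain.M[k_upper][:, 2], y0)
    t2 = np.cross(chain.M[k_lower][:, 2], y0)
    t1, t2 = t1 / np.linalg.norm(t1), t2 / np.linalg.norm(t2)
    return float(np.degrees(np.arccos(np.clip(t1 @ t2, -1.0, 1.0))))


def _vertebra_rotation(chain: _Chain, level: str) -> float:
    return 0.5 * (
        _chain_rotation(chain, INTERFACE_INDEX[(level, "superior")])
        + _chain_rotation(chain, INTERFACE_INDEX[(level, "inferior")])
    )


def _region_truth(chain: _Chain, name: str, elements: list[str], layout: CurveLayout | None) -> dict[str, float]:
    ah, ph = _chain_element_heights(chain)
    idx = [ELEMENT_INDEX[e] for e in elements]
    anterior = float(ah[idx].sum())
    posterior = float(ph[idx].sum())
    verts = [e for e in elements if is_vertebra(e)]
    upper, lower = verts[0], verts[-1]
    cobb = _chain_cobb(chain, INTERFACE_INDEX[(upper, "superior")], INTERFACE_INDEX[(lower, "inferior")])
    if layout is not None and name in ("main_thoracic", "apical_thoracic"):
        rot = _vertebra_rotation(chain, layout.t_apex)
    elif layout is not None and name in ("thoracolumbar", "apical_lumbar"):
        rot = _vertebra_rotation(chain, layout.l_apex)
    else:
        rot = float(np.mean([_vertebra_rotation(chain, v) for v in verts]))
    return {
        "cobb_deg": cobb,
        "axial_rotation_deg": rot,
        "anterior_mm": anterior,
        "posterior_mm": posterior,
        "delta_ap_percent": (anterior - posterior) / posterior * 100.0,
    }


def _subject_regions(spec: SubjectSpec) -> dict[str, list[str]]:
    return spec.layout.region_elements() if spec.layout is not None else dict(CONTROL_REGIONS)


def _apex_margin(chain: _Chain, upper: str, apex: str, lower: str) -> tuple[float, str]:
    """Deviation margin of the intended apex over its neighbours.

    Returns ``(margin_mm, dominant)`` where margin is the apex's perpendicular
    coronal deviation from the end-vertebra chord minus the larger neighbour
    deviation, and ``dominant`` names the bigger neighbour side.
    """
    span = [lv for lv in VERTEBRA_LEVELS if level_index(upper) <= level_index(lv) <= level_index(lower)]
    cent = np.array(
        [
            0.5 * (chain.p[INTERFACE_INDEX[(lv, "superior")]] + chain.p[INTERFACE_INDEX[(lv, "inferior")]])
            for lv in span
        ]
    )
    xz = np.stack([cent @ chain.M[0][:, 0], cent @ chain.M[0][:, 2]], axis=1)
    chord = xz[-1] - xz[0]
    chord = chord / np.linalg.norm(chord)
    dev = np.abs((xz - xz[0]) @ np.array([-chord[1], chord[0]]))
    i = span.index(apex)
    up_dev = dev[i - 1] if i > 0 else 0.0
    dn_dev = dev[i + 1] if i + 1 < len(dev) else 0.0
    return float(dev[i] - max(up_dev, dn_dev)), "cranial" if up_dev >= dn_dev else "caudal"


# ---------------------------------------------------------------------------
# wedge-profile construction and per-subject calibration


def _interp_profile(anchors: list[tuple[int, float]]) -> np.ndarray:
    xs = np.array([a[0] for a in anchors], dtype=float)
    ys = np.array([a[1] for a in anchors], dtype=float)
    return np.interp(np.arange(len(INTERFACES_ASC)), xs, ys)


def _ki(level: str, side: str) -> int:
    return INTERFACE_INDEX[(level, side)]


def _tilt_anchors(
    layout: CurveLayout, c_t: float, c_l: float, lean_t: float = 0.0, lean_l: float = 0.0
) -> list[tuple[int, float]]:
    # transitional wedge on the shared end vertebra, capped to stay anatomical
    w_trans = float(np.clip((c_t - c_l) / 2.0, -12.0, 12.0))
    tilt_sup_low = c_t / 2.0 - w_trans  # lumbar-curve upper measured endplate
    tilt_inf_low = tilt_sup_low - c_l  # lumbar-curve lower measured endplate
    eps_l, eps_t = 0.02 * c_l, 0.02 * c_t
    # apex anchors sit at the mid-tilt of their arc (profile stays monotone
    # inside the curve even when the two end tilts share a sign); the lean
    # terms bend the two legs so the maximal-deviation vertebra coincides
    # with the intended apex (adjusted by calibration)
    mid_l = 0.5 * (tilt_inf_low + tilt_sup_low)
    lo, hi = min(tilt_inf_low, tilt_sup_low), max(tilt_inf_low, tilt_sup_low)
    apex_lo = float(np.clip(mid_l - eps_l + lean_l, lo + 1.5 * eps_l, hi - 1.5 * eps_l))
    apex_hi = float(np.clip(mid_l + eps_l + lean_l, lo + 1.5 * eps_l, hi - 1.5 * eps_l))
    anchors = [
        (0, 0.0),
        (_ki(layout.l_lower, "inferior"), tilt_inf_low),
        (_ki(layout.l_apex, "inferior"), apex_lo),
        (_ki(layout.l_apex, "superior"), apex_hi),
        (_ki(layout.t_lower, "inferior"), c_t / 2.0),
        (_ki(layout.t_lower, "superior"), tilt_sup_low),
        (_ki(layout.t_apex, "inferior"), +eps_t + lean_t),
        (_ki(layout.t_apex, "superior"), -eps_t + lean_t),
        (_ki(layout.t_upper, "superior"), -c_t / 2.0),
        (len(INTERFACES_ASC) - 1, 0.0),
    ]
    # keep the lumbar lower end vertebra a genuine tilt extremum even when its
    # tilt shares the sign of the segment below (large thoracic/lumbar gap)
    try:
        below = neighbor(layout.l_lower, +1)
    except ValueError:
        below = None
    if below is not None and below != "S1":
        dip = max(3.0, 2.0 * eps_l)
        anchors.insert(1, (_ki(below, "superior"), tilt_inf_low + dip))
    return sorted(anchors, key=lambda a: a[0])


def _rotation_anchors(layout: CurveLayout, r_t: float, r_l: float) -> list[tuple[int, float]]:
    junction = 0.1 * r_t + 0.3 * r_l
    return [
        (0, 0.0),
        (_ki(layout.l_lower, "inferior"), 0.2 * r_l),
        (_ki(layout.l_apex, "inferior"), r_l),
        (_ki(layout.l_apex, "superior"), r_l),
        (_ki(layout.t_lower, "superior"), junction),
        (_ki(layout.t_apex, "inferior"), r_t),
        (_ki(layout.t_apex, "superior"), r_t),
        (_ki(layout.t_upper, "superior"), 0.25 * r_t),
        (len(INTERFACES_ASC) - 1, 0.05 * r_t),
    ]


def _required_excess(delta_percent: float, region_height: float) -> float:
    """Total anterior-minus-posterior excess (mm) producing a given Delta(A-P)
    over a region of summed base height ``region_height`` (exact inversion of
    the ratio formula under the anterior+posterior = 2h identity)."""
    d = delta_percent / 100.0
    return d * region_height / (1.0 + d / 2.0)


def _distribute(w: dict[str, float], elements: list[str], total: float, heights: dict[str, float]) -> None:
    hsum = sum(heights[e] for e in elements)
    for e in elements:
        w[e] = total * heights[e] / hsum


def _sagittal_from_excess(w_mm: float, a_low: float, a_up: float) -> float:
    s = w_mm / (2.0 * (a_low + a_up))
    s = float(np.clip(s, -0.999, 0.999))
    return math.degrees(2.0 * math.asin(s))


def _excess_to_wedges(w: dict[str, float], elements: list[ElementParams], chain_ay_lookup: dict[str, tuple[float, float]]) -> None:
    for e in elements:
        a_low, a_up = chain_ay_lookup[e.element_id]
        e.sagittal_wedge_deg = _sagittal_from_excess(w.get(e.element_id, 0.0), a_low, a_up)


def _ay_lookup(elements: list[ElementParams]) -> dict[str, tuple[float, float]]:
    by_level = {e.element_id: e.semi_axis_ap_mm for e in elements if is_vertebra(e.element_id)}
    anatomy_s1_ay = None
    out = {}
    for j, eid in enumerate(ELEMENTS_ASC):
        low_lv = INTERFACES_ASC[j][0]
        up_lv = INTERFACES_ASC[j + 1][0]
        a_low = by_level.get(low_lv) if low_lv != "S1" else anatomy_s1_ay
        if a_low is None:  # sacral plate: reuse L5 size
            a_low = by_level["L5"]
        out[eid] = (a_low, by_level[up_lv])
    return out


def _assemble_elements(
    spec: SubjectSpec,
    state: dict[str, float],
    w_alloc: dict[str, float],
    noise: dict[str, np.ndarray],
    anatomy: dict,
) -> list[ElementParams]:
    elements = default_elements(anatomy, spec.size_scale)
    regions = _subject_regions(spec)
    heights = {e.element_id: e.base_height_mm for e in elements}

    # --- sagittal anterior-excess allocation (mm per element)
    w: dict[str, float] = {e: 0.0 for e in ELEMENTS_ASC}
    if spec.layout is not None:
        lay = spec.layout
        _distribute(w, regions["proximal_junctional"], w_alloc["proximal_junctional"], heights)
        _distribute(w, regions["distal_junctional"], w_alloc["distal_junctional"], heights)
        _distribute(w, regions["apical_thoracic"], w_alloc["apical_thoracic"], heights)
        _distribute(w, regions["apical_lumbar"], w_alloc["apical_lumbar"], heights)
        for curve, wkey in (("main_thoracic", "main_thoracic"), ("thoracolumbar", "thoracolumbar")):
            span = regions[curve]
            inner = regions["apical_thoracic" if curve == "main_thoracic" else "apical_lumbar"]
            taken = set(inner)
            taken |= set(regions["proximal_junctional"]) | set(regions["distal_junctional"])
            flanks = [e for e in span if e not in taken]
            assigned = sum(w[e] for e in span if e in taken)
            _distribute(w, flanks, w_alloc[wkey] - assigned, heights)
        # mild fixed profile outside the measured regions (cosmetic only)
        for e in ("L4-L5", "L5", "L5-S1"):
            if w[e] == 0.0:
                w[e] = 0.3
        for e in span_elements("T1", "T3"):
            if w[e] == 0.0:
                w[e] = -0.2
    else:
        _distribute(w, regions["thoracic_T4T12"], w_alloc["thoracic_T4T12"], heights)
        _distribute(w, regions["lumbar_L1L5"], w_alloc["lumbar_L1L5"], heights)
        if any(abs(v) > 1e-12 for v in w_alloc.values()):  # keep the all-zero spine exactly straight
            w["L5-S1"] = 0.5

    _excess_to_wedges(w, elements, _ay_lookup(elements))

    # --- coronal and twist profiles from interface anchor values
    if spec.layout is not None:
        tilt = _interp_profile(
            _tilt_anchors(spec.layout, state["cobb_t"], state["cobb_l"], state["lean_t"], state["lean_l"])
        )
        rot = _interp_profile(_rotation_anchors(spec.layout, state["rot_t"], state["rot_l"]))
    else:
        tilt = np.zeros(len(INTERFACES_ASC))
        rot = np.zeros(len(INTERFACES_ASC))
    d_tilt = np.diff(tilt)
    d_rot = np.diff(rot)
    for j, e in enumerate(elements):
        e.coronal_wedge_deg = float(np.clip(-d_tilt[j] + noise["coronal"][j], -MAX_WEDGE_DEG, MAX_WEDGE_DEG))
        e.axial_twist_deg = float(np.clip(d_rot[j] + noise["twist"][j], -MAX_WEDGE_DEG, MAX_WEDGE_DEG))
        e.sagittal_wedge_deg = float(np.clip(e.sagittal_wedge_deg + noise["sagittal"][j], -MAX_WEDGE_DEG, MAX_WEDGE_DEG))
    return elements


def _calibrate_subject(spec: SubjectSpec, anatomy: dict, max_iter: int = 20) -> tuple[list[ElementParams], _Chain]:
    """Fixed-point calibration: adjust profile amplitudes until the analytic
    chain metrics reproduce the subject's drawn targets."""
    rng = np.random.default_rng(spec.noise_seed)
    n_el = len(ELEMENTS_ASC)
    noise = {
        "sagittal": rng.normal(0.0, spec.wedge_noise_deg, n_el),
        "coronal": rng.normal(0.0, spec.wedge_noise_deg, n_el),
        "twist": rng.normal(0.0, spec.twist_noise_deg, n_el),
    }
    regions = _subject_regions(spec)
    heights0 = {e.element_id: e.base_height_mm for e in default_elements(anatomy, spec.size_scale)}
    delta_keys = [k for k in regions if f"delta_{k}" in spec.targets or k in spec.targets]

    def tkey(region: str) -> str:
        return region if region in spec.targets else f"delta_{region}"

    w_alloc = {
        r: _required_excess(spec.targets[tkey(r)], sum(heights0[e] for e in regions[r])) for r in delta_keys
    }
    state = {
        "cobb_t": spec.targets.get("cobb_t", 0.0),
        "cobb_l": spec.targets.get("cobb_l", 0.0),
        "rot_t": spec.targets.get("rot_t", 0.0),
        "rot_l": spec.targets.get("rot_l", 0.0),
        "lean_t": 0.0,
        "lean_l": 0.0,
    }
    APEX_MARGIN_MM = 0.6

    elements = _assemble_elements(spec, state, w_alloc, noise, anatomy)
    chain = build_chain(elements, anatomy, spec.size_scale)
    for _ in range(max_iter):
        err = 0.0
        truth = {r: _region_truth(chain, r, regions[r], spec.layout) for r in regions}
        for r in delta_keys:
            e = spec.targets[tkey(r)] - truth[r]["delta_ap_percent"]
            w_alloc[r] += e / 100.0 * truth[r]["posterior_mm"]
            err = max(err, abs(e))
        if spec.layout is not None:
            for skey, region, metric in (
                ("cobb_t", "main_thoracic", "cobb_deg"),
                ("cobb_l", "thoracolumbar", "cobb_deg"),
                ("rot_t", "main_thoracic", "axial_rotation_deg"),
                ("rot_l", "thoracolumbar", "axial_rotation_deg"),
            ):
                e = spec.targets[skey] - truth[region][metric]
                state[skey] += e
                err = max(err, abs(e))
            # keep the maximal-deviation vertebra on the intended apex
            lay = spec.layout
            for lkey, curve, convexity, cobb in (
                ("lean_t", (lay.t_upper, lay.t_apex, lay.t_lower), "right", state["cobb_t"]),
                ("lean_l", (lay.l_upper, lay.l_apex, lay.l_lower), "left", state["cobb_l"]),
            ):
                margin, dominant = _apex_margin(chain, *curve)
                cap = 0.3 * abs(cobb)
                if margin < APEX_MARGIN_MM and abs(state[lkey]) < cap:
                    step = min(2.5, 1.2 * (APEX_MARGIN_MM - margin))
                    direction = 1.0 if (convexity == "left") == (dominant == "cranial") else -1.0
                    state[lkey] = float(np.clip(state[lkey] + direction * step, -cap, cap))
                    err = max(err, APEX_MARGIN_MM - margin)
        if err < 0.01:
            break
        elements = _assemble_elements(spec, state, w_alloc, noise, anatomy)
        chain = build_chain(elements, anatomy, spec.size_scale)
    return elements, chain


# ---------------------------------------------------------------------------
# public generation API


def straight_subject_spec(subject_id: str = "straight", size_scale: float = 1.0) -> SubjectSpec:
    """A wedge-free control subject: every Delta(A-P), rotation and Cobb is 0."""
    return SubjectSpec(
        subject_id=subject_id,
        group="control",
        targets={"thoracic_T4T12": 0.0, "lumbar_L1L5": 0.0},
        size_scale=size_scale,
        wedge_noise_deg=0.0,
        twist_noise_deg=0.0,
    )


def generate_subject(spec: SubjectSpec, seed: int | None = None, anatomy: dict | None = None) -> tuple[SubjectContours, SubjectTruth]:
    """Build one subject: elliptical endplate contours in the world frame plus
    analytic ground truth.  Deterministic for a fixed spec (and seed, which
    feeds the structural noise if the spec does not carry its own)."""
    anatomy = anatomy or default_anatomy()
    if seed is not None and spec.noise_seed == 0:
        spec.noise_seed = seed
    # the straight spine has zero targets everywhere; skip zero-allocation noise
    elements, chain = _calibrate_subject(spec, anatomy)
    regions = _subject_regions(spec)
    truth = SubjectTruth(
        subject_id=spec.subject_id,
        group=spec.group,
        curve_pattern=spec.curve_pattern,
        layout=spec.layout,
        elements=elements,
        region_truth={r: _region_truth(chain, r, els, spec.layout) for r, els in regions.items()},
        standing_cobb=dict(spec.standing_cobb),
        targets=dict(spec.targets),
    )
    contours = SubjectContours(
        subject_id=spec.subject_id,
        contours=_chain_contours(chain),
        group=spec.group,
        meta={
            "curve_pattern": spec.curve_pattern,
            "standing_cobb_deg": dict(spec.standing_cobb),
        },
    )
    return contours, truth


def perturb_observer(subject: SubjectContours, jitter_mm: float, seed: int = 0) -> SubjectContours:
    """Observer-replicate simulation: isotropic zero-mean Gaussian jitter on
    every contour vertex and canal centroid.  ``jitter_mm = 0`` returns an
    unmodified copy."""
    if jitter_mm < 0:
        raise InvalidParameterError("jitter_mm must be >= 0")
    out = subject.copy()
    if jitter_mm == 0:
        return out
    rng = np.random.default_rng(seed)
    for c in out.contours:
        c.points = c.points + rng.normal(0.0, jitter_mm, c.points.shape)
        c.canal_centroid = c.canal_centroid + rng.normal(0.0, jitter_mm, 3)
    return out


# --- cohort drawing --------------------------------------------------------


def _moment_match(x: np.ndarray, mean: float, sd: float) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        return np.full_like(x, mean)
    s = x.std(ddof=1)
    if s < 1e-12:
        return np.full_like(x, mean)
    return mean + (x - x.mean()) * (sd / s)


def _clip_restore_mean(x: np.ndarray, lo: np.ndarray, hi: np.ndarray, target_mean: float, iters: int = 8) -> np.ndarray:
    """Clip to per-subject bounds, then redistribute the mean deficit over
    unclipped subjects so the cohort mean is preserved."""
    x = np.clip(x, lo, hi)
    for _ in range(iters):
        d = target_mean - x.mean()
        if abs(d) < 1e-10:
            break
        free = (x < hi) if d > 0 else (x > lo)
        if not free.any():
            break
        x[free] += d * x.size / free.sum()
        x = np.clip(x, lo, hi)
    return x


def _gamma_draw(rng: np.random.Generator, n: int, mean: float, sd: float, floor: float, match: bool) -> np.ndarray:
    shape = (mean / sd) ** 2
    scale = sd**2 / mean
    x = rng.gamma(shape, scale, n)
    if match:
        x = _moment_match(x, mean, sd)
    return np.maximum(x, floor)


def _per_pattern_draw(rng: np.random.Generator, patterns: np.ndarray, table: dict, match: bool) -> np.ndarray:
    out = np.empty(len(patterns))
    for pat, (mean, sd) in table.items():
        m = patterns == pat
        if m.any():
            draws = rng.normal(mean, sd, m.sum())
            out[m] = _moment_match(draws, mean, sd) if match else draws
    return out


def _draw_ais_specs(cfg: CohortConfig, rng: np.random.Generator) -> list[SubjectSpec]:
    n = cfg.n_subjects
    counts = rng.multinomial(n, cfg.pattern_probs)
    patterns = np.repeat([THORACIC_PATTERN, LUMBAR_PATTERN, DOUBLE_PATTERN], counts)
    mm = cfg.moment_match

    standing_t = np.clip(_per_pattern_draw(rng, patterns, cfg.standing_cobb_t, mm), 24.0, 100.0)
    cobb_noise = rng.normal(0.0, cfg.ct_cobb_noise_sd, n)
    if mm:
        cobb_noise = _moment_match(cobb_noise, 0.0, cfg.ct_cobb_noise_sd)
    cobb_t = np.clip(cfg.ct_cobb_gain * standing_t + cobb_noise, 20.0, 90.0)

    rot_noise = rng.normal(0.0, cfg.rot_noise_sd, n)
    dap_noise = rng.normal(0.0, cfg.dap_noise_sd, n)
    if mm:
        # residualize against the regressor so the cohort-level slopes of
        # rotation and anterior excess per standing degree are exact
        s_c = standing_t - standing_t.mean()
        rot_noise = rot_noise - (rot_noise @ s_c) / (s_c @ s_c) * s_c
        dap_noise = dap_noise - (dap_noise @ s_c) / (s_c @ s_c) * s_c
        rot_noise = _moment_match(rot_noise, 0.0, cfg.rot_noise_sd)
        dap_noise = _moment_match(dap_noise, 0.0, cfg.dap_noise_sd)
        rot_noise -= (rot_noise @ s_c) / (s_c @ s_c) * s_c
        dap_noise -= (dap_noise @ s_c) / (s_c @ s_c) * s_c
    rot_t = (cfg.rot_t_mean - cfg.rot_per_standing_deg * standing_t.mean()) + cfg.rot_per_standing_deg * standing_t + rot_noise
    dap_t = (cfg.dap_t_mean - cfg.dap_per_standing_deg * standing_t.mean()) + cfg.dap_per_standing_deg * standing_t + dap_noise

    cobb_l = np.clip(_per_pattern_draw(rng, patterns, cfg.cobb_l, mm), 15.0, 70.0)
    rot_l = _per_pattern_draw(rng, patterns, cfg.rot_l, mm)
    dap_l = _per_pattern_draw(rng, patterns, cfg.dap_l, mm)
    if mm:
        rot_l = rot_l + (cfg.rot_l_mean - rot_l.mean())
        dap_l = dap_l + (cfg.dap_l_mean - dap_l.mean())
    standing_l = cobb_l / cfg.ct_cobb_gain + rng.normal(0.0, 3.0, n)

    # apical excess is drawn relative to the curve's anterior excess (the two
    # are anatomically coupled); tails are bounded so flank wedges stay sane
    def apical(curve_dap: np.ndarray, mean_sd: tuple[float, float], floor: float) -> np.ndarray:
        mean_exc = mean_sd[0] - curve_dap.mean()
        sd_exc = math.sqrt(max(0.5, mean_sd[1] ** 2 - curve_dap.var(ddof=1)))
        exc = _gamma_draw(rng, n, max(0.5, mean_exc), sd_exc, floor=0.2, match=mm)
        exc = _clip_restore_mean(exc, np.full(n, 0.2), np.full(n, 12.0), max(0.5, mean_exc))
        return _clip_restore_mean(curve_dap + exc, np.full(n, floor), np.full(n, mean_sd[0] + 2.5 * mean_sd[1]), mean_sd[0])

    dap_at = apical(dap_t, cfg.apical_thoracic, floor=1.0)
    dap_al = apical(dap_l, cfg.apical_lumbar, floor=2.0)
    bound = cfg.junctional_margin * np.minimum(dap_at, dap_al)
    dap_pj = rng.normal(*cfg.proximal_junctional, n)
    dap_dj = rng.normal(*cfg.distal_junctional, n)
    if mm:
        dap_pj = _moment_match(dap_pj, *cfg.proximal_junctional)
        dap_dj = _moment_match(dap_dj, *cfg.distal_junctional)
    dap_pj = _clip_restore_mean(dap_pj, -bound, bound, cfg.proximal_junctional[0])
    dap_dj = _clip_restore_mean(dap_dj, -bound, bound, cfg.distal_junctional[0])

    size = np.clip(rng.normal(1.0, 0.035, n), 0.9, 1.1)
    noise_seeds = rng.integers(0, 2**31 - 1, n)

    specs = []
    width = len(str(n))
    for i in range(n):
        specs.append(
            SubjectSpec(
                subject_id=f"ais{i + 1:0{width}d}",
                group="ais",
                curve_pattern=str(patterns[i]),
                layout=CurveLayout(),
                targets={
                    "cobb_t": float(cobb_t[i]),
                    "cobb_l": float(cobb_l[i]),
                    "rot_t": float(rot_t[i]),
                    "rot_l": float(rot_l[i]),
                    "main_thoracic": float(dap_t[i]),
                    "thoracolumbar": float(dap_l[i]),
                    "apical_thoracic": float(dap_at[i]),
                    "apical_lumbar": float(dap_al[i]),
                    "proximal_junctional": float(dap_pj[i]),
                    "distal_junctional": float(dap_dj[i]),
                },
                standing_cobb={"main_thoracic": float(standing_t[i]), "thoracolumbar": float(standing_l[i])},
                size_scale=float(size[i]),
                noise_seed=int(noise_seeds[i]),
                wedge_noise_deg=cfg.wedge_noise_deg,
                twist_noise_deg=cfg.twist_noise_deg,
            )
        )
    return specs


def _draw_control_specs(cfg: CohortConfig, rng: np.random.Generator) -> list[SubjectSpec]:
    n = cfg.n_subjects
    mm = cfg.moment_match
    dap_t = rng.normal(*cfg.control_thoracic, n)
    dap_l = rng.normal(*cfg.control_lumbar, n)
    if mm:
        dap_t = _moment_match(dap_t, *cfg.control_thoracic)
        dap_l = _moment_match(dap_l, *cfg.control_lumbar)
    size = np.clip(rng.normal(1.0, 0.035, n), 0.9, 1.1)
    noise_seeds = rng.integers(0, 2**31 - 1, n)
    width = len(str(n))
    return [
        SubjectSpec(
            subject_id=f"ctl{i + 1:0{width}d}",
            group="control",
            curve_pattern="none",
            targets={"thoracic_T4T12": float(dap_t[i]), "lumbar_L1L5": float(dap_l[i])},
            size_scale=float(size[i]),
            noise_seed=int(noise_seeds[i]),
            wedge_noise_deg=cfg.wedge_noise_deg,
            twist_noise_deg=cfg.control_twist_noise_deg,
        )
        for i in range(n)
    ]


def generate_cohort(config: CohortConfig) -> list[tuple[SubjectContours, SubjectTruth]]:
    """Generate a full cohort; reproducible under a fixed ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    specs = _draw_ais_specs(config, rng) if config.group == "ais" else _draw_control_specs(config, rng)
    anatomy = default_anatomy()
    return [generate_subject(spec, anatomy=anatomy) for spec in specs]


def truth_table(truths: list[SubjectTruth]) -> pd.DataFrame:
    """One row per subject x region with all ground-truth metrics."""
    rows = []
    for t in truths:
        for region, m in t.region_truth.items():
            rows.append(
                {
                    "subject_id": t.subject_id,
                    "group": t.group,
                    "curve_pattern": t.curve_pattern,
                    "region": region,
                    **m,
                    "standing_cobb_deg": t.standing_cobb.get(region, float("nan")),
                }
            )
    return pd.DataFrame(rows)


# re-export the voxel round-trip surface of this module
from .raster import LabeledVolume, extract_contours, rasterize  # noqa: E402,F401
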