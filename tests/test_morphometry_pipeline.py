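import numpy as np
import pytest

from conftest import apply_rigid, measure, rigid_motion
from spinemorph.levels import span_elements
from spinemorph.morphometry_pipeline import (
    PipelineConfig,
    RegionSpec,
    delta_ap,
    define_regions,
    detect_curves,
    element_heights,
    measure_contours,
    measure_subject,
    region_lengths,
)
from spinemorph.spine_model import ElementHeights, build_spine_model
from spinemorph.synthetic_cohort import build_chain, default_elements


class TestDeltaAp:
    def test_equal_lengths(self):
        assert delta_ap(147.0, 147.0) == 0.0

    def test_ten_percent(self):
        assert delta_ap(110.0, 100.0) == 10.0

    def test_printed_mean_lengths(self):
        # (153 - 147) / 147 * 100, evaluated independently
        assert delta_ap(153.0, 147.0) == pytest.approx(4.081632653061225, abs=1e-12)

    def test_exact_formula_identity(self, rng):
        for _ in range(100):
            a, p = rng.uniform(50, 300), rng.uniform(50, 300)
            assert delta_ap(a, p) == (a - p) / p * 100.0

    @pytest.mark.parametrize("posterior", [0.0, -5.0])
    def test_nonpositive_posterior_raises(self, posterior):
        with pytest.raises(ValueError):
            delta_ap(100.0, posterior)


class TestElementHeights:
    def test_straight_stack_heights_match_anatomy(self, straight_subject):
        contours, truth = straight_subject
        spine = build_spine_model(contours)
        heights = {h.element_id: h for h in element_heights(spine)}
        base = {e.element_id: e.base_height_mm for e in truth.elements}
        ay = {e.element_id: e.semi_axis_ap_mm for e in truth.elements if "-" not in e.element_id}
        ay["S1"] = 18.0
        for eid, h in heights.items():
            if "-" in eid:
                # a disc spans endplates of two different AP radii: its height
                # picks up the (tiny) in-plane offset of the landmarks
                up, lo = eid.split("-")
                expected = np.hypot(base[eid], ay[up] - ay[lo])
            else:
                expected = base[eid]
            assert h.anterior_mm == pytest.approx(expected, abs=1e-9)
            assert h.posterior_mm == pytest.approx(expected, abs=1e-9)

    def test_single_sagittal_wedge_closed_form(self):
        # one wedged vertebra: anterior - posterior = 4 a sin(wedge / 2)
        from spinemorph.synthetic_cohort import _chain_contours
        from spinemorph.spine_model import SubjectContours

        elements = default_elements()
        target = next(e for e in elements if e.element_id == "L2")
        target.sagittal_wedge_deg = 8.0
        chain = build_chain(elements)
        spine = build_spine_model(SubjectContours(subject_id="wedge", contours=_chain_contours(chain)))
        h = {x.element_id: x for x in element_heights(spine)}["L2"]
        expected = 4.0 * target.semi_axis_ap_mm * np.sin(np.radians(4.0))
        assert h.anterior_mm - h.posterior_mm == pytest.approx(expected, abs=1e-9)
        assert h.anterior_mm > h.posterior_mm

    def test_rigid_motion_preserves_heights(self, ais_subject, rng):
        contours, _ = ais_subject
        R, t = rigid_motion(rng)
        moved = apply_rigid(contours, R, t)
        h0 = element_heights(build_spine_model(contours))
        h1 = element_heights(build_spine_model(moved))
        for a, b in zip(h0, h1):
            assert a.anterior_mm == pytest.approx(b.anterior_mm, abs=1e-9)
            assert a.posterior_mm == pytest.approx(b.posterior_mm, abs=1e-9)


def fake_heights(elements, anterior, posterior):
    return [ElementHeights(element_id=e, anterior_mm=anterior, posterior_mm=posterior) for e in elements]


class TestRegionLengths:
    def test_summation(self):
        elements = span_elements("T4", "T8")  # 5 vertebrae + 4 discs
        region = RegionSpec(name="span", elements=tuple(elements))
        a, p = region_lengths(fake_heights(elements, 17.0, 16.0), region)
        assert a == pytest.approx(9 * 17.0)
        assert p == pytest.approx(9 * 16.0)

    def test_single_element(self):
        region = RegionSpec(name="one", elements=("T8",))
        a, p = region_lengths(fake_heights(["T8"], 15.3, 14.7), region)
        assert (a, p) == (15.3, 14.7)

    def test_concatenation_additivity(self):
        all_el = span_elements("T4", "T12")
        heights = [
            ElementHeights(element_id=e, anterior_mm=10.0 + i, posterior_mm=9.0 + i) for i, e in enumerate(all_el)
        ]
        whole = RegionSpec(name="whole", elements=tuple(all_el))
        upper = RegionSpec(name="a", elements=tuple(span_elements("T4", "T8")))
        lower = RegionSpec(name="b", elements=tuple(span_elements("T9", "T12")))
        # split leaves out the shared disc T8-T9; add it back explicitly
        disc = next(h for h in heights if h.element_id == "T8-T9")
        wa, wp = region_lengths(heights, whole)
        ua, up = region_lengths(heights, upper)
        la, lp = region_lengths(heights, lower)
        assert wa == pytest.approx(ua + la + disc.anterior_mm)
        assert wp == pytest.approx(up + lp + disc.posterior_mm)

    def test_missing_element_raises(self):
        region = RegionSpec(name="span", elements=tuple(span_elements("T4", "T6")))
        with pytest.raises(Exception, match="T4"):
            region_lengths(fake_heights(["T5"], 1, 1), region)


class TestDetectCurves:
    def test_straight_spine_empty(self, straight_subject):
        spine = build_spine_model(straight_subject[0])
        assert detect_curves(spine) == []

    def test_generated_double_curve_matches_truth(self, ais_subject):
        contours, truth = ais_subject
        spine = build_spine_model(contours)
        curves = {(c.upper_end, c.apex, c.lower_end): c for c in detect_curves(spine)}
        lay = truth.layout
        assert (lay.t_upper, lay.t_apex, lay.t_lower) in curves
        assert (lay.l_upper, lay.l_apex, lay.l_lower) in curves
        thoracic = curves[(lay.t_upper, lay.t_apex, lay.t_lower)]
        lumbar = curves[(lay.l_upper, lay.l_apex, lay.l_lower)]
        assert thoracic.convexity == "right"
        assert lumbar.convexity == "left"
        assert thoracic.cobb_deg == pytest.approx(truth.targets["cobb_t"], abs=0.5)

    def test_cohort_detection_matches_truth(self, small_ais_cohort):
        for contours, truth in small_ais_cohort:
            spine = build_spine_model(contours)
            found = {(c.upper_end, c.apex, c.lower_end) for c in detect_curves(spine)}
            lay = truth.layout
            assert (lay.t_upper, lay.t_apex, lay.t_lower) in found, contours.subject_id
            assert (lay.l_upper, lay.l_apex, lay.l_lower) in found, contours.subject_id

    def test_cobb_floor_discards_small_curves(self, ais_subject):
        spine = build_spine_model(ais_subject[0])
        high_floor = detect_curves(spine, PipelineConfig(cobb_floor_deg=45.0))
        assert len(high_floor) == 1  # only the thoracic curve survives

    def test_manual_override(self, ais_subject):
        spine = build_spine_model(ais_subject[0])
        cfg = PipelineConfig(curve_overrides=(("T6", "T9", "T12", "right"),))
        curves = detect_curves(spine, cfg)
        assert len(curves) == 1
        assert (curves[0].upper_end, curves[0].apex, curves[0].lower_end) == ("T6", "T9", "T12")


class TestDefineRegions:
    def test_example_layout(self, ais_subject):
        spine = build_spine_model(ais_subject[0])
        regions = {r.name: r for r in define_regions(spine, detect_curves(spine))}
        assert set(regions) == {
            "main_thoracic",
            "apical_thoracic",
            "thoracolumbar",
            "apical_lumbar",
            "proximal_junctional",
            "distal_junctional",
        }
        assert regions["apical_thoracic"].elements == ("T7", "T7-T8", "T8", "T8-T9", "T9")
        assert regions["distal_junctional"].elements == ("T11", "T11-T12", "T12")
        assert regions["proximal_junctional"].elements == ("T4", "T4-T5", "T5")

    def test_control_subject_two_spans(self, straight_subject):
        spine = build_spine_model(straight_subject[0])
        regions = define_regions(spine, [])
        assert [r.name for r in regions] == ["thoracic_T4T12", "lumbar_L1L5"]
        assert regions[0].elements[0] == "T4" and regions[0].elements[-1] == "T12"
        assert regions[1].elements[0] == "L1" and regions[1].elements[-1] == "L5"

    def test_region_partition_sanity(self, ais_subject):
        spine = build_spine_model(ais_subject[0])
        regions = {r.name: r for r in define_regions(spine, detect_curves(spine))}
        curve = set(regions["main_thoracic"].elements)
        assert set(regions["apical_thoracic"].elements) <= curve
        for junctional in ("proximal_junctional", "distal_junctional"):
            overlap = [e for e in regions[junctional].elements if e in curve and "-" not in e]
            assert len(overlap) == 1

    def test_junctional_and_apical_shape_invariants(self):
        with pytest.raises(ValueError):
            RegionSpec(name="proximal_junctional", elements=tuple(span_elements("T3", "T5")))
        with pytest.raises(ValueError):
            RegionSpec(name="apical_thoracic", elements=tuple(span_elements("T7", "T10")))
        with pytest.raises(ValueError, match="contiguous"):
            RegionSpec(name="span", elements=("T4", "T5"))


class TestMeasurement:
    def test_straight_spine_all_zero(self, straight_subject):
        metrics = measure(straight_subject[0])
        for m in metrics.values():
            assert m.cobb_deg == pytest.approx(0.0, abs=1e-6)
            assert m.axial_rotation_deg == pytest.approx(0.0, abs=1e-6)
            assert m.delta_ap_percent == pytest.approx(0.0, abs=1e-9)

    def test_calibrated_subject_recovers_targets(self, ais_subject):
        contours, truth = ais_subject
        metrics = measure(contours)
        assert metrics["main_thoracic"].cobb_deg == pytest.approx(58.0, abs=0.1)
        assert metrics["main_thoracic"].axial_rotation_deg == pytest.approx(24.0, abs=0.1)
        assert metrics["main_thoracic"].delta_ap_percent == pytest.approx(3.8, abs=0.05)
        assert metrics["thoracolumbar"].axial_rotation_deg == pytest.approx(-9.0, abs=0.1)
        assert metrics["apical_thoracic"].delta_ap_percent == pytest.approx(7.1, abs=0.05)
        assert metrics["proximal_junctional"].delta_ap_percent == pytest.approx(-1.3, abs=0.05)

    def test_delta_identity_exact_on_all_regions(self, small_ais_cohort):
        for contours, _ in small_ais_cohort:
            _, _, metrics = measure_contours(contours)
            for m in metrics:
                assert m.delta_ap_percent == (m.anterior_mm - m.posterior_mm) / m.posterior_mm * 100.0

    def test_idempotence(self, ais_subject):
        spine = build_spine_model(ais_subject[0])
        regions = define_regions(spine, detect_curves(spine))
        first = measure_subject(spine, regions)
        second = measure_subject(spine, regions)
        assert first == second

    def test_rigid_motion_invariance_of_all_metrics(self, ais_subject, rng):
        contours, _ = ais_subject
        base = measure(contours)
        for _ in range(3):
            R, t = rigid_motion(rng)
            moved = measure(apply_rigid(contours, R, t))
            for name, m in base.items():
                assert moved[name].delta_ap_percent == pytest.approx(m.delta_ap_percent, abs=1e-8)
                assert moved[name].cobb_deg == pytest.approx(m.cobb_deg, abs=1e-8)
                assert moved[name].axial_rotation_deg == pytest.approx(m.axial_rotation_deg, abs=1e-8)

    def test_control_sign_pattern(self, small_control_cohort):
        # thoracic span kyphotic (negative), lumbar span lordotic (positive)
        for contours, _ in small_control_cohort:
            metrics = measure(contours)
            assert metrics["thoracic_T4T12"].delta_ap_percent < 0
            assert metrics["lumbar_L1L5"].delta_ap_percent > 0
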