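import numpy as np
import pytest

from spinemorph.morphometry_pipeline import measure_cohort, measure_contours
from spinemorph.synthetic_cohort import (
    CohortConfig,
    CurveLayout,
    SubjectSpec,
    generate_cohort,
    generate_subject,
    straight_subject_spec,
)


@pytest.fixture(scope="session")
def straight_subject():
    contours, truth = generate_subject(straight_subject_spec())
    return contours, truth


@pytest.fixture(scope="session")
def ais_subject():
    """One calibrated double-curve subject with round targets."""
    spec = SubjectSpec(
        subject_id="ais_demo",
        group="ais",
        curve_pattern="thoracic",
        layout=CurveLayout(),
        targets=dict(
            cobb_t=58.0,
            cobb_l=28.0,
            rot_t=24.0,
            rot_l=-9.0,
            main_thoracic=3.8,
            thoracolumbar=9.4,
            apical_thoracic=7.1,
            apical_lumbar=11.2,
            proximal_junctional=-1.3,
            distal_junctional=1.0,
        ),
        standing_cobb={"main_thoracic": 63.0, "thoracolumbar": 31.0},
        noise_seed=7,
        wedge_noise_deg=0.05,
        twist_noise_deg=0.1,
    )
    return generate_subject(spec)


@pytest.fixture(scope="session")
def small_ais_cohort():
    return generate_cohort(CohortConfig(group="ais", n_subjects=10, seed=5))


@pytest.fixture(scope="session")
def small_control_cohort():
    return generate_cohort(CohortConfig(group="control", n_subjects=8, seed=6))


@pytest.fixture(scope="session")
def small_cohort_table(small_ais_cohort, small_control_cohort):
    subjects = [c for c, _ in small_ais_cohort] + [c for c, _ in small_control_cohort]
    return measure_cohort(subjects)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def rigid_motion(rng):
    """A random rigid transform (rotation matrix, translation)."""
    from scipy.spatial.transform import Rotation

    R = Rotation.from_rotvec(rng.normal(0.0, 0.6, 3)).as_matrix()
    t = rng.normal(0.0, 40.0, 3)
    return R, t


def apply_rigid(subject, R, t):
    moved = subject.copy()
    for c in moved.contours:
        c.points = c.points @ R.T + t
        c.canal_centroid = R @ c.canal_centroid + t
    return moved


def measure(subject):
    _, _, metrics = measure_contours(subject)
    return {m.region: m for m in metrics}
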