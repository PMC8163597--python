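import pytest
from hypothesis import settings

from clinconsist.records import Restoration, SurfaceClass, ToothSite

settings.register_profile("deterministic", derandomize=True, max_examples=80)
settings.load_profile("deterministic")

#: Lowest per-restoration DIs of the ten-restoration worked example.
WORKED_EXAMPLE_MIN_DIS = (4, 3, 5, 5, 6, 6, 4, 5, 4, 6)


def make_restoration(min_di=5, *, restoration_id="r1", student_id="s1", cohort_id="C1",
                     year_of_study=5, staff_id="st1", patient_id="p1",
                     quadrant=3, tooth=6, surface=SurfaceClass.OCCLUSAL_SURFACE,
                     flag=False, stage_dis=None, material="composite"):
    """Build a valid Restoration; stage DIs default to (min_di, 6) so the
    minimum equals ``min_di``."""
    if stage_dis is None:
        stage_dis = (min_di, 6)
    return Restoration(
        restoration_id=restoration_id, student_id=student_id, cohort_id=cohort_id,
        year_of_study=year_of_study, staff_id=staff_id, patient_id=patient_id,
        site=ToothSite(quadrant=quadrant, position=tooth), surface=surface,
        staff_difficult_flag=flag, stage_dis=tuple(stage_dis), material=material,
    )


@pytest.fixture
def restoration_factory():
    return make_restoration


@pytest.fixture
def worked_example():
    """Ten restorations of one final-year student with the documented lowest
    stage DIs 4, 3, 5, 5, 6, 6, 4, 5, 4, 6."""
    return [make_restoration(d, restoration_id=f"r{i}", patient_id=f"p{i % 4}")
            for i, d in enumerate(WORKED_EXAMPLE_MIN_DIS)]


@pytest.fixture(scope="session")
def small_cohort_frame():
    from clinconsist.synthetic import SimulationConfig, simulate_frame
    return simulate_frame(SimulationConfig(n_students_per_cohort=6, seed=11))
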