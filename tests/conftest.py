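import pytest

from mficyto.gating import GateConfig, annotate
from mficyto.preprocessing import arcsinh_transform
from mficyto.synth import StudyDesign, default_panel, generate_study


@pytest.fixture(scope="session")
def small_study():
    """A compact default-gestation study shared across test modules."""
    design = StudyDesign(
        events_per_sample=1000,
        mice_per_day=2,
        days=(10.5, 12.5, 14.5, 16.5, 18.5),
        seed=11,
    )
    events, sample_meta, gt = generate_study(design)
    return design, events, sample_meta, gt


@pytest.fixture(scope="session")
def transformed_study(small_study):
    design, events, sample_meta, gt = small_study
    return design, arcsinh_transform(events), sample_meta, gt


@pytest.fixture(scope="session")
def annotated_study(transformed_study):
    design, events, sample_meta, gt = transformed_study
    annotation = annotate(events, GateConfig())
    return design, events, sample_meta, gt, annotation


@pytest.fixture(scope="session")
def minimal_panel():
    return default_panel(minimal=True)
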