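import numpy as np
import pytest

from spcnet.labels import fuse_labels
from spcnet.phantom import (
    PhantomParams,
    generate_prostate_mask,
    place_lesions,
    render_case,
)
from spcnet.training import PreparedCase

# coarse grid keeps phantom fixtures fast while staying within realistic
# acquisition geometry (0.8 mm in-plane, 3 mm slices)
COARSE = dict(in_plane_spacing_mm=0.8, grid=(16, 96, 96))


@pytest.fixture(scope="session")
def coarse_params() -> PhantomParams:
    return PhantomParams(seed=11, **COARSE)


@pytest.fixture(scope="session")
def gland_mask(coarse_params):
    rng = np.random.default_rng(5)
    return generate_prostate_mask(coarse_params, rng)


@pytest.fixture(scope="session")
def mixed_case(coarse_params, gland_mask):
    rng = np.random.default_rng(6)
    gm = place_lesions(gland_mask, coarse_params, rng, "mixed", n_lesions=2)
    return render_case(gland_mask, gm, coarse_params, rng, "case-mixed")


@pytest.fixture(scope="session")
def normal_case(coarse_params, gland_mask):
    rng = np.random.default_rng(7)
    gm = place_lesions(gland_mask, coarse_params, rng, "normal")
    return render_case(gland_mask, gm, coarse_params, rng, "case-normal", "normal")


def prepared_from_case(case) -> PreparedCase:
    """PreparedCase straight from a phantom case (no resample/crop), with
    raw intensities; good enough for label/lesion/evaluation tests."""
    labels = fuse_labels(case.grade_map, case.pathologist_mask, case.prostate_mask)
    return PreparedCase(
        case_id=case.case_id,
        t2w=case.t2w.data,
        adc=case.adc.data,
        gland=case.prostate_mask.data.astype(bool),
        labels=labels,
        cohort_tag=case.cohort_tag,
    )


@pytest.fixture(scope="session")
def mixed_prepared(mixed_case) -> PreparedCase:
    return prepared_from_case(mixed_case)


@pytest.fixture(scope="session")
def normal_prepared(normal_case) -> PreparedCase:
    return prepared_from_case(normal_case)
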