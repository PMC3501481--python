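import numpy as np
import pytest

from dmnclass.study_design import canonical_designs
from dmnclass.rest_extraction import RestSegment, RestSeries
from dmnclass.synthetic_cohort import (
    default_exclusion,
    generate_cohort,
    make_dmn_cohort_spec,
    tissue_masks,
)


@pytest.fixture(scope="session")
def designs():
    return canonical_designs()


def make_roi_series(data2d: np.ndarray, n_runs: int = 1, tr: float = 1.0) -> RestSeries:
    """Wrap a 2D (roi, t) array as a RestSeries with evenly split segments."""
    data2d = np.asarray(data2d, dtype=float)
    t = data2d.shape[-1]
    bounds = np.linspace(0, t, n_runs + 1).astype(int)
    segments = tuple(
        RestSegment(run_index=i, block_index=0, src_start=0,
                    src_stop=bounds[i + 1] - bounds[i],
                    dst_start=bounds[i], dst_stop=bounds[i + 1])
        for i in range(n_runs)
    )
    return RestSeries(data=data2d, segments=segments, tr=tr)


@pytest.fixture(scope="session")
def small_roi_cohort(designs):
    """3 + 3 subjects, ROI mode, planted effect 0.3 (fast shared fixture)."""
    spec = make_dmn_cohort_spec(0.3, seed=11, n_group_a=3, n_group_b=3)
    subjects = generate_cohort(spec, designs, mode="roi")
    return spec, subjects


@pytest.fixture(scope="session")
def roi_masks():
    return tissue_masks(116)


@pytest.fixture(scope="session")
def roi_exclusion(small_roi_cohort):
    spec, _ = small_roi_cohort
    return default_exclusion(spec)
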