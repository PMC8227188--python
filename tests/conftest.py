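import numpy as np
import pytest

from foveapit.pipeline import StudyConfig, run_center_comparison
from foveapit.preprocessing import resample_radial
from foveapit.center_location import locate_smooth_min
from foveapit.pipeline import scan_to_cloud
from foveapit.synthetic import make_cohort

COHORT_SEED = 1729


@pytest.fixture(scope="session")
def model_cohort():
    """50-eye noisy cohort under the default acquisition conditions."""
    return make_cohort(50, seed=COHORT_SEED)


@pytest.fixture(scope="session")
def model_cohort_radial(model_cohort):
    """Smooth+min-centered radial profile sets for the model cohort.

    Computed once per session.  Occasional out-of-hull tail samples in
    star acquisitions stay NaN and are skipped sample-wise downstream.
    """
    out = []
    for rec in model_cohort:
        sets = {}
        for pattern, scan in (("raster", rec.raster), ("star", rec.star)):
            cloud = scan_to_cloud(scan)
            sets[pattern] = resample_radial(cloud, center=locate_smooth_min(cloud))
        out.append((rec, sets))
    return out


@pytest.fixture(scope="session")
def center_cohort():
    """50-eye cohort with fixation decentration up to 0.4 mm.

    The larger offsets (the worst observed misfixation in clinical raster/
    star pairs is around 0.35 mm) are the regime where centering methods
    actually differ.
    """
    return make_cohort(
        50, decenter_sd_mm=0.15, decenter_max_mm=0.40, seed=COHORT_SEED + 1
    )


@pytest.fixture(scope="session")
def center_report(center_cohort):
    """Center-location comparison on the decentered cohort (computed once)."""
    return run_center_comparison(center_cohort, StudyConfig(seed=COHORT_SEED + 1))
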