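import numpy as np
import pytest

import ficollnmr as f


@pytest.fixture(scope="session")
def small_axis():
    """Coarse ppm grid for fast unit tests (same span as the default grid)."""
    return f.default_ppm_axis(n_points=4096)


@pytest.fixture(scope="session")
def library():
    return f.make_metabolite_library(20, seed=1)


@pytest.fixture(scope="session")
def paired_cohort(small_axis):
    """Small paired two-group cohort with a clear anesthesia decrease."""
    design = f.CohortDesign(n_subjects_per_group=6, anesthesia_decrease=0.7,
                            subject_sd=0.1, noise_sd=0.02, seed=11,
                            axis=small_axis)
    return f.simulate_cohort(design)


@pytest.fixture(scope="session")
def paired_matrix(paired_cohort):
    matrix = f.build_bucket_matrix([s.spectrum for s in paired_cohort])
    annotations = [s.annotation for s in paired_cohort]
    return matrix, annotations
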