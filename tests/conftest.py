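import logging

import numpy as np
import pytest

from tipdating.io_formats import AnnotationRow, AnnotationTable
from tipdating.synthetic_data import StudyConfig, make_study_dataset

logging.getLogger("tipdating").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(20_260_927)


@pytest.fixture(scope="session")
def small_annotation():
    """Single unpartitioned 400 bp layout with a short internal VNTR."""
    return AnnotationTable([
        AnnotationRow("control_region", 1, 400),
        AnnotationRow("VNTR", 150, 200),
    ])


@pytest.fixture(scope="session")
def small_dataset(small_annotation):
    """8 calibrated + 1 undated ingroup tips, no outgroup; fast to date."""
    cfg = StudyConfig(n_calibrated=8, n_undated=1, n_outgroup=0,
                      seq_length=400, annotation=small_annotation)
    return make_study_dataset(cfg, seed=3)


@pytest.fixture(scope="session")
def study_dataset():
    """Six-partition 3 kb dataset with outgroup, for pipeline-level tests."""
    from tipdating.synthetic_data import compact_annotation

    cfg = StudyConfig(n_calibrated=10, n_undated=2, n_outgroup=2,
                      seq_length=3000, annotation=compact_annotation(3000))
    return make_study_dataset(cfg, seed=11)
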