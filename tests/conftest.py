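import numpy as np
import pytest
from hypothesis import settings

from lncoexp import ExpressionMatrix, SimulationParams, StudyDesign
from lncoexp.io_formats import DesignEntry

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("suite")


@pytest.fixture
def paired_design() -> StudyDesign:
    entries = [DesignEntry(f"C{i}", f"p{i}", "tumor") for i in (1, 2, 3)]
    entries += [DesignEntry(f"N{i}", f"p{i}", "normal") for i in (1, 2, 3)]
    return StudyDesign(entries)


@pytest.fixture
def small_matrix(paired_design) -> ExpressionMatrix:
    rng = np.random.default_rng(7)
    values = rng.normal(8, 2, (10, 6))
    return ExpressionMatrix([f"probe{i}" for i in range(10)],
                            [e.sample_id for e in paired_design.entries],
                            values, None)


@pytest.fixture
def tiny_params() -> SimulationParams:
    """Scaled-down cohort for fast pipeline-level tests."""
    return SimulationParams(n_lncrna=60, n_mrna=60, module_size=6,
                            n_terms=8, n_tfs=6, set_size=12,
                            qpcr_n_patients=4)
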