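import numpy as np
import pytest

from tumoronly.pipeline import default_knowledge_base, make_fixtures
from tumoronly.synth import CohortGenerator


@pytest.fixture(scope="session")
def tiny_cohort():
    """12-sample, 3-gene cohort with panels — hand-checkable scale."""
    cfg = make_fixtures("tiny", seed=11)
    gen = CohortGenerator(cfg)
    data = gen.generate_cohort()
    panels = gen.generate_reference_panels()
    kb = default_knowledge_base(cfg)
    return cfg, data, panels, kb


@pytest.fixture(scope="session")
def small_cohort():
    """400-sample, 20-gene cohort for statistical checks."""
    cfg = make_fixtures("small", seed=5)
    gen = CohortGenerator(cfg)
    data = gen.generate_cohort()
    panels = gen.generate_reference_panels()
    multistudy = gen.generate_multistudy_maf()
    return cfg, data, panels, multistudy


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
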