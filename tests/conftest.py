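import numpy as np
import pytest

from ridgemix import GrowthParams, PrintRecord, ReferenceRecord
from ridgemix.growth import expected_mrb


@pytest.fixture
def growth():
    return GrowthParams()


@pytest.fixture(scope="module")
def growth_module():
    return GrowthParams()


@pytest.fixture
def reference_population(growth):
    """Synthetic reference individuals (age, sex, MRB) spanning 2-70 years."""
    rng = np.random.default_rng(42)
    records = []
    for sex in (1, 2):
        ages = np.concatenate([rng.uniform(2, 15, 60), rng.uniform(15, 70, 90)])
        for age in ages:
            mrb = expected_mrb(age, sex, growth) + rng.normal(0, growth.sigma)
            records.append(ReferenceRecord(age=float(age), sex=sex, mrb=max(mrb, 0.05)))
    return records


@pytest.fixture
def adult_male_prints(growth):
    """A Type1-like assemblage: adult men only, tight MRB spread."""
    rng = np.random.default_rng(7)
    mrbs = expected_mrb(rng.uniform(25, 60, 60), 2, growth) + rng.normal(0, growth.sigma, 60)
    return [PrintRecord(id=f"p{i}", mrb=float(m), n_ridges=10)
            for i, m in enumerate(mrbs)]
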