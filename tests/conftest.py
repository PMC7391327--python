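import pytest
from hypothesis import settings

from sealpup.data import SiteYearRecord, SurvivalDataset

settings.register_profile("stable", derandomize=True, deadline=None)
settings.load_profile("stable")
from sealpup.synthetic import generate, pembrokeshire_design


def rec(area, site, year, pups, survivors):
    """Hand-build a post-correction record from integer counts."""
    return SiteYearRecord.from_raw(area, site, year, pups, survivors, correct=False)


@pytest.fixture
def toy_dataset():
    """Five records, two areas, three sites — small enough to check by hand."""
    return SurvivalDataset(
        records=[
            rec("A", "a1", 2001, 10, 8),   # 0.8
            rec("A", "a1", 2002, 20, 10),  # 0.5
            rec("A", "a2", 2002, 5, 5),    # 1.0
            rec("B", "b1", 2001, 40, 20),  # 0.5
            rec("B", "b1", 2002, 10, 9),   # 0.9
        ]
    )


@pytest.fixture(scope="session")
def design_dataset():
    """One realisation of the three-area monitoring design."""
    return generate(pembrokeshire_design(seed=7))
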