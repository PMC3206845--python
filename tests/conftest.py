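from pathlib import Path

import numpy as np
import pytest

from strandmeth.genome import ReferenceRegion, enumerate_cpg_sites
from strandmeth.simulate import GeneratorConfig, make_synthetic_region

FIXTURE_DIR = Path(__file__).resolve().parent.parent / "fixtures"


@pytest.fixture(scope="session")
def fixture_cohort_dir() -> Path:
    return FIXTURE_DIR / "example_cohort"


@pytest.fixture()
def toy_region() -> ReferenceRegion:
    # hand-built: CpG sites at positions 2, 8 and 14
    return ReferenceRegion("TOY", "ACGTTTTCGATTACGAT")


@pytest.fixture()
def toy_site_map(toy_region):
    return enumerate_cpg_sites(toy_region)


@pytest.fixture(scope="session")
def synth_region() -> ReferenceRegion:
    return make_synthetic_region(30, seed=11)


@pytest.fixture(scope="session")
def synth_site_map(synth_region):
    return enumerate_cpg_sites(synth_region)


@pytest.fixture()
def small_config() -> GeneratorConfig:
    return GeneratorConfig(
        seed=3,
        cohort_sizes={"HCC": 4, "adjacent_non_HCC": 4, "cirrhosis": 3,
                      "hepatitis": 3, "normal_liver": 2},
        clone_samples_per_group={"normal_liver": 1, "HCC": 1, "adjacent_non_HCC": 1},
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
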