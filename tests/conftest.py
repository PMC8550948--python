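import numpy as np
import pytest

from paleodairy import synthetic_data as sd
from paleodairy.taxonomy import default_taxonomy


@pytest.fixture(scope="session")
def tree():
    return default_taxonomy()


@pytest.fixture(scope="session")
def small_cohort():
    """A compact noiseless cohort shared across tests."""
    spec = sd.CohortSpec(
        seed=7,
        individuals_per_period={"eneolithic": 4, "early_bronze": 4, "middle_late_bronze": 4},
        preserved_per_period={"eneolithic": 3, "early_bronze": 4, "middle_late_bronze": 4},
        dairy_prevalence={"eneolithic": 0.0, "early_bronze": 0.75, "middle_late_bronze": 0.5},
        equivocal_per_period={"eneolithic": 1, "early_bronze": 0, "middle_late_bronze": 0},
        equus_positives_early_bronze=1,
        protein_families_range=(25, 60),
        noiseless=True,
    )
    return sd.simulate_cohort(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def naive_tryptic_digest(seq: str, missed_cleavages: int, min_length: int) -> set[str]:
    """Independent scan-and-split digestion oracle (cleave after K/R, not
    before P), used to cross-check the production digest."""
    sites = [i + 1 for i in range(len(seq) - 1) if seq[i] in "KR" and seq[i + 1] != "P"]
    bounds = [0] + sites + [len(seq)]
    peptides = set()
    for i in range(len(bounds) - 1):
        for j in range(i + 1, min(i + 2 + missed_cleavages, len(bounds))):
            pep = seq[bounds[i] : bounds[j]]
            if len(pep) >= min_length:
                peptides.add(pep)
    return peptides
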