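import numpy as np
import pytest
from hypothesis import settings

from immunopop.model import AlleleCatalog, GenotypeRecord, PopulationGenotypes

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

COMPLEMENT_CYCLE = {"A": "C", "C": "G", "G": "T", "T": "A"}


def make_diverged_pair(length: int = 219, n_diff: int = 23, seed: int = 42):
    """Two aligned sequences of given length differing at exactly n_diff sites."""
    rng = np.random.default_rng(seed)
    base = rng.choice(list("ACGT"), size=length)
    alt = base.copy()
    for p in rng.choice(length, size=n_diff, replace=False):
        alt[p] = COMPLEMENT_CYCLE[alt[p]]
    return "".join(base), "".join(alt)


@pytest.fixture(scope="session")
def otawa_catalog() -> AlleleCatalog:
    """Two-allele catalog shaped like the lowest-diversity study population:
    219 aligned nucleotides, 23 differences."""
    major, minor = make_diverged_pair()
    return AlleleCatalog("DAB", {"DAB*74": major, "DAB*73": minor})


@pytest.fixture(scope="session")
def otawa_genotypes() -> PopulationGenotypes:
    """19 diploids: 17 homozygous for the major allele, 2 heterozygous."""
    records = [
        GenotypeRecord(f"hom{i}", "Otawa", "DAB", "DAB*74", "DAB*74")
        for i in range(17)
    ] + [
        GenotypeRecord(f"het{i}", "Otawa", "DAB", "DAB*73", "DAB*74")
        for i in range(2)
    ]
    return PopulationGenotypes(records)


@pytest.fixture(scope="session")
def published_selection_table():
    from importlib import resources

    from immunopop.io import read_selection_table

    return read_selection_table(
        resources.files("immunopop.data") / "dab_site_selection.tsv"
    )
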