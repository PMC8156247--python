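import pytest

from cyclomine.ptm import candidate_mass_list
from cyclomine.refdata import REFERENCE_PRECURSORS


@pytest.fixture(scope="session")
def reference_rows():
    return REFERENCE_PRECURSORS


@pytest.fixture(scope="session")
def reference_proteins(reference_rows):
    """The 21 reference precursors as (id, sequence) FASTA-style records."""
    return [(p.gene_id, p.sequence) for p in reference_rows]


@pytest.fixture(scope="session")
def reference_cores(reference_rows):
    """The 17 unique core peptides, first-occurrence order."""
    seen = []
    for p in reference_rows:
        if p.core not in seen:
            seen.append(p.core)
    return seen


@pytest.fixture(scope="session")
def reference_candidates(reference_cores):
    """Candidate list over the 17 cores: 17 bare cycles + 2 amatoxin states."""
    return candidate_mass_list(reference_cores)
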