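import pytest

from pepscreen.peptide_library import ParentProtein, PeptideCandidate
from pepscreen.peptides import KU1, KU3
from pepscreen.synthetic import ku80_ct_scaffold


@pytest.fixture(scope="session")
def parent() -> ParentProtein:
    """Synthetic 120-residue Ku80-Ct parent (absolute numbering 590-709)."""
    return ku80_ct_scaffold()


@pytest.fixture(scope="session")
def ku3(parent) -> PeptideCandidate:
    """The Ku3 peptide as a candidate of the parent region (span 676-703)."""
    pep = PeptideCandidate(
        sequence=KU3.sequence, parent_id=parent.id,
        parent_start=KU3.parent_start, parent_end=KU3.parent_end,
    )
    assert parent.subsequence(676, 703) == pep.sequence
    return pep


@pytest.fixture(scope="session")
def ku1_sequence() -> str:
    return KU1.sequence
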