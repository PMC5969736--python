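import pytest

from crisprcoupler import ReferenceLibrary, design_library


@pytest.fixture(scope="session")
def small_design():
    """A 6-construct library, large enough to show uncoupling patterns."""
    return design_library(6, seed=11)


@pytest.fixture(scope="session")
def small_refs(small_design):
    return ReferenceLibrary.from_design(small_design)


@pytest.fixture(scope="session")
def paper_design():
    """The 57-construct paired design matching the study's library size."""
    return design_library(57, seed=3)


@pytest.fixture(scope="session")
def paper_refs(paper_design):
    return ReferenceLibrary.from_design(paper_design)
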