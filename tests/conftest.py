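import pytest

from uvcbkit.design_registry import (
    AttachmentRules,
    LibraryDesign,
    Scaffold,
    SubstituentGroup,
    paper_fixture,
)


def make_scaffold(id="S", structure="C1CCCCC1", positions=None, **kw):
    positions = positions if positions is not None else [0, 1, 2, 3, 4, 5]
    return Scaffold(id=id, structure=structure, attachment_positions=positions, **kw)


def make_alkyl(id="R1", structure="*C"):
    return SubstituentGroup(id=id, structure=structure, group_class="alkyl")


def make_acid(id="Q1", structure="*CC(=O)O"):
    return SubstituentGroup(id=id, structure=structure, group_class="alkyl_acid")


def make_design(scaffolds=None, alkyls=None, acids=None, **rules):
    return LibraryDesign(
        scaffolds=scaffolds or [make_scaffold()],
        alkyl_groups=alkyls or [make_alkyl()],
        acid_groups=acids or [make_acid()],
        rules=AttachmentRules(**rules),
    )


@pytest.fixture(scope="session")
def paper_design():
    return paper_fixture()


@pytest.fixture(scope="session")
def paper_library(paper_design):
    """Full enumeration of the packaged design (slow; shared across tests)."""
    from uvcbkit.enumerator import enumerate_library

    return enumerate_library(paper_design)
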