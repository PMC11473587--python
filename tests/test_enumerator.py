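"""Enumerator unit tests, including an independent brute-force oracle.

The oracle builds products through RDKit's molzip joining (a different
mechanism than the enumerator's bond surgery) and deduplicates on
canonical SMILES (a different identity function than InChIKey blocks).
"""

import itertools

import pytest
from rdkit import Chem
from rdkit.Chem import rdMolDescriptors

from conftest import make_acid, make_alkyl, make_design, make_scaffold
from uvcbkit.design_registry import SubstituentGroup
from uvcbkit.enumerator import (
    EnumeratedStructure,
    Provenance,
    attach_group,
    deduplicate,
    enumerate_library,
    write_csv,
    write_smiles,
)
from uvcbkit.errors import AttachmentError, ConfigurationError, DesignValidationError
from uvcbkit.profiler import skeleton_key


# ---------------------------------------------------------------------------
# independent oracle

def _oracle_attach(mol, pos, group_smiles):
    """Join via atom-mapped dummies and Chem.molzip."""
    rw = Chem.RWMol(mol)
    d = rw.AddAtom(Chem.Atom(0))
    rw.GetAtomWithIdx(d).SetAtomMapNum(1)
    rw.AddBond(pos, d, Chem.BondType.SINGLE)
    grp = Chem.MolFromSmiles(group_smiles)
    grw = Chem.RWMol(grp)
    for a in grw.GetAtoms():
        if a.GetAtomicNum() == 0:
            a.SetAtomMapNum(1)
    zipped = Chem.molzip(rw.GetMol(), grw.GetMol())
    Chem.SanitizeMol(zipped)
    return zipped


def oracle_enumerate(design):
    """All labeled placements, canonical-SMILES dedup."""
    out = set()
    for scaffold in design.scaffolds:
        core = scaffold.mol()
        for pa, pc in itertools.product(scaffold.alkyl_positions, scaffold.acid_positions):
            if pa == pc and not design.rules.allow_geminal:
                continue
            for alkyl in design.alkyl_groups:
                for acid in design.acid_groups:
                    m = _oracle_attach(core, pa, alkyl.structure)
                    m = _oracle_attach(m, pc, acid.structure)
                    out.add(Chem.MolToSmiles(m))
    return out


# ---------------------------------------------------------------------------

class TestAttachGroup:
    def test_methyl_on_cyclohexane_any_position(self):
        s = make_scaffold()
        expected = Chem.CanonSmiles("CC1CCCCC1")
        for pos in s.attachment_positions:
            mol = attach_group(s, pos, make_alkyl())
            assert Chem.MolToSmiles(mol) == expected

    def test_acetic_chain_gives_cyclohexaneacetic_acid(self):
        mol = attach_group(make_scaffold(), 0, make_acid())
        assert Chem.MolToSmiles(mol) == Chem.CanonSmiles("OC(=O)CC1CCCCC1")

    def test_formula_bookkeeping(self):
        # C6H12 + C2H3O2-marker -> C8H14O2
        mol = attach_group(make_scaffold(), 0, make_acid())
        assert rdMolDescriptors.CalcMolFormula(mol) == "C8H14O2"

    def test_position_without_hydrogen_rejected(self):
        neopentane_core = make_scaffold(structure="CC1(C)CCCC1", positions=[0])
        with pytest.raises(AttachmentError, match="no hydrogen"):
            attach_group(neopentane_core, 1, make_alkyl())

    def test_two_marker_group_rejected(self):
        grp = Chem.MolFromSmiles("*C*")
        with pytest.raises(DesignValidationError, match="marker"):
            attach_group(make_scaffold(), 0, grp)

    def test_scaffold_indices_stable_for_double_substitution(self):
        s = make_scaffold()
        mono = attach_group(s, 0, make_alkyl())
        di = attach_group(mono, 3, make_acid())
        assert Chem.MolToSmiles(di) == Chem.CanonSmiles("CC1CCC(CC(=O)O)CC1")


class TestEnumerateLibrary:
    def test_symmetric_core_collapses_to_substitution_patterns(self):
        # one alkyl + one acid on cyclohexane -> ortho/meta/para only
        result = enumerate_library(make_design())
        assert len(result.structures) == 3

    def test_matches_oracle_on_toy_designs(self):
        designs = [
            make_design(),
            make_design(
                scaffolds=[make_scaffold(structure="C1CCC2CCCCC12", positions=[0, 1, 5])],
                alkyls=[make_alkyl("R1", "*C"), make_alkyl("R2", "*CC")],
            ),
            make_design(
                scaffolds=[
                    make_scaffold("S1", "C1CCCC1", [0, 1]),
                    make_scaffold("S2", "C1CCCCC1", [0, 2, 4]),
                ],
                alkyls=[make_alkyl("R1", "*C"), make_alkyl("R2", "*C(C)C")],
                acids=[make_acid("Q1", "*CC(=O)O"), make_acid("Q2", "*C(C)C(=O)O")],
            ),
        ]
        for design in designs:
            expected = oracle_enumerate(design)
            got = {s.structure for s in enumerate_library(design).structures}
            assert got == expected

    def test_oracle_equivalence_with_geminal(self):
        design = make_design(
            scaffolds=[make_scaffold(structure="C1CCCC1", positions=[0, 1])],
            allow_geminal=True,
        )
        assert {s.structure for s in enumerate_library(design).structures} == oracle_enumerate(design)

    def test_every_product_has_one_acid_and_a_ring(self, paper_design):
        design = make_design(
            scaffolds=[make_scaffold(structure="C1CCC2CCCCC12", positions=[0, 4, 8])],
            alkyls=[make_alkyl("R1", "*CC"), make_alkyl("R2", "*C(C)C")],
        )
        cooh = Chem.MolFromSmarts("[CX3](=O)[OX2H1]")
        for s in enumerate_library(design).structures:
            mol = Chem.MolFromSmiles(s.structure)
            assert len(mol.GetSubstructMatches(cooh)) == 1
            assert any(a.IsInRing() for a in mol.GetAtoms())

    def test_determinism(self, tmp_path):
        design = make_design(
            alkyls=[make_alkyl("R1", "*C"), make_alkyl("R2", "*CCC")],
            acids=[make_acid("Q1"), make_acid("Q2", "*CCC(=O)O")],
        )
        p1, p2 = tmp_path / "a.smi", tmp_path / "b.smi"
        write_smiles(enumerate_library(design).structures, p1)
        write_smiles(enumerate_library(design).structures, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_sorted_output(self):
        result = enumerate_library(make_design())
        smiles = [s.structure for s in result.structures]
        assert smiles == sorted(smiles)

    def test_empty_group_set_rejected(self):
        design = make_design()
        design = design.model_copy(update={"acid_groups": []})
        with pytest.raises(ConfigurationError):
            enumerate_library(design)

    def test_provenance_references_design(self):
        design = make_design()
        for s in enumerate_library(design).structures:
            assert s.provenance.scaffold_id == design.scaffolds[0].id
            assert s.provenance.alkyl_position in design.scaffolds[0].alkyl_positions


class TestDeduplicate:
    def _entry(self, smiles):
        mol = Chem.MolFromSmiles(smiles)
        from rdkit.Chem import inchi

        key = inchi.MolToInchiKey(mol)
        return EnumeratedStructure(
            structure=Chem.MolToSmiles(mol),
            inchikey=key,
            skeleton_key=key[:14],
            provenance=Provenance("s", "a", 0, "q", 1),
        )

    def test_duplicates_collapse(self):
        entries = [self._entry("CC1CCCCC1"), self._entry("C1CCCCC1C")]
        assert len(deduplicate(entries)) == 1

    def test_idempotent(self):
        entries = [self._entry("CC1CCCCC1"), self._entry("CCC")]
        once = deduplicate(entries)
        assert deduplicate(once) == once

    def test_stereo_variants_collapse(self):
        entries = [
            self._entry("C[C@H]1CC[C@@H](C(=O)O)CC1"),
            self._entry("C[C@@H]1CC[C@@H](C(=O)O)CC1"),
        ]
        assert len(deduplicate(entries)) == 1

    def test_first_seen_provenance_kept(self):
        a, b = self._entry("CC1CCCCC1"), self._entry("C1CCCCC1C")
        b = EnumeratedStructure(b.structure, b.inchikey, b.skeleton_key,
                                Provenance("other", "x", 1, "y", 2))
        assert deduplicate([a, b])[0].provenance == a.provenance

    def test_missing_keys_rejected(self):
        bad = EnumeratedStructure("CCC", "", "", Provenance("s", "a", 0, "q", 1))
        with pytest.raises(DesignValidationError, match="identity"):
            deduplicate([bad])

    def test_inconsistent_keys_rejected(self):
        with pytest.raises(DesignValidationError, match="14"):
            EnumeratedStructure(
                "CCC", "ATUOYWHBWRKTHZ-UHFFFAOYSA-N", "XXXXXXXXXXXXXX",
                Provenance("s", "a", 0, "q", 1),
            )


class TestWriters:
    def test_csv_round_trip(self, tmp_path):
        import pandas as pd

        result = enumerate_library(make_design())
        path = tmp_path / "lib.csv"
        write_csv(result.structures, path)
        df = pd.read_csv(path)
        assert list(df["structure"]) == [s.structure for s in result.structures]
        assert (df["skeleton_key"].str.len() == 14).all()
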