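"""Library designs: scaffolds, R-group sets, and attachment rules.

A *library design* declares everything needed to enumerate the organic
component space of a UVCB: ring-system scaffolds with their eligible
attachment positions, a set of alkyl substituents, a set of
carboxylic-acid-bearing substituents, and the attachment policy.  Designs
are stored as human-editable YAML; all structures are SMILES strings with
substituent attachment points marked by a single dummy atom (``*``).

The packaged naphthenic-acid design (8 cores, 26 alkyl chains, 15 acid
chains) is available through :func:`paper_fixture`.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator
from rdkit import Chem

from .errors import ChemistryError, DesignSchemaError, DesignValidationError

__all__ = [
    "Scaffold",
    "SubstituentGroup",
    "AttachmentRules",
    "LibraryDesign",
    "load_design",
    "save_design",
    "paper_fixture",
    "PAPER_FIXTURE_NAME",
]

PAPER_FIXTURE_NAME = "naphthenic_acid_library.yaml"

_COOH = Chem.MolFromSmarts("[CX3](=O)[OX2H1]")


def _parse_smiles(smiles: str, owner: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ChemistryError(f"{owner}: invalid SMILES {smiles!r}")
    return mol


class Scaffold(BaseModel):
    """A core ring system with attachment positions for each group class.

    Attachment positions are atom indices into the scaffold SMILES as
    written.  They may be listed per class (``alkyl_positions`` /
    ``acid_positions``) or once for both via ``attachment_positions``.
    Each position must be a carbon bearing at least one hydrogen; ring
    carbons are the normal case, exocyclic arm carbons are permitted for
    cores drawn with a methylene attachment arm.
    """

    id: str
    structure: str
    ring_class: str = ""
    label: str = ""
    alkyl_positions: list[int] = Field(default_factory=list)
    acid_positions: list[int] = Field(default_factory=list)

    @model_validator(mode="before")
    @classmethod
    def _expand_shared_positions(cls, data):
        if isinstance(data, dict) and "attachment_positions" in data:
            shared = data.pop("attachment_positions")
            data.setdefault("alkyl_positions", list(shared))
            data.setdefault("acid_positions", list(shared))
        return data

    @model_validator(mode="after")
    def _check_chemistry(self) -> "Scaffold":
        mol = _parse_smiles(self.structure, f"scaffold {self.id!r}")
        if not self.alkyl_positions or not self.acid_positions:
            raise DesignValidationError(
                f"scaffold {self.id!r}: attachment positions must be non-empty"
            )
        for pos in {*self.alkyl_positions, *self.acid_positions}:
            if pos < 0 or pos >= mol.GetNumAtoms():
                raise DesignValidationError(
                    f"scaffold {self.id!r}: attachment position {pos} out of range"
                )
            atom = mol.GetAtomWithIdx(pos)
            if atom.GetAtomicNum() != 6 or atom.GetTotalNumHs() < 1:
                raise DesignValidationError(
                    f"scaffold {self.id!r}: position {pos} is not a CH carbon"
                )
        if not any(a.IsInRing() for a in mol.GetAtoms()):
            raise DesignValidationError(f"scaffold {self.id!r}: no ring system")
        return self

    @property
    def attachment_positions(self) -> list[int]:
        """Union of the per-class attachment positions, sorted."""
        return sorted({*self.alkyl_positions, *self.acid_positions})

    def mol(self) -> Chem.Mol:
        return _parse_smiles(self.structure, f"scaffold {self.id!r}")

    def canonicalized(self) -> "Scaffold":
        """Re-express the scaffold against RDKit's canonical atom order.

        The structure is rewritten as the canonical SMILES and the
        attachment positions are remapped through the canonical atom
        ranking, so that two input orderings of the same scaffold yield
        identical canonical forms.
        """
        mol = self.mol()
        order = list(
            Chem.CanonicalRankAtoms(mol, includeChirality=False)
        )  # old index -> canonical rank
        canonical = Chem.MolToSmiles(mol)
        # MolToSmiles output atom order: map via _smilesAtomOutputOrder
        out_order = list(mol.GetPropsAsDict(True, True)["_smilesAtomOutputOrder"])
        new_index = {old: new for new, old in enumerate(out_order)}
        del order
        return self.model_copy(
            update={
                "structure": canonical,
                "alkyl_positions": sorted(new_index[p] for p in self.alkyl_positions),
                "acid_positions": sorted(new_index[p] for p in self.acid_positions),
            }
        )


class SubstituentGroup(BaseModel):
    """An R-group: a substituent with exactly one ``*`` attachment marker."""

    id: str
    structure: str
    group_class: Literal["alkyl", "alkyl_acid"]
    label: str = ""
    carbon_count: int = 0

    @model_validator(mode="after")
    def _check_chemistry(self) -> "SubstituentGroup":
        mol = _parse_smiles(self.structure, f"group {self.id!r}")
        stars = [a for a in mol.GetAtoms() if a.GetAtomicNum() == 0]
        if len(stars) != 1:
            raise DesignValidationError(
                f"group {self.id!r}: expected exactly one '*' marker, "
                f"found {len(stars)}"
            )
        n_cooh = len(mol.GetSubstructMatches(_COOH))
        if self.group_class == "alkyl_acid" and n_cooh != 1:
            raise DesignValidationError(
                f"group {self.id!r}: alkyl_acid groups must contain exactly one "
                f"carboxylic acid (found {n_cooh})"
            )
        if self.group_class == "alkyl":
            if n_cooh != 0:
                raise DesignValidationError(
                    f"group {self.id!r}: alkyl groups must not contain a "
                    "carboxylic acid"
                )
            if any(a.GetAtomicNum() not in (0, 6) for a in mol.GetAtoms()):
                raise DesignValidationError(
                    f"group {self.id!r}: alkyl groups may contain only carbon"
                )
        n_carbon = sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 6)
        if self.carbon_count and self.carbon_count != n_carbon:
            raise DesignValidationError(
                f"group {self.id!r}: declared carbon_count {self.carbon_count} "
                f"!= structure carbon count {n_carbon}"
            )
        object.__setattr__(self, "carbon_count", n_carbon)
        if n_carbon < 1:
            raise DesignValidationError(f"group {self.id!r}: carbon_count < 1")
        return self

    def mol(self) -> Chem.Mol:
        return _parse_smiles(self.structure, f"group {self.id!r}")


class AttachmentRules(BaseModel):
    """Attachment policy applied during enumeration."""

    one_alkyl_one_acid: bool = True
    allow_geminal: bool = False


class LibraryDesign(BaseModel):
    """A validated library design ready for enumeration."""

    name: str = "library"
    description: str = ""
    scaffolds: list[Scaffold]
    alkyl_groups: list[SubstituentGroup]
    acid_groups: list[SubstituentGroup]
    rules: AttachmentRules = Field(default_factory=AttachmentRules)

    @model_validator(mode="after")
    def _check_consistency(self) -> "LibraryDesign":
        ids = [s.id for s in self.scaffolds] + [
            g.id for g in self.alkyl_groups + self.acid_groups
        ]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise DesignValidationError(f"duplicate ids in design: {sorted(dupes)}")
        for g in self.alkyl_groups:
            if g.group_class != "alkyl":
                raise DesignValidationError(
                    f"group {g.id!r} listed under alkyl_groups but has class "
                    f"{g.group_class!r}"
                )
        for g in self.acid_groups:
            if g.group_class != "alkyl_acid":
                raise DesignValidationError(
                    f"group {g.id!r} listed under acid_groups but has class "
                    f"{g.group_class!r}"
                )
        return self

    @property
    def counts(self) -> tuple[int, int, int]:
        """(n scaffolds, n alkyl groups, n acid groups)."""
        return (len(self.scaffolds), len(self.alkyl_groups), len(self.acid_groups))

    def to_dict(self) -> dict:
        return self.model_dump(exclude_defaults=False)


def load_design(path: str | Path) -> LibraryDesign:
    """Load and validate a library design from a YAML file.

    Parameters
    ----------
    path
        Path to a design file conforming to the documented schema.

    Raises
    ------
    DesignSchemaError
        If the file cannot be read or lacks the required sections.
    ChemistryError
        If a SMILES string fails to parse (the message names the entry).
    DesignValidationError
        If an entry violates a design invariant.
    """
    path = Path(path)
    if not path.exists():
        raise DesignSchemaError(f"design file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise DesignSchemaError(f"{path}: not valid YAML: {exc}") from exc
    return design_from_dict(raw, source=str(path))


def design_from_dict(raw: dict, source: str = "<dict>") -> LibraryDesign:
    """Build a validated design from an already-parsed mapping."""
    if not isinstance(raw, dict):
        raise DesignSchemaError(f"{source}: design root must be a mapping")
    for section in ("scaffolds", "alkyl_groups", "acid_groups"):
        if section not in raw:
            raise DesignSchemaError(f"{source}: missing required section {section!r}")
        if not isinstance(raw[section], list):
            raise DesignSchemaError(f"{source}: section {section!r} must be a list")
    scaffolds = [Scaffold(**entry) for entry in raw["scaffolds"]]
    alkyls = [
        SubstituentGroup(**{"group_class": "alkyl", **entry})
        for entry in raw["alkyl_groups"]
    ]
    acids = [
        SubstituentGroup(**{"group_class": "alkyl_acid", **entry})
        for entry in raw["acid_groups"]
    ]
    rules = AttachmentRules(**raw.get("rules", {}))
    return LibraryDesign(
        name=raw.get("name", "library"),
        description=raw.get("description", ""),
        scaffolds=scaffolds,
        alkyl_groups=alkyls,
        acid_groups=acids,
        rules=rules,
    )


def save_design(design: LibraryDesign, path: str | Path) -> None:
    """Serialize a design back to YAML (round-trips through load_design)."""
    data = {
        "name": design.name,
        "description": design.description,
        "rules": design.rules.model_dump(),
        "scaffolds": [
            {
                "id": s.id,
                "label": s.label,
                "ring_class": s.ring_class,
                "structure": s.structure,
                "alkyl_positions": s.alkyl_positions,
                "acid_positions": s.acid_positions,
            }
            for s in design.scaffolds
        ],
        "alkyl_groups": [
            {"id": g.id, "label": g.label, "structure": g.structure}
            for g in design.alkyl_groups
        ],
        "acid_groups": [
            {"id": g.id, "label": g.label, "structure": g.structure}
            for g in design.acid_groups
        ],
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def paper_fixture() -> LibraryDesign:
    """The packaged naphthenic-acid library design (8 cores, 26 alkyls, 15 acids)."""
    ref = importlib.resources.files("uvcbkit.data").joinpath(PAPER_FIXTURE_NAME)
    raw = yaml.safe_load(ref.read_text())
    return design_from_dict(raw, source=PAPER_FIXTURE_NAME)
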