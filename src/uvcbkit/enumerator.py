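"""Two-step combinatorial enumeration of scaffold + alkyl + acid libraries.

For every scaffold, one alkyl group and one acid group are attached over all
declared attachment-position pairs.  Products are canonicalized and
deduplicated on the connectivity block of the standard InChIKey (the
*skeleton key*), which is insensitive to stereochemistry, charge, tautomers
and isotopes.  Symmetric placements therefore collapse without any explicit
symmetry perception, and identical products arising from different cores
collapse globally.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem import inchi

from .design_registry import LibraryDesign, Scaffold, SubstituentGroup
from .errors import AttachmentError, ChemistryError, ConfigurationError, DesignValidationError

RDLogger.DisableLog("rdApp.*")
logger = logging.getLogger(__name__)

__all__ = [
    "Provenance",
    "EnumeratedStructure",
    "EnumerationResult",
    "attach_group",
    "enumerate_library",
    "deduplicate",
    "write_smiles",
    "write_sdf",
    "write_csv",
]


@dataclass(frozen=True)
class Provenance:
    """Which design entries produced a structure (first-seen on duplicates)."""

    scaffold_id: str
    alkyl_id: str
    alkyl_position: int
    acid_id: str
    acid_position: int


@dataclass(frozen=True)
class EnumeratedStructure:
    """A canonical enumerated product with its identity keys."""

    structure: str  # canonical SMILES
    inchikey: str
    skeleton_key: str
    provenance: Provenance

    def __post_init__(self):
        if self.inchikey and self.skeleton_key != self.inchikey[:14]:
            raise DesignValidationError(
                f"skeleton_key {self.skeleton_key!r} is not the first 14 "
                f"characters of {self.inchikey!r}"
            )


@dataclass
class EnumerationResult:
    """Deduplicated structures plus per-combination failure bookkeeping."""

    structures: list[EnumeratedStructure]
    n_products: int = 0
    failures: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.structures)


def _single_marker_neighbor(group_mol: Chem.Mol, owner: str) -> tuple[Chem.Mol, int, int]:
    stars = [a.GetIdx() for a in group_mol.GetAtoms() if a.GetAtomicNum() == 0]
    if len(stars) != 1:
        raise DesignValidationError(
            f"{owner}: group must carry exactly one '*' marker, found {len(stars)}"
        )
    star = stars[0]
    nbrs = [b.GetOtherAtomIdx(star) for b in group_mol.GetAtomWithIdx(star).GetBonds()]
    if len(nbrs) != 1:
        raise DesignValidationError(f"{owner}: marker must have exactly one neighbor")
    return group_mol, star, nbrs[0]


def attach_group(
    scaffold: Scaffold | Chem.Mol,
    position: int,
    group: SubstituentGroup | Chem.Mol,
) -> Chem.Mol:
    """Bond a marked substituent to a scaffold atom, consuming one hydrogen.

    Parameters
    ----------
    scaffold
        A :class:`~uvcbkit.design_registry.Scaffold` or an RDKit molecule.
        Atom indices of the scaffold are preserved in the product, so the
        operation can be applied twice for disubstitution.
    position
        Index of the scaffold atom to substitute; must have >= 1 hydrogen.
    group
        A substituent with exactly one ``*`` attachment marker.

    Returns
    -------
    rdkit.Chem.Mol
        The sanitized product.  Its molecular formula equals scaffold
        formula + group formula - H (the marker replaces one hydrogen).
    """
    core = scaffold.mol() if isinstance(scaffold, Scaffold) else scaffold
    gmol = group.mol() if isinstance(group, SubstituentGroup) else group
    owner = group.id if isinstance(group, SubstituentGroup) else "group"
    if position < 0 or position >= core.GetNumAtoms():
        raise AttachmentError(f"position {position} out of range")
    if core.GetAtomWithIdx(position).GetTotalNumHs() < 1:
        raise AttachmentError(
            f"position {position} has no hydrogen available for substitution"
        )
    gmol, star, star_nbr = _single_marker_neighbor(gmol, owner)
    n = core.GetNumAtoms()
    combo = Chem.RWMol(Chem.CombineMols(core, gmol))
    combo.AddBond(position, n + star_nbr, Chem.BondType.SINGLE)
    combo.RemoveAtom(n + star)
    product = combo.GetMol()
    try:
        Chem.SanitizeMol(product)
    except Exception as exc:  # pragma: no cover - valence failures are rare
        raise ChemistryError(f"substitution at {position} failed: {exc}") from exc
    return product


def _identity(mol: Chem.Mol) -> tuple[str, str, str]:
    smiles = Chem.MolToSmiles(mol)
    key = inchi.MolToInchiKey(mol)
    if not key:
        raise ChemistryError(f"InChIKey generation failed for {smiles}")
    return smiles, key, key[:14]


def enumerate_library(
    design: LibraryDesign,
    allow_geminal: bool | None = None,
) -> EnumerationResult:
    """Enumerate all scaffold x alkyl x acid placements and deduplicate.

    One alkyl and one acid group are attached per product, covering every
    declared (alkyl position, acid position) pair.  Geminal (same-atom)
    double substitution is skipped unless enabled by the design rules or
    the ``allow_geminal`` override.  Chemistry failures on individual
    combinations are logged and counted, never fatal.

    The returned structures are sorted by canonical SMILES, so two runs
    over the same design are byte-identical.
    """
    if not design.alkyl_groups or not design.acid_groups:
        raise ConfigurationError("design must declare at least one group per class")
    if allow_geminal is None:
        allow_geminal = design.rules.allow_geminal

    structures: list[EnumeratedStructure] = []
    failures: list[str] = []
    n_products = 0
    scaffold_mols = {s.id: s.mol() for s in design.scaffolds}
    alkyl_mols = {g.id: g.mol() for g in design.alkyl_groups}
    acid_mols = {g.id: g.mol() for g in design.acid_groups}

    for scaffold in design.scaffolds:
        core = scaffold_mols[scaffold.id]
        for pa in scaffold.alkyl_positions:
            for alkyl in design.alkyl_groups:
                try:
                    mono = attach_group(core, pa, alkyl_mols[alkyl.id])
                except (AttachmentError, ChemistryError) as exc:
                    failures.append(f"{scaffold.id}/{alkyl.id}@{pa}: {exc}")
                    logger.warning("skipping %s", failures[-1])
                    continue
                for pc in scaffold.acid_positions:
                    if pc == pa and not allow_geminal:
                        continue
                    for acid in design.acid_groups:
                        n_products += 1
                        try:
                            product = attach_group(mono, pc, acid_mols[acid.id])
                            smiles, key, skeleton = _identity(product)
                        except (AttachmentError, ChemistryError) as exc:
                            failures.append(
                                f"{scaffold.id}/{alkyl.id}@{pa}/{acid.id}@{pc}: {exc}"
                            )
                            logger.warning("skipping %s", failures[-1])
                            continue
                        structures.append(
                            EnumeratedStructure(
                                structure=smiles,
                                inchikey=key,
                                skeleton_key=skeleton,
                                provenance=Provenance(
                                    scaffold_id=scaffold.id,
                                    alkyl_id=alkyl.id,
                                    alkyl_position=pa,
                                    acid_id=acid.id,
                                    acid_position=pc,
                                ),
                            )
                        )

    unique = deduplicate(structures)
    unique.sort(key=lambda s: s.structure)
    if failures:
        logger.info("enumeration finished with %d failed combinations", len(failures))
    return EnumerationResult(structures=unique, n_products=n_products, failures=failures)


def deduplicate(structures: Iterable[EnumeratedStructure]) -> list[EnumeratedStructure]:
    """Keep one representative per skeleton key (first seen wins). Idempotent."""
    seen: dict[str, EnumeratedStructure] = {}
    for s in structures:
        if not s.skeleton_key or not s.inchikey:
            raise DesignValidationError(f"structure {s.structure!r} missing identity keys")
        if s.skeleton_key not in seen:
            seen[s.skeleton_key] = s
    return list(seen.values())


# ---------------------------------------------------------------------------
# writers

def write_smiles(structures: Sequence[EnumeratedStructure], path: str | Path) -> None:
    """One SMILES per line with tab-separated provenance."""
    with open(path, "w") as fh:
        for s in structures:
            p = s.provenance
            fh.write(
                f"{s.structure}\t{s.skeleton_key}\t{p.scaffold_id}\t{p.alkyl_id}"
                f"\t{p.alkyl_position}\t{p.acid_id}\t{p.acid_position}\n"
            )


def write_sdf(structures: Sequence[EnumeratedStructure], path: str | Path) -> None:
    writer = Chem.SDWriter(str(path))
    try:
        for s in structures:
            mol = Chem.MolFromSmiles(s.structure)
            mol.SetProp("inchikey", s.inchikey)
            mol.SetProp("skeleton_key", s.skeleton_key)
            p = s.provenance
            mol.SetProp("scaffold_id", p.scaffold_id)
            mol.SetProp("alkyl_id", p.alkyl_id)
            mol.SetProp("alkyl_position", str(p.alkyl_position))
            mol.SetProp("acid_id", p.acid_id)
            mol.SetProp("acid_position", str(p.acid_position))
            writer.write(mol)
    finally:
        writer.close()


def write_csv(structures: Sequence[EnumeratedStructure], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            [
                "structure",
                "inchikey",
                "skeleton_key",
                "scaffold_id",
                "alkyl_id",
                "alkyl_position",
                "acid_id",
                "acid_position",
            ]
        )
        for s in structures:
            p = s.provenance
            w.writerow(
                [
                    s.structure,
                    s.inchikey,
                    s.skeleton_key,
                    p.scaffold_id,
                    p.alkyl_id,
                    p.alkyl_position,
                    p.acid_id,
                    p.acid_position,
                ]
            )
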