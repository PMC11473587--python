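"""Per-structure descriptors and library-level summaries.

Descriptors are the ones the downstream assessment relies on: conventional
molecular weight, cyclization degree (ring heavy atoms / total heavy
atoms), and the InChIKey connectivity block used for structure matching
against local registry tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors, inchi

from .errors import ChemistryError, DesignSchemaError

__all__ = [
    "StructureProfile",
    "MwSummary",
    "molecular_weight",
    "cyclization_degree",
    "skeleton_key",
    "profile",
    "profile_library",
    "match_skeletons",
    "summarize_mw",
    "plot_mw_histogram",
]

#: Experimental mean molecular-weight interval for crude naphthenic acids
#: used as the default library coverage reference (g/mol).
CRUDE_ACID_MW_RANGE = (240.0, 330.0)


@dataclass(frozen=True)
class StructureProfile:
    skeleton_key: str
    mol_weight: float
    cyclization_degree: float
    heavy_atoms: int
    ring_atoms: int

    def __post_init__(self):
        assert 0.0 <= self.cyclization_degree <= 1.0
        assert self.ring_atoms <= self.heavy_atoms
        assert self.mol_weight > 0


def _as_mol(structure: str | Chem.Mol) -> Chem.Mol:
    if isinstance(structure, Chem.Mol):
        return structure
    mol = Chem.MolFromSmiles(structure)
    if mol is None:
        raise ChemistryError(f"invalid structure: {structure!r}")
    return mol


def molecular_weight(structure: str | Chem.Mol) -> float:
    """Conventional (abundance-weighted) molecular weight in g/mol,
    including implicit hydrogens."""
    return Descriptors.MolWt(_as_mol(structure))


def cyclization_degree(structure: str | Chem.Mol) -> float:
    """Fraction of heavy atoms that belong to at least one ring."""
    mol = _as_mol(structure)
    heavy = mol.GetNumHeavyAtoms()
    if heavy == 0:
        raise ChemistryError("structure has no heavy atoms")
    in_ring = sum(1 for a in mol.GetAtoms() if a.IsInRing())
    return in_ring / heavy


def skeleton_key(structure: str | Chem.Mol) -> str:
    """First (connectivity) block of the standard InChIKey.

    Insensitive to stereochemistry, bond-type annotations, charge states,
    tautomerism, and isotopes, which makes it the right identity for
    skeleton searching against registry tables.
    """
    key = inchi.MolToInchiKey(_as_mol(structure))
    if not key:
        raise ChemistryError(f"InChIKey generation failed for {structure!r}")
    return key[:14]


def profile(structure: str | Chem.Mol) -> StructureProfile:
    """Compute the full descriptor profile for one structure."""
    mol = _as_mol(structure)
    heavy = mol.GetNumHeavyAtoms()
    ring = sum(1 for a in mol.GetAtoms() if a.IsInRing())
    return StructureProfile(
        skeleton_key=skeleton_key(mol),
        mol_weight=molecular_weight(mol),
        cyclization_degree=ring / heavy,
        heavy_atoms=heavy,
        ring_atoms=ring,
    )


def profile_library(structures: Iterable) -> pd.DataFrame:
    """Profile an iterable of SMILES or EnumeratedStructure into a table."""
    rows = []
    for s in structures:
        smiles = getattr(s, "structure", s)
        p = profile(smiles)
        rows.append(
            {
                "structure": smiles,
                "skeleton_key": p.skeleton_key,
                "mol_weight": p.mol_weight,
                "cyclization_degree": p.cyclization_degree,
                "heavy_atoms": p.heavy_atoms,
                "ring_atoms": p.ring_atoms,
            }
        )
    return pd.DataFrame(rows)


def match_skeletons(
    library_keys: Iterable[str],
    registry_table: pd.DataFrame,
    key_column: str = "skeleton_key",
) -> pd.DataFrame:
    """Join library skeleton keys against a local registry table.

    Returns the registry rows whose ``key_column`` value appears among the
    library keys (one row per matching registry record, metadata retained).
    This is the offline equivalent of a batch InChIKey-skeleton search
    against an external structure database.
    """
    if key_column not in registry_table.columns:
        raise DesignSchemaError(
            f"registry table lacks required key column {key_column!r}"
        )
    keys = set(library_keys)
    matched = registry_table[registry_table[key_column].isin(keys)].copy()
    matched.reset_index(drop=True, inplace=True)
    return matched


@dataclass(frozen=True)
class MwSummary:
    bin_edges: np.ndarray
    counts: np.ndarray
    n: int
    interval: tuple[float, float]
    coverage: float  # fraction of structures inside the interval


def summarize_mw(
    mol_weights: Sequence[float],
    bin_width: float = 10.0,
    interval: tuple[float, float] = CRUDE_ACID_MW_RANGE,
) -> MwSummary:
    """Histogram of molecular weights plus coverage of a reference interval."""
    weights = np.asarray(list(mol_weights), dtype=float)
    if weights.size == 0:
        raise ValueError("empty library")
    lo = np.floor(weights.min() / bin_width) * bin_width
    hi = np.ceil(weights.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(weights, bins=edges)
    inside = (weights >= interval[0]) & (weights <= interval[1])
    return MwSummary(
        bin_edges=edges,
        counts=counts,
        n=weights.size,
        interval=interval,
        coverage=float(inside.mean()),
    )


def plot_mw_histogram(summary: MwSummary, path: str | Path) -> None:
    """Write a PNG of the molecular-weight distribution with the reference
    interval shaded."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    centers = (summary.bin_edges[:-1] + summary.bin_edges[1:]) / 2
    width = summary.bin_edges[1] - summary.bin_edges[0]
    ax.bar(centers, summary.counts, width=width * 0.95, color="steelblue")
    ax.axvspan(*summary.interval, color="gray", alpha=0.3,
               label=f"reference {summary.interval[0]:g}-{summary.interval[1]:g} g/mol")
    ax.set_xlabel("molecular weight (g/mol)")
    ax.set_ylabel("count")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
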