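"""Similarity-weighted read-across.

Targets and analogs are fingerprinted with circular (Morgan-type)
fingerprints; an endpoint for the target is predicted as the
similarity-weighted mean of the k most similar analogs that carry the
endpoint.  Predicted points of departure can be binned into the standard
four-color dose categories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .errors import ChemistryError, DegenerateNeighborhoodError, MissingDataError

__all__ = [
    "Fingerprint",
    "Analog",
    "ReadAcrossInput",
    "ReadAcrossPrediction",
    "POD_BINS",
    "fingerprint",
    "similarity",
    "genra_predict",
    "bin_pod",
    "load_analog_table",
    "synthetic_analog_table",
]


@dataclass(frozen=True)
class Fingerprint:
    """A fixed-length bit set: the indices of the on bits plus the length."""

    bits: frozenset
    n_bits: int


def fingerprint(structure: str | Chem.Mol, radius: int = 2, n_bits: int = 2048) -> Fingerprint:
    """Deterministic circular substructure fingerprint.

    Defaults (radius 2, 2048 bits) follow common read-across practice and
    are configurable.
    """
    if isinstance(structure, Chem.Mol):
        mol = structure
    else:
        mol = Chem.MolFromSmiles(structure)
        if mol is None:
            raise ChemistryError(f"invalid structure: {structure!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    bv = gen.GetFingerprint(mol)
    return Fingerprint(bits=frozenset(bv.GetOnBits()), n_bits=n_bits)


def similarity(a: Fingerprint, b: Fingerprint) -> float:
    """Jaccard/Tanimoto coefficient |a & b| / |a | b| in [0, 1].

    Defined as 0 when both bit sets are empty.  Raises ``ValueError`` on a
    fingerprint length mismatch.
    """
    if a.n_bits != b.n_bits:
        raise ValueError(f"fingerprint length mismatch: {a.n_bits} != {b.n_bits}")
    union = a.bits | b.bits
    if not union:
        return 0.0
    return len(a.bits & b.bits) / len(union)


@dataclass(frozen=True)
class Analog:
    structure: str
    endpoints: Mapping[str, float]
    label: str = ""


@dataclass
class ReadAcrossInput:
    """A target plus candidate analogs with endpoint values (mg/kg/day)."""

    target: str
    analogs: Sequence[Analog]
    k: int = 6

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        for a in self.analogs:
            for name, v in a.endpoints.items():
                if v is not None and v <= 0:
                    raise ValueError(
                        f"analog {a.structure!r} endpoint {name!r} must be positive"
                    )


@dataclass
class ReadAcrossPrediction:
    endpoint: str
    value: float
    used: list[tuple[str, float, float]] = field(default_factory=list)
    # (analog structure, similarity, endpoint value)


def genra_predict(
    inp: ReadAcrossInput,
    endpoint: str,
    radius: int = 2,
    n_bits: int = 2048,
    log_scale: bool = False,
) -> ReadAcrossPrediction:
    """Similarity-weighted mean of the k nearest analogs with the endpoint.

    The prediction is ``sum(s_i * y_i) / sum(s_i)`` over the ``k`` most
    similar analogs possessing the endpoint; analogs tied in similarity
    with the k-th neighbor are all included, which keeps the result
    independent of analog ordering.  With ``log_scale=True`` the weighting
    is done on log10 dose and transformed back.

    Raises
    ------
    MissingDataError
        If no analog carries the endpoint.
    DegenerateNeighborhoodError
        If every candidate analog has zero similarity to the target.
    """
    tfp = fingerprint(inp.target, radius=radius, n_bits=n_bits)
    scored = []
    for analog in inp.analogs:
        value = analog.endpoints.get(endpoint)
        if value is None:
            continue
        s = similarity(tfp, fingerprint(analog.structure, radius=radius, n_bits=n_bits))
        scored.append((analog.structure, s, float(value)))
    if not scored:
        raise MissingDataError(f"no analog carries endpoint {endpoint!r}")
    scored.sort(key=lambda t: (-t[1], t[0]))
    if len(scored) > inp.k:
        cutoff = scored[inp.k - 1][1]
        scored = [t for t in scored if t[1] >= cutoff]
    if all(s == 0.0 for _, s, _ in scored):
        raise DegenerateNeighborhoodError(
            "all analog similarities are zero; weighted mean undefined"
        )
    wsum = sum(s for _, s, _ in scored)
    if log_scale:
        est = 10 ** (sum(s * math.log10(y) for _, s, y in scored) / wsum)
    else:
        est = sum(s * y for _, s, y in scored) / wsum
    return ReadAcrossPrediction(endpoint=endpoint, value=est, used=scored)


# ---------------------------------------------------------------------------
# POD color bins

#: Left-closed/right-open dose bins (mg/kg/day); the last bin is closed.
POD_BINS: list[tuple[str, float, float]] = [
    ("red", 1.7, 250.0),
    ("orange", 250.0, 600.0),
    ("yellow", 600.0, 1200.0),
    ("green", 1200.0, 4531.0),
]


def bin_pod(value: float) -> tuple[str, bool]:
    """Map a POD (mg/kg/day) to its color bin.

    Returns ``(label, clamped)`` where ``clamped`` flags values outside the
    binned span, which are assigned to the nearest edge bin.
    """
    if value <= 0:
        raise ValueError(f"POD must be positive, got {value}")
    if value < POD_BINS[0][1]:
        return POD_BINS[0][0], True
    if value > POD_BINS[-1][2]:
        return POD_BINS[-1][0], True
    for label, lo, hi in POD_BINS[:-1]:
        if lo <= value < hi:
            return label, False
    return POD_BINS[-1][0], False


# ---------------------------------------------------------------------------
# analog table I/O

def load_analog_table(path: str | Path) -> list[Analog]:
    """Read an analog CSV: a ``structure`` column plus one column per endpoint."""
    df = pd.read_csv(path)
    if "structure" not in df.columns:
        raise MissingDataError("analog table lacks a 'structure' column")
    label_col = "label" if "label" in df.columns else None
    endpoint_cols = [c for c in df.columns if c not in ("structure", "label")]
    analogs = []
    for _, row in df.iterrows():
        endpoints = {
            c: float(row[c]) for c in endpoint_cols if pd.notna(row[c])
        }
        analogs.append(
            Analog(
                structure=row["structure"],
                endpoints=endpoints,
                label=str(row[label_col]) if label_col else "",
            )
        )
    return analogs


def synthetic_analog_table(
    seed: int = 0,
    n: int = 8,
    endpoint: str = "chronic_pod",
    low: float = 10.0,
    high: float = 2000.0,
) -> list[Analog]:
    """Small deterministic analog set for tests and demos.

    Generates cycloalkane carboxylic acids with varying chain lengths and
    log-uniform endpoint values in ``[low, high]``.
    """
    import numpy as np

    rng = np.random.default_rng(seed)
    analogs = []
    for i in range(n):
        ring = 5 + (i % 2)
        chain = 1 + (i % 4)
        smiles = "C1" + "C" * (ring - 1) + "1" + "C" * chain + "C(=O)O"
        value = float(10 ** rng.uniform(math.log10(low), math.log10(high)))
        analogs.append(Analog(structure=smiles, endpoints={endpoint: value}))
    return analogs
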