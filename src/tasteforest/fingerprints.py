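"""Binary fingerprint encodings and Tanimoto similarity.

Four hashed binary fingerprints are supported, matching the common
choices for similarity search and fingerprint-based QSAR:

``morgan``
    Circular (ECFP4-style) fingerprint, radius 2, folded to 2,048 bits.
``morgan_feat``
    Circular fingerprint with pharmacophoric (functional-class) atom
    invariants instead of element-based ones (FCFP4-style), 2,048 bits.
``atompair``
    Hashed atom-pair fingerprint (atom types with topological
    distance), 1,024 bits.
``torsion``
    Hashed topological-torsion fingerprint (linear 4-atom paths),
    1,024 bits.

All fingerprints are binary: hash collisions fold with OR semantics.
They are computed on the standardized, largest-fragment heavy-atom
graph with implicit hydrogen counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .chem_io import MoleculeRecord

#: circular fingerprint radius (ECFP4-equivalent); shared by morgan and morgan_feat
MORGAN_RADIUS = 2

N_BITS = {"morgan": 2048, "morgan_feat": 2048, "atompair": 1024, "torsion": 1024}
KINDS = tuple(N_BITS)


@dataclass(frozen=True)
class BitFingerprint:
    """Fixed-length binary substructure encoding.

    ``on_bits`` is a sorted tuple of set-bit indices in ``[0, n_bits)``.
    """

    kind: str
    n_bits: int
    on_bits: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.kind not in N_BITS:
            raise ValueError(f"unknown fingerprint kind {self.kind!r}")
        if self.n_bits != N_BITS[self.kind]:
            raise ValueError(f"{self.kind} fingerprints have {N_BITS[self.kind]} bits, "
                             f"got {self.n_bits}")
        bits = tuple(sorted(set(self.on_bits)))
        if bits and not (0 <= bits[0] and bits[-1] < self.n_bits):
            raise ValueError("on-bit index out of range")
        object.__setattr__(self, "on_bits", bits)

    def to_array(self) -> np.ndarray:
        """Dense 0/1 vector of length ``n_bits`` (dtype uint8)."""
        v = np.zeros(self.n_bits, dtype=np.uint8)
        if self.on_bits:
            v[list(self.on_bits)] = 1
        return v


def _generator(kind: str):
    if kind == "morgan":
        return rdFingerprintGenerator.GetMorganGenerator(
            radius=MORGAN_RADIUS, fpSize=N_BITS[kind])
    if kind == "morgan_feat":
        return rdFingerprintGenerator.GetMorganGenerator(
            radius=MORGAN_RADIUS, fpSize=N_BITS[kind],
            atomInvariantsGenerator=rdFingerprintGenerator.GetMorganFeatureAtomInvGen())
    if kind == "atompair":
        return rdFingerprintGenerator.GetAtomPairGenerator(fpSize=N_BITS[kind])
    if kind == "torsion":
        return rdFingerprintGenerator.GetTopologicalTorsionGenerator(fpSize=N_BITS[kind])
    raise ValueError(f"unknown fingerprint kind {kind!r}")


def compute_fingerprint(record: MoleculeRecord, kind: str = "morgan") -> BitFingerprint:
    """Compute the binary fingerprint of a standardized record.

    Deterministic: the same standardized structure and kind always
    yield identical on-bits, independent of SMILES atom ordering.
    """
    if not record.is_standardized:
        raise ValueError(f"record {record.id!r} must be standardized before fingerprinting")
    fp = _generator(kind).GetFingerprint(record.mol())
    return BitFingerprint(kind=kind, n_bits=N_BITS[kind],
                          on_bits=tuple(fp.GetOnBits()))


def tanimoto(a: BitFingerprint, b: BitFingerprint) -> float:
    """Tanimoto similarity |A∩B| / |A∪B| over on-bit sets.

    Defined as 1.0 when both sets are empty (identical all-zero
    fingerprints).
    """
    if a.kind != b.kind or a.n_bits != b.n_bits:
        raise ValueError(f"fingerprint mismatch: {a.kind}/{a.n_bits} vs {b.kind}/{b.n_bits}")
    sa, sb = set(a.on_bits), set(b.on_bits)
    union = len(sa | sb)
    if union == 0:
        return 1.0
    return len(sa & sb) / union


def fingerprint_matrix(records: list[MoleculeRecord],
                       kind: str = "morgan") -> tuple[np.ndarray, list[str]]:
    """Stack fingerprints of many records into a binary matrix.

    Returns
    -------
    (matrix, ids)
        ``matrix`` is ``len(records) × n_bits`` uint8 with rows in input
        order; ``ids`` the matching record identifiers.
    """
    if not records:
        raise ValueError("no records to fingerprint")
    rows = [compute_fingerprint(r, kind).to_array() for r in records]
    return np.vstack(rows), [r.id for r in records]


def matrix_to_csv(matrix: np.ndarray, ids: list[str], path) -> None:
    """Export a fingerprint matrix as CSV (id column + one 0/1 column per bit)."""
    import pandas as pd

    df = pd.DataFrame(matrix, columns=[f"bit{j}" for j in range(matrix.shape[1])])
    df.insert(0, "id", ids)
    df.to_csv(path, index=False)
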