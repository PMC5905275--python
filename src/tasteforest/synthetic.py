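"""Synthetic two-class molecule sets with class-enriched substructure motifs.

Real sweet/bitter training data comes from curated taste databases that
cannot be bundled; this generator emulates their essential statistical
shape so every other module is testable offline: two classes of valid,
distinct, drug-like small molecules in which each class is enriched for
a planted substructure motif.

Molecules are assembled by attaching random small substituents from a
fixed vocabulary onto random simple scaffolds.  Motif planting is
symmetric-contamination: a molecule carries its own class's motif with
probability ``motif_purity`` and the other class's motif with
probability ``1 - motif_purity`` (independent draws).  The class signal
is therefore ``2·purity − 1``: purity 1.0 separates the classes
perfectly, purity 0.5 makes the two classes exchangeable — an exact
permutation null.

Default motifs echo taste chemistry: a sulfonamide for the sweet class
(the saccharin substructure family) and a fused N-heterocycle
(quinoline) for the bitter class, bitterness being typical of
alkaloids.  Both are illustrative, not mechanistic, and configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from rdkit import Chem

from .chem_io import MoleculeRecord, standardize

SWEET_MOTIF = "CS(N)(=O)=O"      # methylsulfonamide, attached via its carbon
BITTER_MOTIF = "Cc1ccc2ncccc2c1"  # methylquinoline, attached via its methyl carbon

SCAFFOLDS = (
    "c1ccccc1",      # benzene
    "C1CCCCC1",      # cyclohexane
    "c1ccncc1",      # pyridine
    "c1ccoc1",       # furan
    "c1ccsc1",       # thiophene
    "C1CCOC1",       # tetrahydrofuran
    "C1CCNCC1",      # piperidine
    "CCCCCC",        # hexane chain
    "c1ccc(CC)cc1",  # ethylbenzene
    "C1CC1CCC",      # cyclopropane chain
)

SUBSTITUENTS = (
    "C", "CC", "O", "N", "F", "Cl", "OC", "C(C)C",
    "C(=O)O", "C#N", "CO", "Br", "C(=O)C", "CCO",
)


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic labeled molecule set."""

    n_per_class: int = 300
    motif_sweet: str = SWEET_MOTIF
    motif_bitter: str = BITTER_MOTIF
    motif_purity: float = 0.9
    decoration_depth: int = 3
    seed: int = 0
    scaffolds: tuple[str, ...] = SCAFFOLDS
    substituents: tuple[str, ...] = SUBSTITUENTS

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be positive")
        if not 0.0 <= self.motif_purity <= 1.0:
            raise ValueError("motif_purity must be in [0, 1]")
        for smi in (self.motif_sweet, self.motif_bitter):
            if Chem.MolFromSmiles(smi) is None:
                raise ValueError(f"motif does not parse: {smi!r}")


def _attach(mol: Chem.Mol, frag_smiles: str, rng: np.random.Generator) -> Chem.Mol | None:
    """Attach a fragment (via its first H-bearing atom) to a random H-bearing site."""
    frag = Chem.MolFromSmiles(frag_smiles)
    if frag is None:
        return None
    sites = [a.GetIdx() for a in mol.GetAtoms() if a.GetTotalNumHs() > 0]
    anchors = [a.GetIdx() for a in frag.GetAtoms() if a.GetTotalNumHs() > 0]
    if not sites or not anchors:
        return None
    site = sites[rng.integers(len(sites))]
    anchor = anchors[0]
    base_n = mol.GetNumAtoms()
    combo = Chem.RWMol(Chem.CombineMols(mol, frag))
    combo.AddBond(site, base_n + anchor, Chem.BondType.SINGLE)
    try:
        out = combo.GetMol()
        Chem.SanitizeMol(out)
    except Exception:
        return None
    return out


def _build_molecule(cls: str, spec: FixtureSpec, rng: np.random.Generator) -> tuple[str, dict] | None:
    """One decorated scaffold with motif planting; returns (SMILES, provenance)."""
    own = spec.motif_sweet if cls == "sweet" else spec.motif_bitter
    other = spec.motif_bitter if cls == "sweet" else spec.motif_sweet
    mol = Chem.MolFromSmiles(spec.scaffolds[rng.integers(len(spec.scaffolds))])
    planted = []
    if rng.random() < spec.motif_purity:
        mol = _attach(mol, own, rng)
        planted.append("own")
    if mol is not None and rng.random() < 1.0 - spec.motif_purity:
        mol = _attach(mol, other, rng)
        planted.append("other")
    if mol is None:
        return None
    n_dec = int(rng.integers(1, spec.decoration_depth + 1))
    for _ in range(n_dec):
        nxt = _attach(mol, spec.substituents[rng.integers(len(spec.substituents))], rng)
        if nxt is not None:
            mol = nxt
    return Chem.MolToSmiles(mol), {"planted": planted, "own_motif": own}


def generate_labeled_set(spec: FixtureSpec) -> list[MoleculeRecord]:
    """Generate ``2 × n_per_class`` standardized, labeled, distinct molecules.

    Deterministic per seed (byte-identical SMILES across runs).
    Distinctness is enforced by InChIKey, regenerating collisions up to
    a bounded retry count.  Each record's ``meta`` carries motif
    provenance: which motifs were planted and, when the own-class motif
    is present, the atom indices of its match in the standardized
    structure (``motif_atoms``).
    """
    rng = np.random.default_rng(spec.seed)
    seen: set[str] = set()
    records: list[MoleculeRecord] = []
    max_tries = 200 * 2 * spec.n_per_class
    tries = 0
    for cls in ("sweet", "bitter"):
        made = 0
        while made < spec.n_per_class:
            tries += 1
            if tries > max_tries:
                raise RuntimeError(
                    "could not generate enough distinct molecules; increase "
                    "decoration_depth or the scaffold/substituent vocabulary")
            built = _build_molecule(cls, spec, rng)
            if built is None:
                continue
            smiles, prov = built
            rec = MoleculeRecord(id=f"{cls[0]}{made + 1:04d}", smiles_raw=smiles,
                                 label=cls, source="synthetic")
            try:
                rec = standardize(rec)
            except Exception:
                continue
            if rec.inchikey in seen:
                continue
            seen.add(rec.inchikey)
            rec.meta.update(prov)
            if "own" in prov["planted"]:
                match = rec.mol().GetSubstructMatch(Chem.MolFromSmiles(prov["own_motif"]))
                rec.meta["motif_atoms"] = list(match)
            records.append(rec)
            made += 1
    return records


@dataclass(frozen=True)
class ConfusionCase:
    """One random evaluation vector with independently counted ground truth.

    ``counts`` maps each positive-class perspective to its
    (tp, tn, fp, fn) tuple, counted here by an explicit loop so metric
    implementations can be checked against it.
    """

    labels: tuple[str, ...]
    predictions: tuple[str, ...]
    scores_sweet: tuple[float, ...]
    counts: dict = field(hash=False)
    perfect: bool = False


def _count_cells(labels: Sequence[str], predictions: Sequence[str],
                 positive: str) -> tuple[int, int, int, int]:
    tp = tn = fp = fn = 0
    for y, p in zip(labels, predictions):
        if y == positive and p == positive:
            tp += 1
        elif y != positive and p != positive:
            tn += 1
        elif y != positive and p == positive:
            fp += 1
        else:
            fn += 1
    return tp, tn, fp, fn


def generate_confusion_cases(n: int, seed: int = 0) -> list[ConfusionCase]:
    """Random label/prediction/score triples for metric-oracle testing.

    Each case has 12–100 entries with both classes present; every tenth
    case is a perfect classifier (predictions equal labels, scores
    perfectly ranked).  Ground-truth confusion cells are counted
    independently and stored with the case.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    cases = []
    for i in range(n):
        length = int(rng.integers(12, 101))
        # guarantee both classes
        labels = ["sweet", "bitter"] + [
            "sweet" if rng.random() < rng.uniform(0.2, 0.8) else "bitter"
            for _ in range(length - 2)]
        perfect = i % 10 == 0
        if perfect:
            predictions = list(labels)
            scores = [rng.uniform(0.75, 1.0) if y == "sweet" else rng.uniform(0.0, 0.25)
                      for y in labels]
        else:
            quality = rng.uniform(0.5, 0.95)
            predictions = [y if rng.random() < quality
                           else ("bitter" if y == "sweet" else "sweet")
                           for y in labels]
            scores = [float(np.clip(
                (0.75 if p == "sweet" else 0.25) + rng.normal(0, 0.2), 0, 1))
                for p in predictions]
        counts = {pos: _count_cells(labels, predictions, pos)
                  for pos in ("sweet", "bitter")}
        cases.append(ConfusionCase(labels=tuple(labels), predictions=tuple(predictions),
                                   scores_sweet=tuple(scores), counts=counts,
                                   perfect=perfect))
    return cases
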