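"""Reading, standardizing, deduplicating and writing molecule datasets.

Structures come in as SMILES files, SD files or CSV; each compound is
carried through the pipeline as a :class:`MoleculeRecord`.  The
standardization protocol removes water fragments, keeps the largest
organic fragment of salts and mixtures, perceives aromaticity,
neutralizes adjacent opposite formal charges where valence permits, and
assigns an InChIKey used for duplicate detection.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem

log = logging.getLogger(__name__)

LABELS = ("sweet", "bitter", "unlabeled")

#: fragments dropped outright during standardization (water and its ions)
_WATER_SMILES = {"O", "[OH2]", "[OH-]", "[OH3+]"}


@dataclass
class MoleculeRecord:
    """One compound: identity, structures before/after standardization, taste label.

    Attributes
    ----------
    id : str
        Opaque identifier, unique within a dataset.
    smiles_raw : str
        SMILES as read from the input file.
    smiles_std : str or None
        Canonical SMILES after standardization; ``None`` until standardized.
    inchikey : str or None
        27-character InChIKey of the standardized structure.
    label : str
        ``"sweet"``, ``"bitter"`` or ``"unlabeled"``.
    source : str
        Free-text provenance tag.
    meta : dict
        Optional sidecar metadata (e.g. planted-motif provenance of
        synthetic fixtures); never interpreted by the pipeline itself.
    """

    id: str
    smiles_raw: str
    smiles_std: str | None = None
    inchikey: str | None = None
    label: str = "unlabeled"
    source: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")

    @property
    def is_standardized(self) -> bool:
        return self.smiles_std is not None and self.inchikey is not None

    def mol(self) -> Chem.Mol:
        """RDKit molecule of the standardized structure."""
        if self.smiles_std is None:
            raise ValueError(f"record {self.id!r} is not standardized")
        m = Chem.MolFromSmiles(self.smiles_std)
        if m is None:  # invariant: smiles_std always parses
            raise ValueError(f"standardized SMILES of {self.id!r} does not parse")
        return m


class StandardizationError(ValueError):
    """Raised when a structure cannot be standardized (e.g. water only)."""


def parse_molecules(path: str | Path, format: str | None = None) -> list[MoleculeRecord]:
    """Read molecules from a SMILES (.smi), SD (.sdf) or CSV file.

    CSV files need columns ``id`` and ``smiles`` and may carry ``label``.
    SMILES files hold one molecule per line, optionally followed by a
    whitespace-separated identifier.  Unparsable entries are skipped and
    counted in the log; duplicate or missing titles in SD files receive
    generated identifiers.

    Parameters
    ----------
    path:
        Input file.
    format:
        ``"smiles"``, ``"sdf"`` or ``"csv"``; inferred from the file
        extension when omitted.

    Returns
    -------
    list of MoleculeRecord, unstandardized, in file order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = {".smi": "smiles", ".smiles": "smiles", ".sdf": "sdf",
                  ".sd": "sdf", ".csv": "csv"}.get(path.suffix.lower())
        if format is None:
            raise ValueError(f"cannot infer format from suffix of {path}")
    if format == "smiles":
        records = list(_read_smiles(path))
    elif format == "sdf":
        records = list(_read_sdf(path))
    elif format == "csv":
        records = list(_read_csv(path))
    else:
        raise ValueError(f"unknown format {format!r}")
    if not records:
        raise ValueError(f"no parsable molecules in {path}")
    return records


def _read_smiles(path: Path) -> Iterable[MoleculeRecord]:
    n_skipped = 0
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smi = parts[0]
            if Chem.MolFromSmiles(smi) is None:
                n_skipped += 1
                log.warning("skipping unparsable SMILES on line %d: %s", i + 1, smi)
                continue
            mid = parts[1].strip() if len(parts) > 1 else f"mol{i + 1}"
            yield MoleculeRecord(id=mid, smiles_raw=smi, source=str(path))
    if n_skipped:
        log.info("skipped %d unparsable entries in %s", n_skipped, path)


def _read_sdf(path: Path) -> Iterable[MoleculeRecord]:
    seen: set[str] = set()
    n_skipped = 0
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    for i, mol in enumerate(supplier):
        if mol is None:
            n_skipped += 1
            log.warning("skipping unparsable SD entry %d", i + 1)
            continue
        title = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        mid = title.strip() or f"mol{i + 1}"
        while mid in seen:  # SD titles are not guaranteed unique
            mid = f"{mid}_{i + 1}"
        seen.add(mid)
        label = "unlabeled"
        if mol.HasProp("label"):
            cand = mol.GetProp("label").strip().lower()
            if cand in LABELS:
                label = cand
        yield MoleculeRecord(id=mid, smiles_raw=Chem.MolToSmiles(mol),
                             label=label, source=str(path))
    if n_skipped:
        log.info("skipped %d unparsable entries in %s", n_skipped, path)


def _read_csv(path: Path) -> Iterable[MoleculeRecord]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        cols = {c.lower() for c in reader.fieldnames or ()}
        if {"id", "smiles"} <= cols:
            smiles_col = "smiles"
        elif {"id", "smiles_raw"} <= cols:  # dataset CSV written by write_csv
            smiles_col = "smiles_std" if "smiles_std" in cols else "smiles_raw"
        else:
            raise ValueError(f"{path} must have columns id, smiles (and optional label)")
        n_skipped = 0
        for i, row in enumerate(reader):
            row = {k.lower(): (v or "") for k, v in row.items() if k}
            smi = row[smiles_col].strip() or row.get("smiles_raw", "").strip()
            if not smi or Chem.MolFromSmiles(smi) is None:
                n_skipped += 1
                log.warning("skipping unparsable CSV row %d: %s", i + 2, smi)
                continue
            label = row.get("label", "").strip().lower() or "unlabeled"
            if label not in LABELS:
                raise ValueError(f"unknown label {label!r} in row {i + 2} of {path}")
            yield MoleculeRecord(id=row["id"].strip() or f"mol{i + 1}",
                                 smiles_raw=smi, label=label,
                                 source=row.get("source", str(path)))
        if n_skipped:
            log.info("skipped %d unparsable entries in %s", n_skipped, path)


# ---------------------------------------------------------------------------
# standardization


def _neutralize_adjacent_charges(mol: Chem.Mol) -> Chem.Mol:
    """Convert adjacent (+,-) formal-charge pairs into an incremented bond order.

    Only applied where the resulting valences are chemically legal; an
    illegal candidate pair is left untouched with a warning.  Charges
    separated by more than one bond, and 1,2-zwitterions whose
    neutralization would exceed an atom's allowed valence (e.g. the
    nitro group), pass through unchanged.
    """
    order_up = {Chem.BondType.SINGLE: Chem.BondType.DOUBLE,
                Chem.BondType.DOUBLE: Chem.BondType.TRIPLE}
    rejected: set[tuple[int, int]] = set()
    for _ in range(mol.GetNumBonds() + 1):  # each pass fixes at most one pair
        changed = False
        for bond in mol.GetBonds():
            a, b = bond.GetBeginAtom(), bond.GetEndAtom()
            key = tuple(sorted((a.GetIdx(), b.GetIdx())))
            if key in rejected:
                continue
            neg, pos = sorted((a, b), key=lambda at: at.GetFormalCharge())
            if neg.GetFormalCharge() >= 0 or pos.GetFormalCharge() <= 0:
                continue
            if bond.GetBondType() not in order_up:
                continue
            trial = Chem.RWMol(mol)
            tb = trial.GetBondBetweenAtoms(a.GetIdx(), b.GetIdx())
            tb.SetBondType(order_up[bond.GetBondType()])
            ta = trial.GetAtomWithIdx(neg.GetIdx())
            tp = trial.GetAtomWithIdx(pos.GetIdx())
            ta.SetFormalCharge(ta.GetFormalCharge() + 1)
            tp.SetFormalCharge(tp.GetFormalCharge() - 1)
            try:
                out = trial.GetMol()
                Chem.SanitizeMol(out)
                # sanitization may re-normalize an illegal valence back to
                # the charge-separated form (e.g. nitro); that is a no-op
                if (out.GetAtomWithIdx(pos.GetIdx()).GetFormalCharge()
                        == pos.GetFormalCharge()):
                    raise ValueError("neutralization undone by sanitizer")
            except Exception:
                warnings.warn(
                    "adjacent charge pair could not be neutralized without an "
                    "illegal valence; molecule left unmodified at that site")
                rejected.add(key)
                continue
            mol = out
            changed = True
            break
        if not changed:
            break
    return mol


def _strip_to_main_fragment(mol: Chem.Mol) -> Chem.Mol | None:
    """Drop water fragments, then keep the largest organic fragment.

    Organic fragments (those containing carbon) win over inorganic
    counter-ions regardless of size; among candidates the one with the
    most heavy atoms is kept, ties broken by canonical SMILES for
    determinism.  Returns ``None`` when nothing is left.
    """
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    kept = []
    for f in frags:
        smi = Chem.MolToSmiles(f)
        if smi in _WATER_SMILES:
            continue
        kept.append(f)
    if not kept:
        return None
    organic = [f for f in kept
               if any(at.GetAtomicNum() == 6 for at in f.GetAtoms())]
    pool = organic or kept
    pool.sort(key=lambda f: (-f.GetNumHeavyAtoms(), Chem.MolToSmiles(f)))
    return pool[0]


def standardize(record: MoleculeRecord) -> MoleculeRecord:
    """Standardize one record and assign its InChIKey.

    Steps, in order: (1) drop water fragments and keep the largest
    organic fragment of what remains; (2) aromatize (aromaticity
    perception on sanitization); (3) neutralize adjacent opposite formal
    charges into a higher bond order where valence permits; (4) finalize
    hydrogen bookkeeping — explicit hydrogens are normalized into the
    canonical form's implicit-H counts so that equivalent inputs map to
    one canonical SMILES.

    Idempotent: standardizing an already-standardized record returns an
    equal record.

    Raises
    ------
    StandardizationError
        If the input does not parse or nothing remains after water
        removal (e.g. the input was water alone).
    """
    src = record.smiles_std if record.smiles_std is not None else record.smiles_raw
    mol = Chem.MolFromSmiles(src)
    if mol is None:
        raise StandardizationError(f"SMILES of record {record.id!r} does not parse: {src!r}")
    mol = _strip_to_main_fragment(mol)
    if mol is None or mol.GetNumAtoms() == 0:
        raise StandardizationError(f"record {record.id!r} is empty after standardization")
    Chem.SanitizeMol(mol)  # aromaticity perception
    mol = _neutralize_adjacent_charges(mol)
    mol = Chem.RemoveHs(Chem.AddHs(mol))  # normalize explicit-H bookkeeping
    smiles_std = Chem.MolToSmiles(mol)
    inchikey = Chem.MolToInchiKey(mol)
    if not inchikey:
        raise StandardizationError(f"InChIKey generation failed for {record.id!r}")
    return replace(record, smiles_std=smiles_std, inchikey=inchikey)


def standardize_all(records: Iterable[MoleculeRecord],
                    on_error: str = "skip") -> list[MoleculeRecord]:
    """Standardize a batch; ``on_error`` is ``"skip"`` (log) or ``"raise"``."""
    out = []
    for rec in records:
        try:
            out.append(standardize(rec))
        except StandardizationError:
            if on_error == "raise":
                raise
            log.warning("dropping record %s: standardization failed", rec.id)
    return out


def deduplicate(records: Sequence[MoleculeRecord]) -> tuple[list[MoleculeRecord], list[MoleculeRecord]]:
    """Remove duplicate structures by InChIKey.

    The first occurrence of each InChIKey is kept.  Structures that
    appear under *conflicting* taste labels are ambiguous training
    points: every record of such an InChIKey is removed and returned in
    the conflict list.

    Returns
    -------
    (kept, conflicts)
        ``kept`` preserves first-occurrence order and has pairwise
        distinct InChIKeys; ``conflicts`` holds all records of
        label-conflicting keys.
    """
    for rec in records:
        if rec.inchikey is None:
            raise ValueError(f"record {rec.id!r} has no InChIKey; standardize first")
    by_key: dict[str, list[MoleculeRecord]] = {}
    order: list[str] = []
    for rec in records:
        if rec.inchikey not in by_key:
            by_key[rec.inchikey] = []
            order.append(rec.inchikey)
        by_key[rec.inchikey].append(rec)
    kept, conflicts = [], []
    for key in order:
        group = by_key[key]
        labels = {r.label for r in group}
        if len(labels) > 1:
            conflicts.extend(group)
            log.warning("InChIKey %s has conflicting labels %s; removed", key, sorted(labels))
        else:
            kept.append(group[0])
    return kept, conflicts


def write_csv(records: Sequence[MoleculeRecord], path: str | Path) -> None:
    """Write a dataset CSV (id, smiles_raw, smiles_std, inchikey, label, source)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "smiles_raw", "smiles_std", "inchikey", "label", "source"])
        for r in records:
            writer.writerow([r.id, r.smiles_raw, r.smiles_std or "",
                             r.inchikey or "", r.label, r.source])


def read_dataset_csv(path: str | Path) -> list[MoleculeRecord]:
    """Read a CSV previously written by :func:`write_csv` (round-trip)."""
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(MoleculeRecord(
                id=row["id"], smiles_raw=row["smiles_raw"],
                smiles_std=row["smiles_std"] or None,
                inchikey=row["inchikey"] or None,
                label=row["label"], source=row.get("source", "")))
    return out
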