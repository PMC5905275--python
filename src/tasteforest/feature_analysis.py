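"""Class-conditional discrimination analysis of fingerprint features.

Which substructure features separate sweet from bitter compounds?  For
every fingerprint bit this module computes

- the *relative frequency* in each class — the fraction of that class's
  compounds with the bit set;
- the *Bayesian class probability* P(class | feature) — among all
  compounds carrying the bit, the fraction belonging to the class
  (undefined for bits no compound carries);
- an *active-for* assignment: a bit is active for a class when its
  frequency in that class exceeds the class's average relative
  frequency over all bits while staying below the other class's
  average (strict inequalities on both sides).

Top-k active features per class are ranked by own-class relative
frequency, and circular-fingerprint bits can be traced back to the
atom environments that set them, for chemical interpretation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .chem_io import MoleculeRecord
from .fingerprints import MORGAN_RADIUS, N_BITS


@dataclass(frozen=True)
class FeatureClassScore:
    """Per-bit class-conditional statistics.

    ``p_sweet_given_f``/``p_bitter_given_f`` are NaN for bits that occur
    in no compound (0/0 is left undefined, never coerced to 0); when
    defined they sum to 1.
    """

    bit: int
    freq_sweet: float
    freq_bitter: float
    p_sweet_given_f: float = math.nan
    p_bitter_given_f: float = math.nan
    active_for: str = "none"  # sweet | bitter | both | none


def _split_classes(matrix: np.ndarray, labels: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    if matrix.shape[0] != len(labels):
        raise ValueError("matrix rows and labels differ in length")
    sweet = matrix[labels == "sweet"]
    bitter = matrix[labels == "bitter"]
    if sweet.shape[0] == 0 or bitter.shape[0] == 0:
        raise ValueError("both classes must be present")
    return sweet, bitter


def relative_frequencies(matrix: np.ndarray,
                         labels: Sequence[str]) -> tuple[list[FeatureClassScore], dict[str, float]]:
    """Per-bit class relative frequencies and each class's average.

    Returns one score per matrix column plus the class means — the
    average relative frequency over all bits, which is the activity
    threshold used by :func:`active_features`.
    """
    sweet, bitter = _split_classes(matrix, labels)
    freq_s = sweet.mean(axis=0)
    freq_b = bitter.mean(axis=0)
    scores = [FeatureClassScore(bit=j, freq_sweet=float(freq_s[j]),
                                freq_bitter=float(freq_b[j]))
              for j in range(matrix.shape[1])]
    class_means = {"sweet": float(freq_s.mean()), "bitter": float(freq_b.mean())}
    return scores, class_means


def active_features(scores: Sequence[FeatureClassScore],
                    class_means: dict[str, float]) -> list[FeatureClassScore]:
    """Assign each bit's active class by the mean-threshold rule.

    Active for sweet iff freq_sweet > mean_sweet and
    freq_bitter < mean_bitter; symmetrically for bitter.  Strict
    inequalities: frequency exactly at a mean is inactive.  A bit
    meeting both class rules is marked ``both``; neither, ``none``.
    """
    if not {"sweet", "bitter"} <= class_means.keys():
        raise ValueError("class_means must provide 'sweet' and 'bitter'")
    ms, mb = class_means["sweet"], class_means["bitter"]
    out = []
    for s in scores:
        sweet_act = s.freq_sweet > ms and s.freq_bitter < mb
        bitter_act = s.freq_bitter > mb and s.freq_sweet < ms
        active = ("both" if sweet_act and bitter_act
                  else "sweet" if sweet_act
                  else "bitter" if bitter_act
                  else "none")
        out.append(replace(s, active_for=active))
    return out


def bayes_feature_scores(matrix: np.ndarray, labels: Sequence[str],
                         smoothing: float = 0.0) -> list[FeatureClassScore]:
    """Bayesian P(class | feature) per bit, with frequencies alongside.

    P(c | F) = (compounds of class c carrying F) / (all compounds
    carrying F); a pure ratio by default.  Optional additive
    ``smoothing`` (off by default) adds the pseudocount to each class's
    carrier count.  Bits carried by no compound get NaN probabilities.
    """
    sweet, bitter = _split_classes(matrix, labels)
    n_s_on = sweet.sum(axis=0).astype(float)
    n_b_on = bitter.sum(axis=0).astype(float)
    freq_s = n_s_on / sweet.shape[0]
    freq_b = n_b_on / bitter.shape[0]
    out = []
    for j in range(matrix.shape[1]):
        tot = n_s_on[j] + n_b_on[j]
        if tot == 0:
            p_s = p_b = math.nan
        else:
            denom = tot + 2 * smoothing
            p_s = (n_s_on[j] + smoothing) / denom
            p_b = (n_b_on[j] + smoothing) / denom
        out.append(FeatureClassScore(bit=j, freq_sweet=float(freq_s[j]),
                                     freq_bitter=float(freq_b[j]),
                                     p_sweet_given_f=float(p_s),
                                     p_bitter_given_f=float(p_b)))
    return out


def top_features(scores: Sequence[FeatureClassScore], cls: str,
                 k: int = 10) -> list[FeatureClassScore]:
    """Top-k bits active for a class, by own-class frequency descending.

    Ties break toward the lower bit index.  When fewer than k bits are
    active for the class, all of them are returned with a warning.
    """
    if cls not in ("sweet", "bitter"):
        raise ValueError("cls must be 'sweet' or 'bitter'")
    if k < 1:
        raise ValueError("k must be positive")
    active = [s for s in scores if s.active_for in (cls, "both")]
    key = (lambda s: (-s.freq_sweet, s.bit)) if cls == "sweet" else \
          (lambda s: (-s.freq_bitter, s.bit))
    active.sort(key=key)
    if k > len(active):
        warnings.warn(f"only {len(active)} bits active for {cls}; returning all")
        return active
    return active[:k]


def feature_dissimilarity(score_a: Sequence[float], score_b: Sequence[float]) -> float:
    """Dissimilarity of two features as 1 − Pearson correlation.

    Takes the two features' class-specific score vectors (any equal
    length ≥ 2); identical profiles give 0, exactly anti-proportional
    profiles give 2.  Zero-variance vectors have no defined
    correlation and raise.
    """
    a = np.asarray(score_a, dtype=float)
    b = np.asarray(score_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("score vectors must be 1-D, equal length >= 2")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("Pearson correlation undefined for zero-variance vector")
    r = float(np.corrcoef(a, b)[0, 1])
    return 1.0 - r


def bit_to_substructure(record: MoleculeRecord, bit: int,
                        kind: str = "morgan") -> list[dict]:
    """Trace a circular-fingerprint bit back to its atom environments.

    For every atom environment of the molecule that hashes (after
    folding) to the bit, returns the central atom index, radius, the
    environment rendered as a SMILES substructure string, and the atom
    indices it covers.

    Only circular kinds (``morgan``/``morgan_feat``) are invertible
    this way; the bit must be set in the record's fingerprint.
    """
    if kind not in ("morgan", "morgan_feat"):
        raise ValueError("substructure trace-back is defined for circular fingerprints only")
    if not record.is_standardized:
        raise ValueError("record must be standardized")
    mol = record.mol()
    if kind == "morgan":
        gen = rdFingerprintGenerator.GetMorganGenerator(
            radius=MORGAN_RADIUS, fpSize=N_BITS[kind])
    else:
        gen = rdFingerprintGenerator.GetMorganGenerator(
            radius=MORGAN_RADIUS, fpSize=N_BITS[kind],
            atomInvariantsGenerator=rdFingerprintGenerator.GetMorganFeatureAtomInvGen())
    ao = rdFingerprintGenerator.AdditionalOutput()
    ao.AllocateBitInfoMap()
    gen.GetFingerprint(mol, additionalOutput=ao)
    info = ao.GetBitInfoMap()
    if bit not in info:
        raise ValueError(f"bit {bit} is not set for record {record.id!r}")
    out = []
    for center, radius in info[bit]:
        if radius == 0:
            atoms = [center]
            sub = Chem.MolFragmentToSmiles(mol, atomsToUse=atoms)
        else:
            env = Chem.FindAtomEnvironmentOfRadiusN(mol, radius, center)
            atom_set = {center}
            for bidx in env:
                b = mol.GetBondWithIdx(bidx)
                atom_set.update((b.GetBeginAtomIdx(), b.GetEndAtomIdx()))
            atoms = sorted(atom_set)
            sub = Chem.MolFragmentToSmiles(mol, atomsToUse=atoms,
                                           bondsToUse=list(env))
        out.append({"center": int(center), "radius": int(radius),
                    "substructure": sub, "atoms": [int(a) for a in atoms]})
    return out


def feature_report_csv(scores: Sequence[FeatureClassScore], path) -> None:
    """Export the per-bit report as CSV (frequencies, probabilities, activity)."""
    import pandas as pd

    pd.DataFrame([{
        "bit": s.bit, "freq_sweet": s.freq_sweet, "freq_bitter": s.freq_bitter,
        "p_sweet_given_f": s.p_sweet_given_f,
        "p_bitter_given_f": s.p_bitter_given_f,
        "active_for": s.active_for,
    } for s in scores]).to_csv(path, index=False)
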