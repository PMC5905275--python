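"""Class-conditional feature statistics vs naive exhaustive oracles."""

import math

import numpy as np
import pytest

from tasteforest import (
    active_features,
    bayes_feature_scores,
    bit_to_substructure,
    compute_fingerprint,
    feature_dissimilarity,
    relative_frequencies,
    top_features,
)
from tasteforest.feature_analysis import FeatureClassScore


def _random_case(rng, n_rows=100, n_bits=64):
    matrix = (rng.random((n_rows, n_bits)) < rng.uniform(0.05, 0.4)).astype(np.uint8)
    labels = ["sweet", "bitter"] + [
        "sweet" if x else "bitter" for x in rng.integers(0, 2, n_rows - 2)]
    return matrix, labels


def _naive_frequencies(matrix, labels):
    """Double-loop oracle for per-bit class frequencies."""
    out = {}
    for cls in ("sweet", "bitter"):
        rows = [i for i, y in enumerate(labels) if y == cls]
        out[cls] = [sum(matrix[i][j] for i in rows) / len(rows)
                    for j in range(matrix.shape[1])]
    return out


def _naive_active(freqs, mean_s, mean_b):
    out = []
    for fs, fb in zip(freqs["sweet"], freqs["bitter"]):
        s = fs > mean_s and fb < mean_b
        b = fb > mean_b and fs < mean_s
        out.append("both" if s and b else "sweet" if s else "bitter" if b else "none")
    return out


class TestRelativeFrequencies:
    def test_pure_class_bit(self):
        matrix = np.array([[1], [1], [0], [0]], dtype=np.uint8)
        labels = ["sweet", "sweet", "bitter", "bitter"]
        scores, _ = relative_frequencies(matrix, labels)
        assert scores[0].freq_sweet == 1.0 and scores[0].freq_bitter == 0.0

    def test_absent_bit(self):
        matrix = np.zeros((4, 2), dtype=np.uint8)
        scores, means = relative_frequencies(matrix, ["sweet", "sweet", "bitter", "bitter"])
        assert scores[0].freq_sweet == scores[0].freq_bitter == 0.0
        assert means == {"sweet": 0.0, "bitter": 0.0}

    def test_fractional_count(self):
        matrix = np.array([[1], [1], [1], [0], [0]], dtype=np.uint8)
        labels = ["sweet"] * 4 + ["bitter"]
        scores, _ = relative_frequencies(matrix, labels)
        assert scores[0].freq_sweet == 0.75

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            relative_frequencies(np.ones((2, 2), dtype=np.uint8), ["sweet", "sweet"])


class TestOracleEquivalence:
    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(77)
        for _ in range(10):
            matrix, labels = _random_case(rng)
            scores, means = relative_frequencies(matrix, labels)
            naive = _naive_frequencies(matrix, labels)
            for j, s in enumerate(scores):
                assert s.freq_sweet == naive["sweet"][j]
                assert s.freq_bitter == naive["bitter"][j]
            assert means["sweet"] == pytest.approx(np.mean(naive["sweet"]))
            assigned = active_features(scores, means)
            expected = _naive_active(naive, means["sweet"], means["bitter"])
            assert [s.active_for for s in assigned] == expected

    def test_bayes_matches_counting_and_conserves(self):
        rng = np.random.default_rng(78)
        matrix, labels = _random_case(rng)
        scores = bayes_feature_scores(matrix, labels)
        for j, s in enumerate(scores):
            n_s = sum(matrix[i][j] for i, y in enumerate(labels) if y == "sweet")
            n_b = sum(matrix[i][j] for i, y in enumerate(labels) if y == "bitter")
            if n_s + n_b == 0:
                assert math.isnan(s.p_sweet_given_f)
                assert math.isnan(s.p_bitter_given_f)
            else:
                assert s.p_sweet_given_f == n_s / (n_s + n_b)
                assert s.p_sweet_given_f + s.p_bitter_given_f == pytest.approx(1.0)


class TestActiveRule:
    def test_rule_application(self):
        s = FeatureClassScore(bit=0, freq_sweet=0.6, freq_bitter=0.02)
        out = active_features([s], {"sweet": 0.1, "bitter": 0.1})
        assert out[0].active_for == "sweet"

    def test_boundary_equality_is_inactive(self):
        s = FeatureClassScore(bit=0, freq_sweet=0.1, freq_bitter=0.0)
        out = active_features([s], {"sweet": 0.1, "bitter": 0.1})
        assert out[0].active_for == "none"


class TestBayesExamples:
    def test_three_sweet_one_bitter(self):
        matrix = np.array([[1], [1], [1], [1], [0]], dtype=np.uint8)
        labels = ["sweet", "sweet", "sweet", "bitter", "bitter"]
        s = bayes_feature_scores(matrix, labels)[0]
        assert s.p_sweet_given_f == 0.75

    def test_bitter_only_bit(self):
        matrix = np.array([[0], [1]], dtype=np.uint8)
        s = bayes_feature_scores(matrix, ["sweet", "bitter"])[0]
        assert s.p_bitter_given_f == 1.0


class TestTopFeatures:
    def _scores(self):
        return active_features(
            [FeatureClassScore(bit=j, freq_sweet=f, freq_bitter=0.0)
             for j, f in enumerate([0.5, 0.7, 0.7, 0.3, 0.05])],
            {"sweet": 0.1, "bitter": 0.1})

    def test_sorted_with_tie_toward_lower_index(self):
        top = top_features(self._scores(), "sweet", 3)
        assert [s.bit for s in top] == [1, 2, 0]

    def test_k_exceeding_active_warns_and_returns_all(self):
        with pytest.warns(UserWarning, match="active"):
            top = top_features(self._scores(), "sweet", 10)
        assert [s.bit for s in top] == [1, 2, 0, 3]

    def test_frequencies_non_increasing(self):
        top = top_features(self._scores(), "sweet", 4)
        freqs = [s.freq_sweet for s in top]
        assert freqs == sorted(freqs, reverse=True)


class TestDissimilarity:
    def test_identical_vectors(self):
        assert feature_dissimilarity([1, 2, 3], [1, 2, 3]) == pytest.approx(0.0)

    def test_antiproportional_vectors(self):
        assert feature_dissimilarity([1, 2, 3], [3, 2, 1]) == pytest.approx(2.0)

    def test_hand_computed_pearson(self):
        # r((1,2,3),(1,2,4)) = 9/sqrt(84) = 0.981981...; 1 - r = 0.018019...
        assert feature_dissimilarity([1, 2, 3], [1, 2, 4]) == pytest.approx(
            1 - 9 / 84 ** 0.5, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            feature_dissimilarity([1, 1, 1], [1, 2, 3])


class TestBitToSubstructure:
    def test_radius_zero_is_single_atom(self, ethanol):
        fp = compute_fingerprint(ethanol, "morgan")
        envs = [e for b in fp.on_bits for e in bit_to_substructure(ethanol, b)]
        r0 = [e for e in envs if e["radius"] == 0]
        assert r0 and all(len(e["atoms"]) == 1 for e in r0)

    def test_off_bit_rejected(self, ethanol):
        fp = set(compute_fingerprint(ethanol, "morgan").on_bits)
        off = next(b for b in range(2048) if b not in fp)
        with pytest.raises(ValueError, match="not set"):
            bit_to_substructure(ethanol, off)

    def test_non_circular_kind_rejected(self, ethanol):
        with pytest.raises(ValueError, match="circular"):
            bit_to_substructure(ethanol, 0, kind="torsion")

    def test_environment_atoms_within_molecule(self, std_records):
        rec = std_records[2]  # saccharin
        fp = compute_fingerprint(rec, "morgan")
        n_atoms = rec.mol().GetNumAtoms()
        for b in list(fp.on_bits)[:10]:
            for env in bit_to_substructure(rec, b):
                assert all(0 <= a < n_atoms for a in env["atoms"])
                assert env["substructure"]


def test_frequency_sum_identity(small_labeled_set):
    """Sum of per-bit class frequencies = mean on-bit count per molecule."""
    from tasteforest import fingerprint_matrix
    matrix, _ = fingerprint_matrix(small_labeled_set, "morgan")
    labels = [r.label for r in small_labeled_set]
    scores, _ = relative_frequencies(matrix, labels)
    for cls, attr in (("sweet", "freq_sweet"), ("bitter", "freq_bitter")):
        rows = matrix[[i for i, y in enumerate(labels) if y == cls]]
        total = sum(getattr(s, attr) for s in scores)
        assert total == pytest.approx(rows.sum(axis=1).mean())
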