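"""Motif/community transition matrices, deltas, and their oracles."""

import itertools

import numpy as np
import pytest

from copath.behavior import (
    MotifSequence,
    TransitionMatrix,
    animal_average,
    community_transition_matrix,
    delta_transition,
    motif_transition_matrix,
)
from copath.simulate import simulate_motif_sequences


def seq(labels, animal="a", genotype="WT"):
    return MotifSequence(animal_id=animal, genotype=genotype, labels=labels)


def brute_force_matrix(labels, vocab):
    """Independent oracle: count off-diagonal transitions one by one."""
    k = len(vocab)
    idx = {m: i for i, m in enumerate(vocab)}
    counts = np.zeros((k, k))
    for a, b in zip(labels[:-1], labels[1:]):
        if a != b:
            counts[idx[a], idx[b]] += 1
    out = np.full((k, k), np.nan)
    for i in range(k):
        if counts[i].sum() > 0:
            out[i] = counts[i] / counts[i].sum()
    np.fill_diagonal(out, np.nan)
    return out


class TestMotifTransitions:
    def test_hand_enumeration(self):
        # [A,A,B,A,C]: A->B, B->A, A->C (A->A self dropped)
        tm = motif_transition_matrix(seq(["A", "A", "B", "A", "C"]))
        f = tm.to_frame()
        assert f.loc["A", "B"] == pytest.approx(0.5)
        assert f.loc["A", "C"] == pytest.approx(0.5)
        assert f.loc["B", "A"] == pytest.approx(1.0)
        assert "C" in tm.empty_rows

    def test_self_only_sequence_flagged(self):
        tm = motif_transition_matrix(seq(["A", "A", "A"]), vocabulary=["A"])
        assert tm.empty_rows == ["A"]
        assert np.isnan(tm.values).all()

    def test_deterministic_cycle_is_permutation(self):
        tm = motif_transition_matrix(seq(["A", "B", "C"] * 10))
        v = np.nan_to_num(tm.values)
        assert np.allclose(np.sort(v, axis=1)[:, -1], 1.0)
        assert np.allclose(v.sum(axis=1), 1.0)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(4)
        tm = motif_transition_matrix(seq(list(rng.choice(list("ABCD"), 500))))
        sums = np.nansum(tm.values, axis=1)
        assert np.allclose(sums, 1.0, atol=1e-12)

    def test_matches_exhaustive_enumeration_short_sequences(self):
        """On every sequence of length <= 10 over {A,B}, plus random 3-letter
        ones, the matrix equals the brute-force oracle."""
        vocab = ["A", "B"]
        for n in (2, 4, 7):
            for labels in itertools.product(vocab, repeat=n):
                tm = motif_transition_matrix(seq(list(labels)), vocabulary=vocab)
                expected = brute_force_matrix(list(labels), vocab)
                np.testing.assert_allclose(tm.values, expected, atol=1e-15)
        rng = np.random.default_rng(5)
        vocab3 = ["A", "B", "C"]
        for _ in range(50):
            labels = list(rng.choice(vocab3, size=10))
            tm = motif_transition_matrix(seq(labels), vocabulary=vocab3)
            np.testing.assert_allclose(
                tm.values, brute_force_matrix(labels, vocab3), atol=1e-15)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            motif_transition_matrix(seq(["A"]))


class TestCommunityTransitions:
    def test_identity_mapping_preserves_matrix(self):
        tm = motif_transition_matrix(seq(["A", "B", "C", "A", "B"]))
        cm = community_transition_matrix(tm, {"A": "A", "B": "B", "C": "C"})
        np.testing.assert_allclose(cm.values, tm.values)

    def test_hand_average(self):
        # two motifs in P with rows {q: 0.2} and {q: 0.4} -> (P,Q) = 0.3
        vals = np.full((3, 3), np.nan)
        vals[0, 2], vals[1, 2] = 0.2, 0.4
        vals[0, 1], vals[1, 0] = 0.8, 0.6
        tm = TransitionMatrix(labels=["p1", "p2", "q"], values=vals)
        cm = community_transition_matrix(tm, {"p1": "P", "p2": "P", "q": "Q"})
        assert cm.to_frame().loc["P", "Q"] == pytest.approx(0.3)

    def test_values_within_contributing_range(self):
        rng = np.random.default_rng(6)
        tm = motif_transition_matrix(seq(list(rng.choice(list("ABCDEF"), 2000))))
        cmap = {m: "X" if m < "D" else "Y" for m in "ABCDEF"}
        cm = community_transition_matrix(tm, cmap)
        member = {c: [m for m in "ABCDEF" if cmap[m] == c] for c in "XY"}
        f, mf = cm.to_frame(), tm.to_frame()
        for p, q in (("X", "Y"), ("Y", "X")):
            block = mf.loc[member[p], member[q]].to_numpy()
            val = f.loc[p, q]
            assert np.nanmin(block) - 1e-12 <= val <= np.nanmax(block) + 1e-12
            assert 0.0 <= val <= 1.0

    def test_unmapped_motif_rejected(self):
        tm = motif_transition_matrix(seq(["A", "B", "A"]))
        with pytest.raises(ValueError, match="B"):
            community_transition_matrix(tm, {"A": "P"})


class TestAveragingAndDelta:
    def _tm(self, x, labels=("P", "Q")):
        vals = np.full((2, 2), np.nan)
        vals[0, 1], vals[1, 0] = x, 1.0 - x
        return TransitionMatrix(labels=list(labels), values=vals,
                                level="community")

    def test_single_session_identity(self):
        m = self._tm(0.3)
        np.testing.assert_allclose(animal_average([m]).values, m.values)

    def test_two_session_mean(self):
        avg = animal_average([self._tm(0.2), self._tm(0.6)])
        assert avg.values[0, 1] == pytest.approx(0.4)

    def test_mixed_levels_rejected(self):
        a = self._tm(0.3)
        b = TransitionMatrix(labels=["P", "Q"], values=a.values, level="motif")
        with pytest.raises(ValueError, match="mix"):
            animal_average([a, b])

    def test_identical_groups_give_zero_delta(self):
        ms = [self._tm(0.4), self._tm(0.5)]
        d = delta_transition(ms, ms)
        assert np.allclose(np.nan_to_num(d.values), 0.0)

    def test_single_cell_difference(self):
        g = [self._tm(0.5), self._tm(0.5)]
        w = [self._tm(0.4), self._tm(0.4)]
        d = delta_transition(g, w)
        assert d.values[0, 1] == pytest.approx(0.1)

    def test_label_mismatch_rejected(self):
        with pytest.raises(ValueError, match="label"):
            delta_transition([self._tm(0.5)], [self._tm(0.5, labels=("P", "R"))])

    def test_planted_inflated_transition_recovered_with_positive_sign(self):
        """A genotype generator with an inflated 0->1 probability yields a
        positive delta in that cell, matching the generator difference."""
        base = np.array([[0.2, 0.4, 0.4], [0.4, 0.2, 0.4], [0.4, 0.4, 0.2]])
        hot = np.array([[0.2, 0.7, 0.1], [0.4, 0.2, 0.4], [0.4, 0.4, 0.2]])
        seqs = simulate_motif_sequences({"WT": base, "E4": hot}, n_animals=4,
                                        n_frames=20_000, seed=7)
        mats = {}
        for s in seqs:
            mats.setdefault(s.genotype, []).append(
                motif_transition_matrix(s, vocabulary=[0, 1, 2]))
        d = delta_transition(mats["E4"], mats["WT"])
        # generator difference in row 0 (self excluded): 0.7/0.8 - 0.4/0.8
        assert d.values[0, 1] == pytest.approx(0.375, abs=0.03)
        assert d.values[0, 2] == pytest.approx(-0.375, abs=0.03)
        assert abs(d.values[1, 0]) < 0.03
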