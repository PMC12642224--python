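"""Motif- and community-level transition matrices and genotype deltas.

Transitions between motifs are counted per session, self-transitions are
excluded at the count stage (remaining in the same motif is trivially the
most likely event), and rows are normalized over the remaining targets.
Motifs are then mapped to behavioral communities (walk/run, rear, groom,
...) and community-level probabilities are obtained by averaging over all
motif pairs belonging to each community transition. Genotype effects are
delta matrices: genotype group mean minus the WT group mean.

Degenerate rows (a motif that never transitions away) propagate as NaN,
never as zero probability mass, so they cannot bias group deltas.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sequences import MotifSequence


@dataclass
class TransitionMatrix:
    """Row-stochastic transition probabilities with the diagonal excluded.

    ``values[i, j]`` is P(next = j | current = i, next != i). The diagonal
    is NaN by construction; rows of states with no observed off-diagonal
    transition are entirely NaN and listed in ``empty_rows``.
    """

    labels: list
    values: np.ndarray = field(repr=False)
    level: str = "motif"  # "motif" or "community"
    empty_rows: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.labels)
        if self.values.shape != (k, k):
            raise ValueError("values must be square over labels")
        if self.level not in ("motif", "community"):
            raise ValueError("level must be 'motif' or 'community'")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass
class DeltaTransition:
    """Signed difference of group-mean transition matrices (genotype - WT)."""

    labels: list
    values: np.ndarray = field(repr=False)
    reference: str = "WT"
    level: str = "community"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def transition_counts(labels_seq, vocabulary: list) -> np.ndarray:
    """Raw counts of consecutive-frame transitions, self-transitions removed."""
    index = {m: i for i, m in enumerate(vocabulary)}
    seq = np.fromiter((index[m] for m in labels_seq), dtype=np.intp,
                      count=len(labels_seq))
    k = len(vocabulary)
    counts = np.zeros((k, k))
    src, dst = seq[:-1], seq[1:]
    keep = src != dst
    np.add.at(counts, (src[keep], dst[keep]), 1.0)
    return counts


def motif_transition_matrix(
    sequence: MotifSequence, vocabulary: list | None = None
) -> TransitionMatrix:
    """Row-normalized motif transition matrix for one session.

    Counting and normalization both exclude self-transitions, so each
    non-degenerate row sums to 1 over the off-diagonal targets.
    """
    if len(sequence) < 2:
        raise ValueError("need at least 2 frames")
    vocab = vocabulary if vocabulary is not None else sequence.vocabulary
    counts = transition_counts(sequence.labels, vocab)
    row_sums = counts.sum(axis=1)
    values = np.full_like(counts, np.nan)
    ok = row_sums > 0
    values[ok] = counts[ok] / row_sums[ok, None]
    np.fill_diagonal(values, np.nan)
    empty = [m for m, good in zip(vocab, ok) if not good]
    return TransitionMatrix(labels=list(vocab), values=values, level="motif",
                            empty_rows=empty)


def community_transition_matrix(
    motif_matrix: TransitionMatrix, community_map: dict
) -> TransitionMatrix:
    """Average motif-level transition values over community pairs.

    Entry (P, Q), P != Q, is the unweighted mean of the motif-level values
    over all pairs (i in P, j in Q, i != j); pairs with zero observed
    transitions contribute 0, whereas motifs with fully-missing rows are
    excluded from the average (NaN-aware mean). The community diagonal is
    excluded (NaN).
    """
    if motif_matrix.level != "motif":
        raise ValueError("expected a motif-level matrix")
    missing = [m for m in motif_matrix.labels if m not in community_map]
    if missing:
        raise ValueError(f"motifs without community mapping: {missing}")
    communities = sorted(set(community_map[m] for m in motif_matrix.labels))
    cidx = {c: i for i, c in enumerate(communities)}
    member = np.array([cidx[community_map[m]] for m in motif_matrix.labels])
    k = len(communities)
    values = np.full((k, k), np.nan)
    V = motif_matrix.values
    for p in range(k):
        rows = np.flatnonzero(member == p)
        for q in range(k):
            if p == q:
                continue
            cols = np.flatnonzero(member == q)
            block = V[np.ix_(rows, cols)]
            if np.isnan(block).all():
                continue
            values[p, q] = np.nanmean(block)
    empty = [communities[p] for p in range(k)
             if np.isnan(np.delete(values[p], p)).all()]
    return TransitionMatrix(labels=communities, values=values,
                            level="community", empty_rows=empty)


def _check_matching(matrices: list[TransitionMatrix]) -> None:
    if not matrices:
        raise ValueError("no matrices supplied")
    labels, level = matrices[0].labels, matrices[0].level
    for m in matrices[1:]:
        if m.labels != labels:
            raise ValueError("label sets differ between matrices")
        if m.level != level:
            raise ValueError("cannot mix motif- and community-level matrices")


def animal_average(session_matrices: list[TransitionMatrix]) -> TransitionMatrix:
    """Element-wise (NaN-aware) mean of one animal's session matrices."""
    _check_matching(session_matrices)
    stack = np.stack([m.values for m in session_matrices])
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(stack, axis=0)
    return TransitionMatrix(labels=session_matrices[0].labels, values=mean,
                            level=session_matrices[0].level)


def _group_mean(matrices: list[TransitionMatrix]) -> np.ndarray:
    stack = np.stack([m.values for m in matrices])
    with np.errstate(invalid="ignore"):
        return np.nanmean(stack, axis=0)


def delta_transition(
    genotype_matrices: list[TransitionMatrix],
    wt_matrices: list[TransitionMatrix],
    reference: str = "WT",
) -> DeltaTransition:
    """Group-mean transition difference (genotype - WT), element-wise.

    Positive entries mean the transition is more likely in the genotype
    group than in WT.
    """
    _check_matching(genotype_matrices + wt_matrices)
    delta = _group_mean(genotype_matrices) - _group_mean(wt_matrices)
    return DeltaTransition(labels=genotype_matrices[0].labels, values=delta,
                           reference=reference,
                           level=genotype_matrices[0].level)
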