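"""Genotype-structured Markov motif-sequence generator.

Each simulated animal emits a first-order Markov chain over a shared motif
vocabulary, with one transition matrix per genotype. The empirical
transition matrix of a simulated sequence converges to its generator, so
planted between-genotype differences give downstream delta-matrix and
permutation-test code a known ground truth.
"""

from __future__ import annotations

import numpy as np

from ..behavior.sequences import MotifSequence


def _validate_stochastic(T: np.ndarray, name: str) -> np.ndarray:
    T = np.asarray(T, dtype=float)
    if T.ndim != 2 or T.shape[0] != T.shape[1]:
        raise ValueError(f"transition matrix for {name!r} must be square")
    if (T < 0).any() or not np.allclose(T.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError(f"rows of the transition matrix for {name!r} must "
                         "be non-negative and sum to 1")
    return T


def simulate_motif_sequences(
    transition_matrices: dict[str, np.ndarray],
    usage_init: np.ndarray | None = None,
    n_animals: int = 5,
    n_frames: int = 10_000,
    seed: int | None = None,
    motif_labels: list | None = None,
    frame_rate: float = 30.0,
) -> list[MotifSequence]:
    """Simulate ``n_animals`` Markov motif sequences per genotype.

    Parameters
    ----------
    transition_matrices : dict
        genotype -> row-stochastic motif transition matrix (self-transitions
        allowed; they model dwell time).
    usage_init : array, optional
        Initial motif distribution (uniform by default).
    n_animals : int
        Animals per genotype.
    n_frames : int
        Frames per animal (>= 2).
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    mats = {g: _validate_stochastic(T, g) for g, T in transition_matrices.items()}
    sizes = {T.shape[0] for T in mats.values()}
    if len(sizes) != 1:
        raise ValueError("all genotypes must share one motif vocabulary")
    k = sizes.pop()
    labels = motif_labels if motif_labels is not None else list(range(k))
    if len(labels) != k:
        raise ValueError("motif_labels must match matrix size")
    if usage_init is None:
        usage_init = np.full(k, 1.0 / k)
    usage_init = np.asarray(usage_init, dtype=float)
    if usage_init.shape != (k,) or (usage_init < 0).any():
        raise ValueError("usage_init must be a distribution over motifs")
    usage_init = usage_init / usage_init.sum()

    rng = np.random.default_rng(seed)
    label_arr = np.asarray(labels, dtype=object)
    out: list[MotifSequence] = []
    for g in mats:  # insertion order keeps the draw sequence reproducible
        C = np.cumsum(mats[g], axis=1)
        states = np.empty((n_animals, n_frames), dtype=np.intp)
        cur = rng.choice(k, size=n_animals, p=usage_init)
        states[:, 0] = cur
        # vectorized over animals; each step inverts the row CDF of the chain
        for t in range(1, n_frames):
            u = rng.random(n_animals)
            cur = np.minimum((u[:, None] > C[cur]).sum(axis=1), k - 1)
            states[:, t] = cur
        for a in range(n_animals):
            out.append(
                MotifSequence(
                    animal_id=f"{g}_a{a + 1:02d}",
                    genotype=g,
                    labels=list(label_arr[states[a]]),
                    frame_rate=frame_rate,
                )
            )
    return out
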