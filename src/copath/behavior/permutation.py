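"""Animal-block permutation test for delta transition matrices.

The animal is the unit of replication: the null distribution of the
genotype-vs-WT delta is built by shuffling group labels across animals
(never across frames or sessions), preserving group sizes. Two-sided
per-cell p-values use add-one smoothing, p = (1 + #{|d_perm| >= |d_obs|})
/ (n_perm + 1), so the smallest attainable p is 1/(n_perm + 1) and the
test is exactly valid for any number of random permutations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np

from .transitions import DeltaTransition, TransitionMatrix, _check_matching


@dataclass
class PermutationResult:
    observed: DeltaTransition
    p_two_sided: np.ndarray = field(repr=False)
    n_perm: int = 0
    seed: int | None = None

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.p_two_sided, index=self.observed.labels,
                            columns=self.observed.labels)


def permutation_test(
    genotype_matrices: list[TransitionMatrix],
    wt_matrices: list[TransitionMatrix],
    n_perm: int = 10_000,
    seed: int | None = None,
) -> PermutationResult:
    """Animal-block permutation test on the genotype-vs-WT delta matrix.

    Cells where the observed delta is undefined (no animal contributed a
    value on one side) get NaN p-values.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    _check_matching(genotype_matrices + wt_matrices)
    n_g, n_w = len(genotype_matrices), len(wt_matrices)
    n = n_g + n_w
    if n < 3:
        raise ValueError("need at least 3 animals in total")
    if comb(n, n_g) < 2:
        raise ValueError("groups too small for any distinct permutation")

    labels = genotype_matrices[0].labels
    k = len(labels)
    stack = np.stack([m.values for m in genotype_matrices + wt_matrices])
    flat = stack.reshape(n, k * k)
    # NaN-aware group means via value/count sums so permutations vectorize
    vals = np.nan_to_num(flat, nan=0.0)
    cnts = (~np.isnan(flat)).astype(float)

    def group_delta(idx_g: np.ndarray, idx_w: np.ndarray) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            mg = vals[idx_g].sum(axis=-2) / cnts[idx_g].sum(axis=-2)
            mw = vals[idx_w].sum(axis=-2) / cnts[idx_w].sum(axis=-2)
        return mg - mw

    obs = group_delta(np.arange(n_g), np.arange(n_g, n))

    rng = np.random.default_rng(seed)
    # each row is a random assignment of the n animals; first n_g -> genotype
    perm = np.argsort(rng.random((n_perm, n)), axis=1)
    null = group_delta(perm[:, :n_g], perm[:, n_g:])

    with np.errstate(invalid="ignore"):
        exceed = (np.abs(null) >= np.abs(obs)[None, :]).sum(axis=0)
    p = (1.0 + exceed) / (n_perm + 1.0)
    p = np.where(np.isnan(obs), np.nan, p)

    observed = DeltaTransition(labels=labels, values=obs.reshape(k, k),
                               level=genotype_matrices[0].level)
    return PermutationResult(observed=observed,
                             p_two_sided=p.reshape(k, k),
                             n_perm=n_perm, seed=seed)
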