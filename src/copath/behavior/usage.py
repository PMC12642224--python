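"""Motif usage profiles, correlation dissimilarity, and usage clustering.

Usage is the fraction of frames each animal spends in each motif. Animals
(and motifs) are compared by 1 - Pearson correlation of their usage
profiles and grouped by hierarchical clustering of that dissimilarity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .sequences import MotifSequence


def motif_usage(
    sequences: list[MotifSequence], vocabulary: list | None = None
) -> pd.DataFrame:
    """Animals x motifs matrix of frame fractions; each row sums to 1.

    ``vocabulary`` fixes the motif column set (shared across animals); by
    default it is the union of motifs observed in the sequences.
    """
    if not sequences:
        raise ValueError("no sequences supplied")
    if vocabulary is None:
        vocabulary = sorted({m for s in sequences for m in s.labels})
    index = {m: j for j, m in enumerate(vocabulary)}
    rows = np.zeros((len(sequences), len(vocabulary)))
    for i, seq in enumerate(sequences):
        for m in seq.labels:
            try:
                rows[i, index[m]] += 1
            except KeyError:
                raise ValueError(
                    f"motif {m!r} of animal {seq.animal_id!r} not in vocabulary"
                ) from None
        rows[i] /= len(seq.labels)
    return pd.DataFrame(rows, index=[s.animal_id for s in sequences],
                        columns=vocabulary)


def delta_usage(usage: pd.DataFrame, genotypes: pd.Series,
                reference: str = "WT") -> pd.DataFrame:
    """Per-genotype delta index of motif usage: group mean minus reference mean.

    Interpretation note: computed as (genotype mean usage - WT mean usage)
    per motif; positive values mean the genotype over-uses the motif.
    """
    genotypes = genotypes.reindex(usage.index)
    if genotypes.isna().any():
        raise ValueError("every animal in the usage matrix needs a genotype")
    if reference not in set(genotypes):
        raise ValueError(f"reference group {reference!r} absent")
    ref_mean = usage.loc[genotypes == reference].mean(axis=0)
    out = {}
    for g in genotypes.unique():
        if g == reference:
            continue
        out[g] = usage.loc[genotypes == g].mean(axis=0) - ref_mean
    return pd.DataFrame(out).T


def usage_dissimilarity(
    usage: pd.DataFrame, wt_mean_profile: pd.Series | np.ndarray | None = None
) -> tuple[pd.DataFrame, pd.Series, list]:
    """Pairwise 1 - Pearson r between animal profiles, plus WT dissimilarity.

    Returns (pairwise dissimilarity matrix, per-animal dissimilarity to the
    WT group-mean profile, list of zero-variance animals flagged for
    exclusion from clustering). Dissimilarity is in [0, 2]: 0 for identical
    profiles, 2 for perfect anti-correlation.
    """
    X = usage.to_numpy(dtype=float)
    sd = X.std(axis=1)
    flagged = [a for a, s in zip(usage.index, sd) if s == 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X)
    diss = 1.0 - corr
    np.fill_diagonal(diss, 0.0)
    dmat = pd.DataFrame(diss, index=usage.index, columns=usage.index)

    wt_diss = pd.Series(np.nan, index=usage.index, name="wt_dissimilarity")
    if wt_mean_profile is not None:
        w = np.asarray(wt_mean_profile, dtype=float)
        if w.std() == 0:
            raise ValueError("WT mean profile has zero variance")
        for i, a in enumerate(usage.index):
            if sd[i] == 0:
                continue
            r = np.corrcoef(X[i], w)[0, 1]
            wt_diss[a] = 1.0 - r
    return dmat, wt_diss, flagged


def hierarchical_cluster(
    dissimilarity: pd.DataFrame, linkage_rule: str = "average"
) -> tuple[list, np.ndarray]:
    """Cluster a symmetric zero-diagonal dissimilarity matrix.

    Returns (leaf ordering as labels, scipy linkage matrix with n-1 merges).
    Default linkage is average (UPGMA); configurable.
    """
    D = dissimilarity.to_numpy(dtype=float)
    if np.isnan(D).any():
        raise ValueError("NaN entries in dissimilarity matrix")
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("dissimilarity matrix must be square and symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-12):
        raise ValueError("dissimilarity matrix must have a zero diagonal")
    # force exact symmetry before condensing (corrcoef rounding)
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    Z = hierarchy.linkage(squareform(D, checks=False), method=linkage_rule)
    order = hierarchy.leaves_list(Z)
    labels = [dissimilarity.index[i] for i in order]
    return labels, Z
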