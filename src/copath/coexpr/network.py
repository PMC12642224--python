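"""Co-expression network construction: soft threshold, adjacency, TOM,
and module detection.

The network is unsigned: adjacency a_ij = |cor(g_i, g_j)|^beta, with beta
chosen to approximate scale-free topology (smallest power on a candidate
grid whose scale-free fit R^2 reaches 0.8, else the grid maximum; per
cell-type overrides may be supplied). The topological overlap matrix

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)

combines direct adjacency with shared neighborhood. Modules come from
average-linkage clustering of 1 - TOM with a height-based cut, a minimum
module size, and merging of modules whose eigengenes are closer than the
merge cut height; leftovers go to "grey".
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

#: deepSplit granularity -> fraction of the tree height at which to cut;
#: larger deepSplit cuts lower and splits more finely. On TOM trees the
#: between-module merges sit near the root (dissimilarity ~0.95-1.0), so
#: even deepSplit 1 must cut below them.
DEEP_SPLIT_CUT_FRACTION = {0: 0.97, 1: 0.92, 2: 0.88, 3: 0.84, 4: 0.80}


def _correlation(m: pd.DataFrame) -> np.ndarray:
    X = m.to_numpy(dtype=float)
    sd = X.std(axis=1)
    if (sd == 0).any():
        bad = list(m.index[sd == 0][:5])
        raise ValueError(f"zero-variance genes present (should have been "
                         f"filtered): {bad}")
    return np.corrcoef(X)


def scale_free_fit(adjacency: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of the log-log linear fit of the connectivity distribution."""
    k = adjacency.sum(axis=1) - np.diag(adjacency)
    k = k[k > 0]
    if k.size < n_bins:
        return 0.0
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    which = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        sel = which == b
        if sel.sum() == 0:
            continue
        xs.append(np.log10(k[sel].mean()))
        ys.append(np.log10(sel.mean()))
    if len(xs) < 3:
        return 0.0
    xs, ys = np.array(xs), np.array(ys)
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r**2)


def pick_soft_threshold(
    m: pd.DataFrame,
    betas: tuple[int, ...] = tuple(range(1, 21)),
    target_r2: float = 0.8,
    override: int | None = None,
) -> tuple[int, pd.DataFrame]:
    """Choose the soft-thresholding power beta.

    Returns (beta, diagnostics table with fit R^2 and mean connectivity
    per candidate). ``override`` short-circuits the search — use it to
    reproduce published per-cell-type powers (24 pyramidal, 14 astrocyte,
    14 interneuron, 7 microglia).
    """
    if override is not None:
        return int(override), pd.DataFrame()
    if m.shape[1] < 8:
        raise ValueError("need >= 8 samples to estimate the soft threshold")
    abscor = np.abs(_correlation(m))
    rows = []
    chosen = None
    for b in betas:
        adj = abscor**b
        r2 = scale_free_fit(adj)
        rows.append((b, r2, float((adj.sum(axis=1) - 1).mean())))
        if chosen is None and r2 >= target_r2:
            chosen = b
    table = pd.DataFrame(rows, columns=["beta", "fit_r2", "mean_k"])
    return int(chosen if chosen is not None else betas[-1]), table


def build_network(m: pd.DataFrame, beta: int) -> tuple[np.ndarray, np.ndarray]:
    """Unsigned adjacency |cor|^beta and its topological overlap matrix."""
    adjacency = np.abs(_correlation(m)) ** beta
    np.fill_diagonal(adjacency, 1.0)
    A = adjacency.copy()
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=1)
    L = A @ A
    kmin = np.minimum.outer(k, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (L + A) / (kmin + 1.0 - A)
    np.fill_diagonal(tom, 1.0)
    return adjacency, tom


def _eigengene_matrix(m: pd.DataFrame, assignment: pd.Series) -> pd.DataFrame:
    """First-PC eigengene per module (helper used by module merging)."""
    from .eigengenes import module_eigengene

    return module_eigengene(m, assignment).me


def detect_modules(
    m: pd.DataFrame,
    tom: np.ndarray,
    merge_cut_height: float = 0.30,
    deep_split: int = 1,
    min_module_size: int = 30,
) -> pd.Series:
    """Detect modules from the TOM; unassigned genes go to "grey".

    Average-linkage clustering of 1 - TOM is cut at a height set by
    ``deep_split`` (a fraction of the tree height; larger deep_split cuts
    lower and splits more finely). Clusters below ``min_module_size``
    become grey. Modules whose eigengene dissimilarity (1 - cor) is below
    ``merge_cut_height`` are merged iteratively. Modules are labelled
    M1, M2, ... in decreasing size order.
    """
    if tom.shape[0] != tom.shape[1] or tom.shape[0] != len(m):
        raise ValueError("TOM must be square over the genes of m")
    if deep_split not in DEEP_SPLIT_CUT_FRACTION:
        raise ValueError(f"deep_split must be one of "
                         f"{sorted(DEEP_SPLIT_CUT_FRACTION)}")
    D = 1.0 - tom
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    np.maximum(D, 0.0, out=D)
    Z = hierarchy.linkage(squareform(D, checks=False), method="average")
    height = Z[:, 2].max()
    cut = DEEP_SPLIT_CUT_FRACTION[deep_split] * height
    flat = hierarchy.fcluster(Z, t=cut, criterion="distance")

    labels = pd.Series("grey", index=m.index, name="module", dtype=object)
    sizes = pd.Series(flat).value_counts()
    rank = 1
    for cid, size in sizes.items():
        if size < min_module_size:
            continue
        labels[flat == cid] = f"raw{rank}"
        rank += 1
    if (labels == "grey").all():
        warnings.warn("no module reached min_module_size; all genes grey")
        return labels

    # merge modules with similar eigengenes
    if merge_cut_height > 0:
        while True:
            mods = [x for x in labels.unique() if x != "grey"]
            if len(mods) < 2:
                break
            me = _eigengene_matrix(m, labels)
            cor = np.corrcoef(me.loc[mods].to_numpy())
            diss = 1.0 - cor  # signed: anti-correlated MEs stay separate
            np.fill_diagonal(diss, np.inf)
            i, j = np.unravel_index(np.argmin(diss), diss.shape)
            if diss[i, j] >= merge_cut_height:
                break
            labels[labels == mods[j]] = mods[i]

    # relabel in decreasing size order
    final = [x for x in labels.value_counts().index if x != "grey"]
    mapping = {old: f"M{i + 1}" for i, old in enumerate(final)}
    mapping["grey"] = "grey"
    return labels.map(mapping)
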