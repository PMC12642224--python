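"""Pseudobulk aggregation, log2CPM normalization, and gene filtering.

Single-cell counts are summed to per-sample pseudobulk profiles (the
biological sample is the replicate), normalized to log2 counts per
million, then filtered: housekeeping genes out (ribosomal, mitochondrial,
histone-related name patterns), genes below the 10th percentile of median
absolute deviation out, and finally the top 5,000 most variable genes
retained.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.stats import median_abs_deviation

#: default housekeeping name patterns: ribosomal (Rpl/Rps), mitochondrial
#: (mt-), histone-related (Hist) prefixes, mouse nomenclature
HOUSEKEEPING_PATTERNS = (r"^Rpl", r"^Rps", r"^mt-", r"^Hist")


def pseudobulk_aggregate(
    cell_counts, gene_names: list, cell_ids: list, cell_to_sample: dict
) -> pd.DataFrame:
    """Sum gene x cell counts into gene x sample pseudobulk counts.

    ``cell_counts`` may be dense or scipy-sparse (genes x cells). Column
    sums are conserved exactly: sum(pseudobulk) == sum(input).
    """
    unmapped = [c for c in cell_ids if c not in cell_to_sample]
    if unmapped:
        raise ValueError(f"cells without sample mapping: {unmapped[:5]}"
                         + ("..." if len(unmapped) > 5 else ""))
    samples = sorted(set(cell_to_sample[c] for c in cell_ids))
    sidx = {s: j for j, s in enumerate(samples)}
    cols = np.array([sidx[cell_to_sample[c]] for c in cell_ids])
    # indicator matrix (cells x samples) does the grouping as one product
    ind = sparse.csr_matrix(
        (np.ones(len(cell_ids)), (np.arange(len(cell_ids)), cols)),
        shape=(len(cell_ids), len(samples)),
    )
    if sparse.issparse(cell_counts):
        agg = np.asarray((cell_counts @ ind).todense())
    else:
        agg = np.asarray(cell_counts) @ ind.toarray()
    return pd.DataFrame(agg, index=gene_names, columns=samples)


def normalize_log2cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """log2(count / library size * 1e6 + 1) per sample (pseudocount 1)."""
    libsize = counts.sum(axis=0)
    zero = libsize[libsize <= 0]
    if len(zero):
        raise ValueError(f"zero library size for samples {list(zero.index)}")
    cpm = counts.div(libsize, axis=1) * 1e6
    return np.log2(cpm + 1.0)


@dataclass
class GeneFilterReport:
    n_input: int
    n_housekeeping_removed: int
    n_mad_removed: int
    n_variance_removed: int
    n_retained: int


def filter_genes(
    m: pd.DataFrame,
    housekeeping_patterns: tuple[str, ...] = HOUSEKEEPING_PATTERNS,
    mad_percentile: float = 10.0,
    top_n: int = 5000,
) -> tuple[pd.DataFrame, GeneFilterReport]:
    """Three sequential filters: housekeeping names, low MAD, top-N variance.

    Genes with zero MAD (constant across samples) are always removed at
    the MAD step — they carry no co-expression signal and break
    correlation-based steps downstream. If fewer than ``top_n`` genes
    survive the first two filters, all of them are kept with a warning.
    The variance used for the final ranking is the variance of log2CPM.
    """
    n_input = len(m)
    pattern = re.compile("|".join(housekeeping_patterns))
    keep = ~m.index.to_series().astype(str).str.contains(pattern)
    m1 = m.loc[keep]
    n_hk = n_input - len(m1)

    mad = pd.Series(
        median_abs_deviation(m1.to_numpy(dtype=float), axis=1), index=m1.index
    )
    cutoff = np.percentile(mad, mad_percentile)
    m2 = m1.loc[(mad >= cutoff) & (mad > 0)]
    n_mad = len(m1) - len(m2)

    if len(m2) <= top_n:
        if len(m2) < top_n:
            warnings.warn(
                f"only {len(m2)} genes survive upstream filters; keeping all"
            )
        m3 = m2
    else:
        var = m2.var(axis=1)
        top = var.sort_values(ascending=False, kind="mergesort").index[:top_n]
        m3 = m2.loc[m2.index.isin(set(top))]
    n_var = len(m2) - len(m3)

    report = GeneFilterReport(
        n_input=n_input,
        n_housekeeping_removed=n_hk,
        n_mad_removed=n_mad,
        n_variance_removed=n_var,
        n_retained=len(m3),
    )
    if m3.isna().any().any():
        m3 = m3.dropna()
    return m3, report
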