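"""Module eigengenes, module membership (kME), sign alignment, centering.

The module eigengene (ME) is the first principal component of the
gene-standardized module submatrix: one summary activity value per
sample, unit norm. kME is the Pearson correlation of each gene's profile
with an ME; the own-module |kME| ranks hub genes. ME polarity is
arbitrary, so signs are aligned to correlate positively with the mean
expression of the top 50 hub genes. For genotype comparisons MEs are
WT-centered (WT mean subtracted) and scaled by either the WT SD or the
SD pooled across genotypes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class Eigengenes:
    """Module x sample eigengene matrix plus bookkeeping flags."""

    me: pd.DataFrame  # modules x samples
    variance_explained: pd.Series
    sign_aligned: bool = False
    centering: str = "none"  # none | wt_sd | pooled_sd
    flagged_modules: list = field(default_factory=list)

    def copy(self) -> "Eigengenes":
        return Eigengenes(
            me=self.me.copy(),
            variance_explained=self.variance_explained.copy(),
            sign_aligned=self.sign_aligned,
            centering=self.centering,
            flagged_modules=list(self.flagged_modules),
        )


def module_eigengene(
    m: pd.DataFrame, assignment: pd.Series, exclude: tuple = ("grey",)
) -> Eigengenes:
    """First principal component of each module's expression submatrix.

    Genes are standardized across samples before the SVD; the ME is the
    leading right-singular vector (unit norm over samples). Rank-deficient
    submatrices fall back to the available rank with a warning.
    """
    assignment = assignment.reindex(m.index)
    mods = [x for x in assignment.dropna().unique() if x not in exclude]
    if not mods:
        raise ValueError("no modules to summarize")
    rows, var_expl, flagged = {}, {}, []
    for mod in mods:
        sub = m.loc[assignment == mod].to_numpy(dtype=float)
        if sub.shape[0] < 2:
            raise ValueError(f"module {mod!r} has fewer than 2 genes")
        mu = sub.mean(axis=1, keepdims=True)
        sd = sub.std(axis=1, keepdims=True)
        zero = (sd == 0).ravel()
        if zero.any():
            flagged.append(mod)
            sd = np.where(sd == 0, 1.0, sd)
        X = (sub - mu) / sd
        try:
            _, s, vt = np.linalg.svd(X, full_matrices=False)
        except np.linalg.LinAlgError:
            warnings.warn(f"SVD failed for module {mod!r}; using zeros")
            rows[mod] = np.zeros(sub.shape[1])
            var_expl[mod] = 0.0
            continue
        if s[0] == 0:
            warnings.warn(f"module {mod!r} is rank deficient; ME set to 0")
            flagged.append(mod)
            rows[mod] = np.zeros(sub.shape[1])
            var_expl[mod] = 0.0
            continue
        rows[mod] = vt[0]
        var_expl[mod] = float(s[0] ** 2 / (s**2).sum())
    me = pd.DataFrame(rows, index=m.columns).T
    return Eigengenes(me=me, variance_explained=pd.Series(var_expl),
                      flagged_modules=flagged)


def kme(m: pd.DataFrame, eigengenes: Eigengenes) -> pd.DataFrame:
    """Gene x module Pearson correlations between expression and MEs."""
    X = m.to_numpy(dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    xn = np.linalg.norm(Xc, axis=1)
    E = eigengenes.me.to_numpy(dtype=float)
    Ec = E - E.mean(axis=1, keepdims=True)
    en = np.linalg.norm(Ec, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (Xc @ Ec.T) / np.outer(xn, en)
    return pd.DataFrame(corr, index=m.index, columns=eigengenes.me.index)


def align_sign(
    eigengenes: Eigengenes,
    kme_table: pd.DataFrame,
    m: pd.DataFrame,
    assignment: pd.Series,
    n_hub: int = 50,
) -> tuple[Eigengenes, pd.DataFrame]:
    """Flip MEs so they correlate positively with their top hub genes.

    For each module, the mean expression of the top ``n_hub`` genes by
    own-module |kME| is computed; when its correlation with the ME is
    negative, both the ME and the module's kME column are inverted. An
    exactly-zero correlation leaves the sign unchanged with a warning.
    Applying the operation twice equals applying it once (involution on
    the aligned state).
    """
    assignment = assignment.reindex(m.index)
    out = eigengenes.copy()
    kme_out = kme_table.copy()
    for mod in out.me.index:
        members = assignment.index[assignment == mod]
        ranked = kme_table.loc[members, mod].abs().sort_values(
            ascending=False, kind="mergesort")
        hubs = ranked.index[: min(n_hub, len(ranked))]
        hub_mean = m.loc[hubs].mean(axis=0).to_numpy()
        me_vec = out.me.loc[mod].to_numpy()
        if hub_mean.std() == 0 or me_vec.std() == 0:
            warnings.warn(f"cannot orient module {mod!r}: constant profile")
            continue
        r = np.corrcoef(me_vec, hub_mean)[0, 1]
        if r == 0:
            warnings.warn(f"module {mod!r} orientation is exactly zero; "
                          "sign left unchanged")
            continue
        if r < 0:
            out.me.loc[mod] = -me_vec
            kme_out[mod] = -kme_out[mod]
    out.sign_aligned = True
    return out, kme_out


#: divisor floor for zero-variance guards (machine-safe epsilon)
_EPS = np.finfo(float).eps


def wt_center(
    eigengenes: Eigengenes, design: pd.DataFrame, mode: str = "wt_sd"
) -> Eigengenes:
    """WT-center MEs: subtract the WT group mean, divide by a group SD.

    mode "wt_sd" divides by the WT standard deviation (contribution
    analysis); mode "pooled_sd" divides by the SD pooled within genotypes
    (effect-size-scaled heatmaps). Zero-variance divisors are floored at
    machine epsilon and the module flagged.
    """
    if mode not in ("wt_sd", "pooled_sd"):
        raise ValueError("mode must be 'wt_sd' or 'pooled_sd'")
    design = design.loc[eigengenes.me.columns]
    wt_cols = design.index[design["genotype"] == "WT"]
    if len(wt_cols) < 2:
        raise ValueError("need >= 2 WT samples to center")
    out = eigengenes.copy()
    flagged = list(out.flagged_modules)
    for mod in out.me.index:
        vals = out.me.loc[mod]
        wt_mean = vals[wt_cols].mean()
        if mode == "wt_sd":
            sd = vals[wt_cols].std(ddof=1)
        else:
            groups = [vals[design.index[design["genotype"] == g]]
                      for g in design["genotype"].unique()]
            num = sum((len(g) - 1) * g.std(ddof=1) ** 2
                      for g in groups if len(g) > 1)
            den = sum(len(g) - 1 for g in groups if len(g) > 1)
            sd = np.sqrt(num / den) if den > 0 else 0.0
        if not np.isfinite(sd) or sd < _EPS:
            sd = _EPS
            if mod not in flagged:
                flagged.append(mod)
        out.me.loc[mod] = (vals - wt_mean) / sd
    out.centering = mode
    out.flagged_modules = flagged
    return out


def hub_genes(
    kme_table: pd.DataFrame, assignment: pd.Series, n: int = 25
) -> dict[str, pd.DataFrame]:
    """Top ``n`` genes per module ranked by own-module |kME|.

    Ties are broken lexicographically by gene id for reproducibility.
    Modules smaller than ``n`` return all their genes without padding.
    """
    out = {}
    for mod in kme_table.columns:
        members = assignment.index[assignment == mod]
        if len(members) == 0:
            continue
        tbl = pd.DataFrame({
            "kme": kme_table.loc[members, mod],
            "abs_kme": kme_table.loc[members, mod].abs(),
        })
        # stable sort on a lexicographically pre-sorted index breaks
        # |kME| ties by gene id, never randomly
        tbl = tbl.loc[sorted(members)].sort_values(
            "abs_kme", ascending=False, kind="mergesort")
        out[mod] = tbl.head(n)
    return out
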