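"""Gene-level two-way factorial ANOVA and module-level aggregation.

Every gene's log2CPM profile is fitted with y ~ E4 * NLF (main effects
plus interaction). Per-term p-values are aggregated within each module
(grey excluded) by Fisher's method, X^2 = -2 sum(ln p) on 2k degrees of
freedom, with Benjamini-Hochberg FDR control across modules per term.
Module eigengene contrasts (genotype vs WT) use ordinary linear-model
t-tests with BH correction across all module x contrast pairs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.multitest import multipletests

TERMS = ("E4", "NLF", "E4xNLF")
_TERM_KEYS = {"E4": "e4", "NLF": "nlf", "E4xNLF": "e4:nlf"}


def gene_two_way_anova(m: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Per-gene two-factor ANOVA with interaction.

    Returns a gene-indexed frame with p and eta-squared (SS_term /
    SS_total) per term. Genes with zero residual degrees of freedom are
    skipped (all-NaN row).
    """
    design = design.loc[m.columns]
    counts = design.groupby(["e4", "nlf"]).size()
    if len(counts) < 4 or (counts < 2).any():
        raise ValueError("need >= 2 samples in each of the four genotype cells")
    base = pd.DataFrame({
        "e4": design["e4"].to_numpy(dtype=float),
        "nlf": design["nlf"].to_numpy(dtype=float),
    })
    rows = {}
    for gene in m.index:
        data = base.assign(y=m.loc[gene].to_numpy(dtype=float))
        fit = smf.ols("y ~ e4 * nlf", data=data).fit()
        if fit.df_resid <= 0:
            rows[gene] = {f"p_{t}": np.nan for t in TERMS}
            continue
        tab = sm.stats.anova_lm(fit, typ=2)
        ss_total = tab["sum_sq"].sum()
        row = {}
        for term in TERMS:
            key = _TERM_KEYS[term]
            row[f"p_{term}"] = float(tab.loc[key, "PR(>F)"])
            row[f"eta2_{term}"] = (
                float(tab.loc[key, "sum_sq"] / ss_total) if ss_total > 0
                else np.nan
            )
        rows[gene] = row
    return pd.DataFrame(rows).T.reindex(m.index)


def fisher_combine(pvalues: np.ndarray) -> tuple[float, float]:
    """Fisher's method: X^2 = -2 sum(ln p) ~ chi2(2k) under the null."""
    p = np.clip(np.asarray(pvalues, dtype=float), 1e-300, 1.0)
    stat = -2.0 * np.log(p).sum()
    return float(stat), float(stats.chi2.sf(stat, df=2 * p.size))


def aggregate_fisher(
    per_gene: pd.DataFrame,
    assignment: pd.Series,
    exclude: tuple = ("grey",),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Aggregate gene-level ANOVA p-values to modules via Fisher's method.

    Output rows are module x term with the Fisher statistic (df = 2k),
    combined p, BH q across modules per term, genes tested and skipped,
    the fraction nominally significant (p < alpha), and the mean
    eta-squared.
    """
    assignment = assignment.reindex(per_gene.index)
    mods = [x for x in assignment.dropna().unique() if x not in exclude]
    if not mods:
        raise ValueError("no modules to aggregate")
    rows = []
    for mod in mods:
        genes = per_gene.loc[assignment == mod]
        for term in TERMS:
            p = genes[f"p_{term}"].dropna()
            skipped = len(genes) - len(p)
            if len(p) == 0:
                rows.append((mod, term, np.nan, 0, np.nan, 0, skipped,
                             np.nan, np.nan))
                continue
            stat, comb = fisher_combine(p.to_numpy())
            rows.append((
                mod, term, stat, 2 * len(p), comb, len(p), skipped,
                float((p < alpha).mean()),
                float(genes[f"eta2_{term}"].mean()),
            ))
    out = pd.DataFrame(rows, columns=[
        "module", "term", "fisher_stat", "df", "p_combined", "n_genes",
        "n_skipped", "frac_nominal_sig", "mean_eta2",
    ])
    out["q_fdr"] = np.nan
    for term in TERMS:
        sel = (out["term"] == term) & out["p_combined"].notna()
        if sel.any():
            out.loc[sel, "q_fdr"] = multipletests(
                out.loc[sel, "p_combined"], method="fdr_bh")[1]
    return out.set_index(["module", "term"])


def me_contrasts(
    eigengenes, design: pd.DataFrame, fdr_threshold: float = 0.05
) -> pd.DataFrame:
    """Per-module genotype-vs-WT contrasts on the ME matrix.

    Fits ME ~ C(genotype) with WT as the reference level and reports the
    three contrast t-tests per module, BH-adjusted across all module x
    contrast pairs. Uses ordinary (unmoderated) linear-model inference.
    """
    me = eigengenes.me if hasattr(eigengenes, "me") else eigengenes
    design = design.loc[me.columns]
    present = set(design["genotype"])
    if {"WT", "E4", "NLF", "E4NLF"} - present:
        raise ValueError("all four genotypes must be present")
    geno = pd.Categorical(design["genotype"],
                          categories=["WT", "E4", "NLF", "E4NLF"])
    rows = []
    for mod in me.index:
        y = me.loc[mod].to_numpy(dtype=float)
        if np.ptp(y) == 0:  # constant ME: no genotype effect, by definition
            for g in ("E4", "NLF", "E4NLF"):
                rows.append((mod, g, 0.0, 0.0, 1.0))
            continue
        data = pd.DataFrame({"me": y, "genotype": geno})
        fit = smf.ols("me ~ C(genotype)", data=data).fit()
        if np.linalg.matrix_rank(fit.model.exog) < fit.model.exog.shape[1]:
            raise ValueError("singular design in ME contrasts")
        for g in ("E4", "NLF", "E4NLF"):
            name = f"C(genotype)[T.{g}]"
            rows.append((mod, g, fit.params[name], fit.tvalues[name],
                         fit.pvalues[name]))
    out = pd.DataFrame(rows, columns=["module", "contrast", "estimate", "t",
                                      "p"])
    out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    out["significant"] = out["p_adj"] < fdr_threshold
    return out.set_index(["module", "contrast"])
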