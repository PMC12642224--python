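"""Genotype contribution decomposition of module-eigengene change.

For every module the magnitude of activity change in each mutant
genotype group is the absolute deviation of its mean (WT-centered) ME
from the WT mean:

    d_g(module) = | mean_g(ME) - mean_WT(ME) |,  g in {E4, NLF, E4NLF}

Per module, the three shifts are normalized to shares summing to 1; per
cell type they are summed across modules into totals T_g and proportions
c_g = T_g / sum_g T_g, which apportion the overall co-expression
dysregulation among APOE4 alone, amyloid alone, and their combination.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .eigengenes import Eigengenes

MUTANTS = ("E4", "NLF", "E4NLF")


@dataclass
class ContributionResult:
    """Per-module absolute ME shifts, shares, and cell-type proportions."""

    shifts: pd.DataFrame  # modules x (E4, NLF, E4NLF), WT-SD units
    shares: pd.DataFrame  # rows sum to 1; all-zero-shift modules excluded
    totals: pd.Series  # T_g, summed across modules
    proportions: pd.Series  # c_g, sums to 1
    excluded_modules: list = field(default_factory=list)
    cell_type: str | None = None


def contribution(
    centered: Eigengenes, design: pd.DataFrame,
    exclude: tuple = ("grey",), cell_type: str | None = None,
) -> ContributionResult:
    """Decompose total ME change into E4 / NLF / E4xNLF contributions.

    Expects WT-centered eigengenes (the WT group mean of each row is 0 by
    construction, so d_g is simply |mean_g|). Modules whose three shifts
    are all zero have undefined shares and are excluded from the share
    table but not from the totals (they add nothing there).
    """
    me = centered.me.drop(index=[x for x in exclude if x in centered.me.index])
    if me.empty:
        raise ValueError("no modules left after exclusion")
    design = design.loc[me.columns]
    present = set(design["genotype"])
    missing = {"WT", *MUTANTS} - present
    if missing:
        raise ValueError(f"genotypes missing from the design: {sorted(missing)}")

    group_means = {
        g: me[design.index[design["genotype"] == g]].mean(axis=1)
        for g in ("WT",) + MUTANTS
    }
    shifts = pd.DataFrame(
        {g: (group_means[g] - group_means["WT"]).abs() for g in MUTANTS}
    )
    row_sum = shifts.sum(axis=1)
    excluded = list(shifts.index[row_sum == 0])
    shares = shifts.loc[row_sum > 0].div(row_sum[row_sum > 0], axis=0)
    totals = shifts.sum(axis=0)
    grand = totals.sum()
    if grand == 0:
        raise ValueError("all module shifts are zero; proportions undefined")
    proportions = totals / grand
    return ContributionResult(
        shifts=shifts, shares=shares, totals=totals,
        proportions=proportions, excluded_modules=excluded,
        cell_type=cell_type,
    )


def compare_contributions(
    neuronal: list[ContributionResult] | pd.DataFrame,
    glial: list[ContributionResult] | pd.DataFrame,
) -> pd.DataFrame:
    """Neuronal-vs-glial comparison of per-module contribution shares.

    Two-sided Mann-Whitney U per component (E4, NLF, E4NLF) on the
    module-level shares, Bonferroni-corrected over the three components.
    Accepts ContributionResult lists (shares are pooled across cell
    types) or ready-made share DataFrames.
    """

    def pool(x) -> pd.DataFrame:
        if isinstance(x, pd.DataFrame):
            return x
        return pd.concat([r.shares for r in x], axis=0)

    n_shares, g_shares = pool(neuronal), pool(glial)
    if len(n_shares) < 3 or len(g_shares) < 3:
        raise ValueError("need >= 3 modules per class")
    rows = []
    for comp in MUTANTS:
        a = n_shares[comp].to_numpy()
        b = g_shares[comp].to_numpy()
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            u, p = np.nan, 1.0  # ties-only degenerate input
        else:
            u, p = mannwhitneyu(a, b, alternative="two-sided")
        rows.append((comp, u, p, min(1.0, 3.0 * p)))
    return pd.DataFrame(
        rows, columns=["component", "U", "p", "p_bonferroni"]
    ).set_index("component")
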