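"""Network export for interactive viewers and heatmap value tables.

Edges are within-module gene pairs with |Pearson r| >= 0.3 (inclusive),
written in the two-file edge/node tabular convention (Cytoscape-style).
Node attributes carry the signed kME (color) and |kME| (size/hubness).
Heatmap tables rank module genes by |kME| (variance fallback), keep up
to the top 100, and report WT-centered genotype means.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def export_edges(
    m: pd.DataFrame,
    assignment: pd.Series,
    kme_table: pd.DataFrame,
    threshold: float = 0.3,
    n_hub: int = 25,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Within-module correlation edges and a node attribute table.

    Returns (edge table with canonical gene_a < gene_b ordering, node
    table with kME, |kME| and a hub flag for the top ``n_hub`` genes of
    each module by |kME|).
    """
    assignment = assignment.reindex(m.index)
    edges = []
    nodes = []
    for mod in [x for x in assignment.dropna().unique() if x != "grey"]:
        genes = sorted(assignment.index[assignment == mod])
        if not genes:
            continue
        sub = m.loc[genes].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(sub)
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                r = corr[i, j]
                if np.isfinite(r) and abs(r) >= threshold:
                    edges.append((genes[i], genes[j], float(r), mod))
        km = kme_table.loc[genes, mod]
        ranked = km.abs().sort_values(ascending=False, kind="mergesort")
        hubs = set(ranked.index[:n_hub])
        for g in genes:
            nodes.append((g, mod, float(km[g]), float(abs(km[g])), g in hubs))
    edge_table = pd.DataFrame(
        edges, columns=["gene_a", "gene_b", "r", "module"])
    node_table = pd.DataFrame(
        nodes, columns=["gene", "module", "kme", "abs_kme", "hub"])
    return edge_table, node_table


def module_gene_heatmap_values(
    m: pd.DataFrame,
    assignment: pd.Series,
    kme_table: pd.DataFrame | None,
    design: pd.DataFrame,
    module: str,
    top_n: int = 100,
) -> dict[str, pd.DataFrame]:
    """Gene x genotype mean tables for one module's heatmap.

    Genes are ranked by |kME| when available, by variance otherwise, and
    capped at ``top_n``. WT-centering is gene-wise: subtract the WT mean
    and divide by the gene's SD across all samples, with zero variance
    guarded to one. Returns raw genotype means, centered genotype means,
    and a row-scaled view (each row divided by its max |value|).
    """
    assignment = assignment.reindex(m.index)
    genes = list(assignment.index[assignment == module])
    if not genes:
        raise ValueError(f"module {module!r} has no genes in the matrix")
    if kme_table is not None and module in kme_table.columns:
        ranked = kme_table.loc[genes, module].abs().sort_values(
            ascending=False, kind="mergesort")
        genes = list(ranked.index[:top_n])
    else:
        var = m.loc[genes].var(axis=1).sort_values(
            ascending=False, kind="mergesort")
        genes = list(var.index[:top_n])

    sub = m.loc[genes]
    design = design.loc[sub.columns]
    wt_cols = design.index[design["genotype"] == "WT"]
    wt_mean = sub[wt_cols].mean(axis=1)
    sd = sub.std(axis=1, ddof=1)
    sd = sd.where(sd > 0, 1.0)  # zero variance guarded to one
    centered = sub.sub(wt_mean, axis=0).div(sd, axis=0)

    genotypes = ["WT", "E4", "NLF", "E4NLF"]

    def genotype_means(frame: pd.DataFrame) -> pd.DataFrame:
        return pd.DataFrame({
            g: frame[design.index[design["genotype"] == g]].mean(axis=1)
            for g in genotypes if (design["genotype"] == g).any()
        })

    raw_means = genotype_means(sub)
    centered_means = genotype_means(centered)
    peak = centered_means.abs().max(axis=1)
    row_scaled = centered_means.div(peak.where(peak > 0, 1.0), axis=0)
    return {"raw": raw_means, "centered": centered_means,
            "row_scaled": row_scaled}
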