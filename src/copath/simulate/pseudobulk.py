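"""Pseudobulk expression generator with planted co-expression modules.

Samples follow the 2x2 genotype design (E4, NLF factors). Each planted
module has a per-sample latent activity whose mean is

    effect_e4 * e4 + effect_nlf * nlf + effect_interaction * e4 * nlf

(in latent-SD units), plus Gaussian sample noise. Module genes load on
the latent with gene-specific loadings plus independent Gaussian noise;
background genes are pure noise. Everything is on the log2CPM-like scale
the co-expression stage consumes, so with noise_sd = 0 the planted
genotype means are recovered exactly by the downstream contribution
decomposition (closed form).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..design import validate_design


@dataclass
class PlantedModuleSpec:
    """Ground-truth description of one planted co-expression module."""

    module_id: str
    n_genes: int
    effect_e4: float = 0.0  # latent-mean shift in SD units
    effect_nlf: float = 0.0
    effect_interaction: float = 0.0
    noise_sd: float = 0.3
    loading_range: tuple[float, float] = (0.8, 1.0)

    def __post_init__(self) -> None:
        if self.n_genes < 3:
            raise ValueError("n_genes must be >= 3")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        lo, hi = self.loading_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("loading_range must be an interval within [0, 1]")


def simulate_pseudobulk(
    design: pd.DataFrame,
    modules: list[PlantedModuleSpec],
    n_background_genes: int = 200,
    seed: int | None = None,
    *,
    background_noise_sd: float = 1.0,
    baseline_range: tuple[float, float] = (2.0, 8.0),
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Simulate a gene x sample expression matrix with planted modules.

    Returns (expression DataFrame, gene -> module Series with background
    genes mapped to "background", ground-truth effect table with the
    planted per-genotype latent means).
    """
    validate_design(design, min_per_genotype=2)
    if not modules:
        raise ValueError("module list must not be empty")
    ids = [m.module_id for m in modules]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate module_id")

    rng = np.random.default_rng(seed)
    e4 = design["e4"].to_numpy(dtype=float)
    nlf = design["nlf"].to_numpy(dtype=float)
    n_samples = len(design)

    blocks, gene_names, gene_module = [], [], []
    truth_rows = []
    for m in modules:
        latent_mean = (m.effect_e4 * e4 + m.effect_nlf * nlf
                       + m.effect_interaction * e4 * nlf)
        latent = latent_mean + (
            rng.normal(0.0, m.noise_sd, n_samples) if m.noise_sd > 0 else 0.0
        )
        loadings = rng.uniform(*m.loading_range, m.n_genes)
        baseline = rng.uniform(*baseline_range, m.n_genes)
        noise = (rng.normal(0.0, m.noise_sd, (m.n_genes, n_samples))
                 if m.noise_sd > 0 else 0.0)
        blocks.append(baseline[:, None] + loadings[:, None] * latent[None, :]
                      + noise)
        gene_names.extend(f"{m.module_id}_g{i + 1:03d}" for i in range(m.n_genes))
        gene_module.extend([m.module_id] * m.n_genes)
        truth_rows.append(
            {
                "module_id": m.module_id,
                "n_genes": m.n_genes,
                "effect_e4": m.effect_e4,
                "effect_nlf": m.effect_nlf,
                "effect_interaction": m.effect_interaction,
                "noise_sd": m.noise_sd,
                "mean_WT": 0.0,
                "mean_E4": m.effect_e4,
                "mean_NLF": m.effect_nlf,
                "mean_E4NLF": m.effect_e4 + m.effect_nlf + m.effect_interaction,
            }
        )

    if n_background_genes > 0:
        baseline = rng.uniform(*baseline_range, n_background_genes)
        blocks.append(baseline[:, None]
                      + rng.normal(0.0, background_noise_sd,
                                   (n_background_genes, n_samples)))
        gene_names.extend(f"bg_g{i + 1:04d}" for i in range(n_background_genes))
        gene_module.extend(["background"] * n_background_genes)

    expr = pd.DataFrame(np.vstack(blocks), index=gene_names,
                        columns=design.index)
    truth_modules = pd.Series(gene_module, index=gene_names, name="module")
    truth_effects = pd.DataFrame(truth_rows).set_index("module_id")
    return expr, truth_modules, truth_effects
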