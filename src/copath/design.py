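"""Two-factor genotype design for the APOE4 (E4) x humanized-amyloid (NLF) cross.

Every analysis in this package that compares genotypes works on a 2x2
factorial design: the E4 factor is present in the E4 and E4NLF groups, the
NLF factor in the NLF and E4NLF groups, and wild type (WT) carries neither.
"""

from __future__ import annotations

import pandas as pd

#: Canonical genotype labels keyed by the (e4, nlf) factor pair.
GENOTYPE_BY_FACTORS = {(0, 0): "WT", (1, 0): "E4", (0, 1): "NLF", (1, 1): "E4NLF"}
FACTORS_BY_GENOTYPE = {v: k for k, v in GENOTYPE_BY_FACTORS.items()}
GENOTYPES = ("WT", "E4", "NLF", "E4NLF")


def genotype_label(e4: int, nlf: int) -> str:
    """Genotype label uniquely determined by the two binary factors."""
    try:
        return GENOTYPE_BY_FACTORS[(int(e4), int(nlf))]
    except KeyError:
        raise ValueError(f"factors must be binary, got e4={e4!r}, nlf={nlf!r}") from None


def make_design(genotypes: dict[str, str] | pd.Series) -> pd.DataFrame:
    """Build a sample design table from a sample_id -> genotype mapping.

    Returns a DataFrame indexed by sample_id with columns ``e4``, ``nlf``
    (0/1 integers) and ``genotype`` (one of WT/E4/NLF/E4NLF).
    """
    if isinstance(genotypes, pd.Series):
        genotypes = genotypes.to_dict()
    ids = list(genotypes)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_id in design")
    rows = []
    for sid, label in genotypes.items():
        if label not in FACTORS_BY_GENOTYPE:
            raise ValueError(f"unknown genotype label {label!r} for sample {sid!r}")
        e4, nlf = FACTORS_BY_GENOTYPE[label]
        rows.append((sid, e4, nlf, label))
    frame = pd.DataFrame(rows, columns=["sample_id", "e4", "nlf", "genotype"])
    return frame.set_index("sample_id")


def balanced_design(n_per_genotype: int, prefix: str = "S") -> pd.DataFrame:
    """Design with ``n_per_genotype`` samples in each of the four genotypes."""
    mapping = {}
    i = 1
    for g in GENOTYPES:
        for _ in range(n_per_genotype):
            mapping[f"{prefix}{i:03d}_{g}"] = g
            i += 1
    return make_design(mapping)


def validate_design(design: pd.DataFrame, min_per_genotype: int = 1) -> None:
    """Check factor/label consistency and group sizes; raise ValueError if bad."""
    required = {"e4", "nlf", "genotype"}
    if not required.issubset(design.columns):
        raise ValueError(f"design must have columns {sorted(required)}")
    if design.index.has_duplicates:
        raise ValueError("duplicate sample_id in design")
    for sid, row in design.iterrows():
        if genotype_label(row["e4"], row["nlf"]) != row["genotype"]:
            raise ValueError(f"genotype label inconsistent with factors for {sid!r}")
    counts = design["genotype"].value_counts()
    for g in GENOTYPES:
        if counts.get(g, 0) < min_per_genotype:
            raise ValueError(
                f"genotype {g} has {counts.get(g, 0)} samples, "
                f"need >= {min_per_genotype}"
            )
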