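"""Male/female phenotype expression-ratio matrix (heatmap backbone).

For each sex-related factor the "male" phenotype mean (XY-, testes, or
testosterone) is divided by the "female" phenotype mean (XX, ovaries,
blank), giving a genes x 3 matrix whose log2 is antisymmetric under
swapping the phenotype labels.  Means are *marginal*: the unweighted
average of the four design-cell means on each side, which equals the
pooled sample mean for balanced designs and is robust to group-size
imbalance otherwise.

Cells are annotated from the factorial ANOVA: ``*`` for a significant
main effect of the factor, ``+`` for a significant interaction involving
it (raw p < alpha, matching figure-style annotation).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .simulate import FACTORS, MALE_LEVEL

__all__ = ["ratio_matrix", "write_ratio_matrix"]

log = logging.getLogger(__name__)

_SHORT = {"sex_chromosome": "chr", "gonadal_sex": "gon", "hormone": "act"}


def ratio_matrix(
    expression: pd.DataFrame,
    design: pd.DataFrame,
    anova: pd.DataFrame | None = None,
    alpha: float = 0.05,
    gene_order: list[str] | None = None,
) -> pd.DataFrame:
    """Genes x factors ratio matrix with significance flags.

    Parameters
    ----------
    expression
        Samples x genes relative expression (positive values).
    design
        Design table; samples absent from the expression matrix are
        ignored.
    anova
        Optional tidy table from :func:`fcgnet.factorial.anova_all_genes`
        supplying the flag columns; without it flags are left False.
    gene_order
        Optional explicit row order (e.g. a figure's layout).

    Returns
    -------
    DataFrame indexed by gene with columns ``chr_ratio``, ``gon_ratio``,
    ``act_ratio`` and matching ``*_main`` / ``*_interaction`` boolean
    flags.  A non-positive female-phenotype mean leaves the cell NaN.
    """
    d = design.set_index("sample_id").loc[expression.index]
    cells = expression.groupby(
        [d["sex_chromosome"], d["gonadal_sex"], d["hormone"]]
    ).mean()

    out = pd.DataFrame(index=expression.columns)
    out.index.name = "gene"
    for factor in FACTORS:
        short = _SHORT[factor]
        level_idx = cells.index.get_level_values(factor)
        male = cells[level_idx == MALE_LEVEL[factor]].mean(axis=0)
        female = cells[level_idx != MALE_LEVEL[factor]].mean(axis=0)
        ratio = male / female
        bad = female <= 0
        if bad.any():
            log.warning(
                "factor %s: %d gene(s) with non-positive female-phenotype mean",
                factor, int(bad.sum()),
            )
            ratio[bad] = np.nan
        out[f"{short}_ratio"] = ratio

    for factor in FACTORS:
        short = _SHORT[factor]
        out[f"{short}_main"] = False
        out[f"{short}_interaction"] = False
    if anova is not None:
        sig = anova[anova["p"] < alpha]
        for factor in FACTORS:
            short = _SHORT[factor]
            main = set(sig.loc[sig["term"] == short, "gene"])
            inter_terms = [
                t for t in anova["term"].unique()
                if ":" in t and short in t.split(":")
            ]
            inter = set(sig.loc[sig["term"].isin(inter_terms), "gene"])
            out[f"{short}_main"] = out.index.isin(main)
            out[f"{short}_interaction"] = out.index.isin(inter)

    if gene_order is not None:
        missing = [g for g in gene_order if g not in out.index]
        if missing:
            raise ValueError(f"gene_order contains unknown genes: {missing}")
        out = out.loc[gene_order]
    return out


def write_ratio_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t")
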