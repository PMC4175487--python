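"""Gene-by-gene correlation with the emotionality composite.

Each gene's expression is compared with the overall anxiety-like
emotionality Z-score by Pearson correlation, both across all animals and
after splitting by each single sex-related factor (XX vs XY-, gonadal
females vs males, blank- vs testosterone-treated) — seven strata in all.
Two-sided p-values use the t transform with n-2 df; BH-FDR control is
applied separately per gene category within each stratum, and a sign
class (+/-/ns) is assigned only to BH-significant correlations.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError
from .factorial import bh_adjust

__all__ = ["pearson", "stratified_correlations", "sign_summary", "STRATA"]

log = logging.getLogger(__name__)

#: stratum name -> (factor column, level); None selects all samples
STRATA: dict[str, tuple[str, str] | None] = {
    "all": None,
    "XX": ("sex_chromosome", "XX"),
    "XY-": ("sex_chromosome", "XY-"),
    "gonadal_female": ("gonadal_sex", "ovaries"),
    "gonadal_male": ("gonadal_sex", "testes"),
    "blank": ("hormone", "blank"),
    "testosterone": ("hormone", "testosterone"),
}


def pearson(x, y, name: str = "") -> tuple[float, float]:
    """Product-moment correlation with two-sided p (t transform, n-2 df)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError(f"{name or 'correlation'}: need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError(
            f"{name or 'correlation'}: zero variance, correlation undefined"
        )
    res = stats.pearsonr(x, y)
    # perfect fits yield p = 0; clamp into (0, 1] for the BH step-up
    p = max(float(res.pvalue), float(np.finfo(float).tiny))
    return float(res.statistic), p


def stratified_correlations(
    expression: pd.DataFrame,
    emotionality: pd.Series,
    design: pd.DataFrame,
    categories: Mapping[str, str],
    fdr: float = 0.05,
    declared_m: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Gene x stratum correlation table with per-category BH control.

    Parameters
    ----------
    expression
        Samples x genes relative-expression matrix.
    emotionality
        Overall emotionality z per sample (``z_overall``).
    design
        Design table mapping samples to factor levels.
    categories
        Gene -> category label; BH families are (stratum, category).
    declared_m
        Optional category -> declared family size (>= genes tested).

    Strata with fewer than 3 samples, or degenerate variance, are flagged
    missing (NaN r/p with a note) rather than dropped.
    """
    common = [s for s in expression.index if s in set(emotionality.index)]
    expr = expression.loc[common]
    emo = emotionality.loc[common]
    d = design.set_index("sample_id").loc[common]

    rows = []
    for stratum, sel in STRATA.items():
        if sel is None:
            ids = list(expr.index)
        else:
            col, level = sel
            ids = list(expr.index[(d[col] == level).to_numpy()])
        for gene in expr.columns:
            cat = categories.get(gene, "unknown")
            x = expr.loc[ids, gene].to_numpy(float)
            y = emo.loc[ids].to_numpy(float)
            if len(ids) < 3:
                rows.append((gene, cat, stratum, np.nan, len(ids), np.nan, "n<3"))
                continue
            try:
                r, p = pearson(x, y, name=f"{gene}/{stratum}")
            except DegenerateDataError:
                rows.append(
                    (gene, cat, stratum, np.nan, len(ids), np.nan, "zero variance")
                )
                continue
            rows.append((gene, cat, stratum, r, len(ids), p, ""))
    out = pd.DataFrame(
        rows, columns=["gene", "category", "stratum", "r", "n", "p", "note"]
    )

    out["q"] = np.nan
    out["significant"] = False
    for (stratum, cat), sub in out.groupby(["stratum", "category"]):
        m = sub["gene"].nunique()
        if declared_m and cat in declared_m:
            m = max(int(declared_m[cat]), m)
        rej, q = bh_adjust(sub["p"], fdr, m=m)
        out.loc[sub.index, "q"] = q
        out.loc[sub.index, "significant"] = rej
    out["sign_class"] = "ns"
    pos = out["significant"] & (out["r"] > 0)
    neg = out["significant"] & (out["r"] < 0)
    out.loc[pos, "sign_class"] = "+"
    out.loc[neg, "sign_class"] = "-"
    return out


def sign_summary(correlations: pd.DataFrame) -> pd.DataFrame:
    """Per-stratum listing of BH-significant positive/negative genes.

    One row per (stratum, sign) with the gene names joined by commas, or
    ``None`` when the list is empty — the layout of a published
    gene-by-behavior correlation summary.
    """
    rows = []
    for stratum in STRATA:
        sub = correlations[correlations["stratum"] == stratum]
        for sign, label in (("+", "(+) correlation"), ("-", "(-) correlation")):
            genes = sorted(sub.loc[sub["sign_class"] == sign, "gene"])
            rows.append(
                (stratum, label, ", ".join(genes) if genes else "None")
            )
    return pd.DataFrame(rows, columns=["stratum", "direction", "genes"])


def sign_summary_markdown(summary: pd.DataFrame) -> str:
    lines = ["| Correlation | Genes |", "| --- | --- |"]
    for _, row in summary.iterrows():
        lines.append(
            f"| {row['direction']} with anxiety-like behavior in {row['stratum']} "
            f"| {row['genes']} |"
        )
    return "\n".join(lines) + "\n"
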