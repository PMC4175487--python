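"""Per-gene 2x2x2 factorial ANOVA, Tukey contrasts, and BH-FDR control.

The model is the full three-way factorial — sex chromosome complement x
gonadal sex x circulating hormone with all three two-way interactions and
the three-way interaction — fitted with sum-to-zero (effect) coding.
Each term is tested with a Type-III F (full model vs the model with that
term's column removed); on balanced designs this coincides with the
classical factorial sums-of-squares decomposition, and the test suite
cross-checks both against a textbook SS oracle and against statsmodels'
``anova_lm(typ=3)``.

Post-hoc pairwise contrasts use the studentized-range (Tukey HSD)
distribution with the mean-square error of the full three-way model,
gated — as in standard practice for planned follow-ups — on the omnibus
model showing at least one significant term.

Multiple testing across genes is controlled per gene category with the
Benjamini-Hochberg step-up procedure; the declared family size ``m`` may
exceed the number of p-values supplied (tests counted but not listed).
"""

from __future__ import annotations

import itertools
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DegenerateDataError

__all__ = [
    "TERMS",
    "fit_factorial",
    "fit_threeway",
    "anova_all_genes",
    "tukey_contrasts",
    "bh_adjust",
]

log = logging.getLogger(__name__)

#: model terms in fit order (chr = sex chromosome, gon = gonadal sex,
#: act = activational hormone)
TERMS = ("chr", "gon", "act", "chr:gon", "chr:act", "gon:act", "chr:gon:act")

_FACTOR_COLUMN = {
    "chr": "sex_chromosome",
    "gon": "gonadal_sex",
    "act": "hormone",
}
_FIRST_LEVEL = {"chr": "XX", "gon": "ovaries", "act": "blank"}


def _effect_codes(design: pd.DataFrame) -> dict[str, np.ndarray]:
    """Sum-to-zero +-1 codes for the three binary factors."""
    codes = {}
    for term, col in _FACTOR_COLUMN.items():
        levels = design[col].to_numpy()
        codes[term] = np.where(levels == _FIRST_LEVEL[term], 1.0, -1.0)
    return codes


def _terms_for(factors: Sequence[str]) -> tuple[str, ...]:
    """All main effects and interactions of the given factors, mains first."""
    terms: list[str] = []
    for size in range(1, len(factors) + 1):
        for combo in itertools.combinations(factors, size):
            terms.append(":".join(combo))
    return tuple(terms)


def _model_matrix(design: pd.DataFrame, terms: Sequence[str]) -> np.ndarray:
    """Intercept + one effect-coded column per term."""
    c = _effect_codes(design)
    cols = [np.ones(len(design))]
    for term in terms:
        col = np.ones(len(design))
        for part in term.split(":"):
            col = col * c[part]
        cols.append(col)
    return np.column_stack(cols)


def _sse(X: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """(residual sum of squares, matrix rank) via least squares."""
    _beta, res, rank, _sv = np.linalg.lstsq(X, y, rcond=None)
    if res.size:
        sse = float(res[0])
    else:  # rank-deficient or saturated: compute residuals explicitly
        fitted = X @ _beta
        sse = float(np.sum((y - fitted) ** 2))
    return sse, rank


def fit_factorial(
    y: pd.Series | np.ndarray,
    design: pd.DataFrame,
    factors: Sequence[str] = ("chr", "gon", "act"),
) -> pd.DataFrame:
    """Type-III F-tests for a full-factorial model over binary factors.

    Parameters
    ----------
    y
        Expression values; if a Series, it is aligned to
        ``design['sample_id']``.
    design
        Design table with the factor columns.
    factors
        Which of ``chr``/``gon``/``act`` enter the model; the model
        always contains all their interactions.

    Returns
    -------
    DataFrame indexed by term with columns ``ss``, ``F``, ``df_num``,
    ``df_den``, ``p``.  Terms that are inestimable (empty cells making
    the column collinear) get NaN with a logged warning.
    """
    if isinstance(y, pd.Series):
        y = y.reindex(design["sample_id"]).to_numpy(float)
    else:
        y = np.asarray(y, float)
    if len(y) != len(design):
        raise ValueError("y and design have different lengths")
    if np.isnan(y).any():
        raise ValueError("y contains missing values")
    for f in factors:
        if f not in _FACTOR_COLUMN:
            raise ValueError(f"unknown factor {f!r}")

    terms = _terms_for(factors)
    X = _model_matrix(design, terms)
    sse_full, rank_full = _sse(X, y)
    df_resid = len(y) - rank_full
    if df_resid <= 0:
        raise DegenerateDataError("no residual degrees of freedom")
    total_ss = float(np.sum((y - y.mean()) ** 2))
    if sse_full <= max(1e-12 * max(total_ss, 1.0), 1e-30):
        raise DegenerateDataError("zero residual variance (constant within cells)")
    mse = sse_full / df_resid

    rows = []
    for i, term in enumerate(terms):
        X_red = np.delete(X, i + 1, axis=1)
        sse_red, rank_red = _sse(X_red, y)
        if rank_red == rank_full:  # column collinear: term inestimable
            log.warning("term %s inestimable (empty cell?)", term)
            rows.append((term, np.nan, np.nan, 1, df_resid, np.nan))
            continue
        ss = max(sse_red - sse_full, 0.0)
        F = ss / mse
        p = max(float(stats.f.sf(F, 1, df_resid)), float(np.finfo(float).tiny))
        rows.append((term, ss, F, 1, df_resid, p))
    out = pd.DataFrame(
        rows, columns=["term", "ss", "F", "df_num", "df_den", "p"]
    ).set_index("term")
    return out


def fit_threeway(y: pd.Series | np.ndarray, design: pd.DataFrame) -> pd.DataFrame:
    """The full three-way model: all main effects, the three first-order
    interactions, and the second-order interaction."""
    return fit_factorial(y, design, factors=("chr", "gon", "act"))


def bh_adjust(
    p_values: Sequence[float], fdr: float = 0.05, m: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up procedure with a declared family size.

    Rejects all ``p_(i)`` with rank ``i <= k*`` where
    ``k* = max{k : p_(k) <= fdr * k / m}``.  ``m`` defaults to the number
    of p-values but may be declared larger (category members tested but
    not listed); declaring it smaller is a configuration error.

    Returns
    -------
    (reject, q)
        Boolean rejection flags and monotone q-values
        (``q_(k) = min_{j>=k} p_(j) * m / j``, capped at 1), both in the
        input order.  NaN p-values are never rejected and get NaN q.
    """
    p = np.asarray(p_values, float)
    n = p.size
    if m is None:
        m = n
    m = int(m)
    finite = ~np.isnan(p)
    n_finite = int(finite.sum())
    if m < n_finite:
        raise ConfigError(f"declared family size m={m} < number of tests {n_finite}")
    if n_finite and ((p[finite] <= 0).any() or (p[finite] > 1).any()):
        raise ValueError("p-values must lie in (0, 1]")

    reject = np.zeros(n, bool)
    q = np.full(n, np.nan)
    if n_finite == 0:
        return reject, q
    idx = np.where(finite)[0]
    order = idx[np.argsort(p[idx], kind="mergesort")]
    p_sorted = p[order]
    ranks = np.arange(1, n_finite + 1)
    passed = p_sorted <= fdr * ranks / m
    if passed.any():
        k_star = int(np.max(np.where(passed)[0])) + 1
        reject[order[:k_star]] = True
    q_sorted = np.minimum.accumulate((p_sorted * m / ranks)[::-1])[::-1]
    q[order] = np.minimum(q_sorted, 1.0)
    return reject, q


def anova_all_genes(
    expression: pd.DataFrame,
    design: pd.DataFrame,
    categories: Mapping[str, str],
    fdr: float = 0.05,
    declared_m: Mapping[str, int] | None = None,
    family: str = "per-term",
    trend_p: float = 0.1,
) -> pd.DataFrame:
    """Tidy per-gene, per-term ANOVA results with BH control per category.

    ``family`` selects the BH pooling mode:

    * ``"per-term"`` (default): one family per (category, term) — each
      factor corrected across the genes of its category;
    * ``"pooled-main"``: the three main-effect p-values of a category
      pooled into one family of size ``3 * m``; interactions remain
      per-term.

    ``declared_m`` optionally overrides the family size per category
    (must be >= the number of genes actually tested).
    """
    if family not in ("per-term", "pooled-main"):
        raise ConfigError(f"unknown BH family mode {family!r}")
    rows = []
    for gene in expression.columns:
        cat = categories.get(gene, "unknown")
        try:
            tab = fit_threeway(expression[gene], design)
        except DegenerateDataError as err:
            log.warning("gene %s: %s", gene, err)
            for term in TERMS:
                rows.append((gene, cat, term, np.nan, np.nan, 1, np.nan, np.nan, True))
            continue
        for term in TERMS:
            r = tab.loc[term]
            rows.append(
                (gene, cat, term, r["ss"], r["F"], 1, r["df_den"], r["p"], False)
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "gene", "category", "term", "ss", "F",
            "df_num", "df_den", "p", "degenerate",
        ],
    )

    out["q"] = np.nan
    out["significant"] = False
    main_terms = ("chr", "gon", "act")
    for cat, sub in out.groupby("category"):
        n_genes = sub["gene"].nunique()
        m = n_genes
        if declared_m and cat in declared_m:
            if declared_m[cat] < n_genes:
                raise ConfigError(
                    f"declared m={declared_m[cat]} < {n_genes} genes in {cat!r}"
                )
            m = int(declared_m[cat])
        if family == "pooled-main":
            mask = sub["term"].isin(main_terms)
            fam_idx = sub.index[mask]
            rej, q = bh_adjust(out.loc[fam_idx, "p"], fdr, m=3 * m)
            out.loc[fam_idx, "q"] = q
            out.loc[fam_idx, "significant"] = rej
            remaining = [t for t in TERMS if t not in main_terms]
        else:
            remaining = list(TERMS)
        for term in remaining:
            fam_idx = sub.index[sub["term"] == term]
            rej, q = bh_adjust(out.loc[fam_idx, "p"], fdr, m=m)
            out.loc[fam_idx, "q"] = q
            out.loc[fam_idx, "significant"] = rej
    out["trend"] = out["p"] < trend_p
    return out


def tukey_contrasts(
    y: pd.Series | np.ndarray,
    design: pd.DataFrame,
    cells: str = "gon:act",
    alpha: float = 0.05,
    gate: bool = True,
) -> pd.DataFrame:
    """Tukey HSD pairwise contrasts among design cells.

    ``cells`` is ``"gon:act"`` (the four gonadal-sex x hormone cells, the
    usual interaction follow-up) or ``"full"`` (all eight cells).  The
    error term is the MSE of the full three-way model, and p-values come
    from the studentized range distribution with ``k`` = number of cells
    and the full model's residual df (Tukey-Kramer form under unequal
    cell sizes).

    When ``gate`` is true the contrasts are only computed if the omnibus
    three-way ANOVA shows at least one term with ``p < alpha``; otherwise
    an empty frame is returned with a logged reason.
    """
    if isinstance(y, pd.Series):
        yv = y.reindex(design["sample_id"]).to_numpy(float)
    else:
        yv = np.asarray(y, float)

    omnibus = fit_threeway(yv, design)
    if gate and not (omnibus["p"] < alpha).any():
        log.info("omnibus ANOVA not significant; no post-hoc contrasts computed")
        return pd.DataFrame(
            columns=["contrast", "diff", "se", "q", "p", "significant"]
        )

    if cells == "gon:act":
        labels = design["gonadal_sex"] + "/" + design["hormone"]
    elif cells == "full":
        labels = design["group"]
    else:
        raise ConfigError(f"unknown cell layout {cells!r}")
    labels = labels.to_numpy()

    X = _model_matrix(design, TERMS)
    sse_full, rank_full = _sse(X, yv)
    df_resid = len(yv) - rank_full
    mse = sse_full / df_resid

    cell_names = list(pd.unique(labels))
    k = len(cell_names)
    means = {c: yv[labels == c].mean() for c in cell_names}
    ns = {c: int((labels == c).sum()) for c in cell_names}

    rows = []
    for a, b in itertools.combinations(cell_names, 2):
        diff = means[a] - means[b]
        se = np.sqrt(mse / 2.0 * (1.0 / ns[a] + 1.0 / ns[b]))
        q_stat = abs(diff) / se
        p = float(stats.studentized_range.sf(q_stat, k, df_resid))
        p = min(max(p, np.finfo(float).tiny), 1.0)
        rows.append((f"{a} - {b}", diff, se, q_stat, p, p < alpha))
    return pd.DataFrame(
        rows, columns=["contrast", "diff", "se", "q", "p", "significant"]
    )
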