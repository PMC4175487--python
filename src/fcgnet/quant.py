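"""Delta-Ct quantification of replicate qPCR CT values.

Quadruplicate CT measurements are collapsed by arithmetic mean, and each
target gene is expressed relative to two internal-control genes as the
arbitrary signal ``2**(-dCT) * 10000``, where ``dCT`` is the target CT
minus the reference CT.  Normalizing against the arithmetic mean of the
two control CTs is algebraically identical to taking the geometric mean
of the two per-control relative intensities ``2**-(CT_g - CT_c)``; both
forms are implemented and the identity is asserted in the test suite.

Averaging CT before the delta (rather than averaging intensities) keeps
the replicate collapse consistent with the geometric-mean convention:
the mean of CTs is the log2 of the geometric mean of intensities.
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import MissingDataError

__all__ = [
    "collapse_replicates",
    "relative_expression",
    "reference_stability_check",
]

log = logging.getLogger(__name__)

SCALE = 10_000.0


def collapse_replicates(ct_long: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Collapse replicate CTs to one value per sample x gene.

    Parameters
    ----------
    ct_long
        Long-format table with columns ``sample_id``, ``gene``,
        ``replicate``, ``ct``.

    Returns
    -------
    (ct_mean, n_replicates)
        Wide samples x genes tables: the arithmetic-mean CT and the
        replicate count retained for QC.  Sample/gene combinations never
        measured appear as NaN (0 in the count table) rather than being
        dropped silently.
    """
    required = {"sample_id", "gene", "ct"}
    missing = required - set(ct_long.columns)
    if missing:
        raise ValueError(f"ct table missing columns: {sorted(missing)}")
    if not np.isfinite(ct_long["ct"]).all():
        raise ValueError("CT values must be finite")
    grouped = ct_long.groupby(["sample_id", "gene"], sort=False)["ct"]
    ct_mean = grouped.mean().unstack("gene")
    n_rep = grouped.size().unstack("gene").fillna(0).astype(int)
    n_missing = int(ct_mean.isna().to_numpy().sum())
    if n_missing:
        log.warning("%d sample x gene cells have no replicates", n_missing)
    return ct_mean, n_rep


def relative_expression(
    ct_mean: pd.DataFrame,
    reference_genes: Sequence[str],
    method: str = "mean-ct",
) -> pd.DataFrame:
    """Relative expression in arbitrary units (``2**-dCT * 10000``).

    Parameters
    ----------
    ct_mean
        Wide samples x genes mean-CT table from
        :func:`collapse_replicates`.
    reference_genes
        Exactly two internal-control gene names present in the columns.
    method
        ``"mean-ct"`` computes ``dCT = CT_g - mean(CT_c1, CT_c2)``;
        ``"geometric"`` takes the geometric mean of the two per-control
        intensities.  The two are mathematically identical and kept as
        mutual cross-checks.

    Samples missing either reference CT are excluded (with a logged
    reason) since dCT is undefined for them.
    """
    refs = list(reference_genes)
    if len(refs) != 2:
        raise ValueError("exactly two reference genes are required")
    for r in refs:
        if r not in ct_mean.columns:
            raise MissingDataError(f"reference gene {r!r} absent from CT table")
    targets = [g for g in ct_mean.columns if g not in refs]

    ok = ct_mean[refs].notna().all(axis=1)
    if (~ok).any():
        dropped = list(ct_mean.index[~ok])
        log.warning(
            "excluding %d sample(s) with missing reference CT: %s",
            len(dropped), dropped,
        )
    ct = ct_mean.loc[ok]

    if method == "mean-ct":
        dct = ct[targets].sub(ct[refs].mean(axis=1), axis=0)
        expr = np.power(2.0, -dct) * SCALE
    elif method == "geometric":
        rel1 = np.power(2.0, -(ct[targets].sub(ct[refs[0]], axis=0)))
        rel2 = np.power(2.0, -(ct[targets].sub(ct[refs[1]], axis=0)))
        expr = np.sqrt(rel1 * rel2) * SCALE
    else:
        raise ValueError(f"unknown method {method!r}")
    expr.columns.name = "gene"
    return expr


def reference_stability_check(
    ct_mean: pd.DataFrame,
    design: pd.DataFrame,
    reference_genes: Sequence[str],
    threshold: float = 0.5,
) -> dict[str, float]:
    """QC: range of per-group mean CT for each reference gene.

    CT is a log2-scale quantity, so a group-mean range above
    ``threshold`` (default 0.5 cycles ~ 1.4-fold) suggests the control is
    influenced by the design factors; a warning is emitted but nothing is
    dropped (controls are assumed validated upstream).
    """
    groups = design.set_index("sample_id")["group"]
    ranges: dict[str, float] = {}
    for gene in reference_genes:
        means = ct_mean[gene].groupby(groups.reindex(ct_mean.index)).mean()
        rng = float(means.max() - means.min())
        ranges[gene] = rng
        if rng > threshold:
            warnings.warn(
                f"reference gene {gene} varies across groups "
                f"(CT range {rng:.2f} > {threshold})",
                stacklevel=2,
            )
    return ranges
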