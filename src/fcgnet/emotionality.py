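"""Composite anxiety-like emotionality Z-scores.

Each raw behavior measure is standardized against a comparison group
(by default the XX, blank-capsule mice): ``z = direction * (X - mu) /
sigma`` with ``mu``/``sigma`` the comparison-group mean and sample SD
(n-1 denominator).  The direction flips measures for which a larger raw
value means *less* anxiety (e.g. time in the open arms), so increased
scores always reflect increased anxiety-like emotionality.

Scores are then composed in two enforced levels: per-measure z-scores
are averaged within each behavior test (EPM, OF, ...), and the per-test
scores are averaged into one overall emotionality score per animal.
Pooling all measures into a single mean would weight tests by their
measure count and is deliberately not offered.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, MissingDataError

__all__ = ["zscore_measure", "emotionality_scores", "comparison_group_ids"]

log = logging.getLogger(__name__)


def comparison_group_ids(
    design: pd.DataFrame,
    sex_chromosome: str = "XX",
    hormone: str = "blank",
) -> list[str]:
    """Sample ids of the comparison group (default: XX + blank capsule)."""
    mask = (design["sex_chromosome"] == sex_chromosome) & (
        design["hormone"] == hormone
    )
    return list(design.loc[mask, "sample_id"])


def zscore_measure(
    values: pd.Series,
    comparison_ids: Sequence[str],
    direction: int,
    measure: str = "",
) -> pd.Series:
    """Per-sample z-score of one measure against the comparison group.

    Comparison-group members receive scores too (their mean is ~0 by
    construction).  A zero comparison-group SD makes the scale undefined
    and raises :class:`DegenerateDataError` naming the measure.
    """
    if direction not in (-1, 1):
        raise ValueError("direction must be +1 or -1")
    comp = values.reindex(comparison_ids).dropna()
    if len(comp) < 2:
        raise MissingDataError(
            f"measure {measure or values.name!r}: fewer than 2 comparison-group "
            "observations"
        )
    mu = comp.mean()
    sigma = comp.std(ddof=1)
    if sigma == 0 or not np.isfinite(sigma):
        raise DegenerateDataError(
            f"measure {measure or values.name!r}: comparison-group SD is zero"
        )
    return direction * (values - mu) / sigma


def emotionality_scores(
    behavior: pd.DataFrame,
    directions: Mapping[str, int],
    comparison_ids: Sequence[str],
) -> pd.DataFrame:
    """Three-level emotionality composite per animal.

    Parameters
    ----------
    behavior
        Long table with columns ``sample_id``, ``test``, ``measure``,
        ``value``.
    directions
        Measure -> +1 (larger raw value = more anxious) or -1.
    comparison_ids
        Sample ids defining mu and sigma for every measure.

    Returns
    -------
    DataFrame indexed by sample with one ``z_<test>`` column per behavior
    test and ``z_overall`` (mean of the per-test scores).  Samples missing
    every measure of a test get NaN for that test and are averaged over
    the remaining tests; a sample missing all tests is an error.
    """
    required = {"sample_id", "test", "measure", "value"}
    missing_cols = required - set(behavior.columns)
    if missing_cols:
        raise ValueError(f"behavior table missing columns: {sorted(missing_cols)}")
    measures = behavior[["test", "measure"]].drop_duplicates()
    unmapped = [m for m in measures["measure"] if m not in directions]
    if unmapped:
        raise ValueError(f"measures without a direction: {unmapped}")

    wide = behavior.pivot_table(
        index="sample_id", columns="measure", values="value", aggfunc="mean"
    )
    per_measure = pd.DataFrame(index=wide.index)
    for _, row in measures.iterrows():
        m = row["measure"]
        per_measure[m] = zscore_measure(
            wide[m], comparison_ids, int(directions[m]), measure=m
        )

    result = pd.DataFrame(index=wide.index)
    test_of = dict(zip(measures["measure"], measures["test"]))
    for test in measures["test"].unique():
        cols = [m for m, t in test_of.items() if t == test]
        block = per_measure[cols]
        n_missing = int(block.isna().to_numpy().sum())
        if n_missing:
            log.info("test %s: %d missing measure values excluded", test, n_missing)
        result[f"z_{test}"] = block.mean(axis=1)

    test_cols = [c for c in result.columns if c.startswith("z_")]
    if result[test_cols].isna().all(axis=1).any():
        bad = list(result.index[result[test_cols].isna().all(axis=1)])
        raise MissingDataError(f"samples with no scorable test: {bad}")
    result["z_overall"] = result[test_cols].mean(axis=1)
    result.index.name = "sample_id"
    return result
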