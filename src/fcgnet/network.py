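"""|r|^3-weighted gene co-expression networks and their global properties.

Within a group of samples, every gene pair gets a signed Pearson
correlation ``r_ij``; the edge weight is ``w_ij = |r_ij|**3``, boosting
strong correlations and shrinking weak (noise-driven) ones.  The sign is
kept separately for annotation only — all graph statistics use the
magnitude weights.

Global properties follow the weighted conventions:

* **density** — mean weighted degree over ``n - 1``; 1 for a complete
  unit-weight graph;
* **global clustering coefficient** — the node mean of the weighted
  local coefficient ``sum_{j!=i} sum_{k!=i,j} w_ij w_jk w_ki /
  ((sum_j w_ij)^2 - sum_j w_ij^2)`` (ordered pairs in the numerator,
  matching the symmetric denominator); nodes whose denominator is zero
  are excluded from the mean;
* **assortativity** — Newman's degree-correlation coefficient over the
  edge list, ``r = [M^-1 sum j_i k_i - (M^-1 sum (j_i+k_i)/2)^2] /
  [M^-1 sum (j_i^2+k_i^2)/2 - (M^-1 sum (j_i+k_i)/2)^2]``.  Since every
  node of a complete weighted graph has the same *edge count*, the
  endpoint values ``j_i, k_i`` are the *weighted* degrees and the edge
  list is the set of pairs with positive (post-threshold) weight; a
  perfectly regular graph has zero denominator and the value is reported
  undefined, not zero.

Networks from paired groups (e.g. gonadal males vs females) are compared
by a label permutation test: pooled samples are reassigned at random
preserving group sizes, both networks rebuilt, and the two-sided p-value
is the smoothed tail frequency ``(1 + #{|d_perm| >= |d_obs|}) /
(n_valid + 1)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import UndefinedPropertyError
from .simulate import FACTORS, MALE_LEVEL

__all__ = [
    "CoexpressionNetwork",
    "PermutationResult",
    "build_network",
    "density",
    "local_clustering",
    "clustering_global",
    "assortativity",
    "network_properties",
    "compare_networks",
    "project_reference",
    "to_edge_list",
    "write_graphml",
    "properties_table",
]

log = logging.getLogger(__name__)

PROPERTIES = ("density", "clustering", "assortativity")


@dataclass
class CoexpressionNetwork:
    """A per-group weighted gene graph."""

    genes: list[str]
    corr: np.ndarray  # signed r, zero diagonal
    weight: np.ndarray  # |r|**3 after thresholding, zero diagonal
    group: str = ""
    n_samples: int = 0
    tau: float = 0.0

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def weighted_degree(self) -> np.ndarray:
        return self.weight.sum(axis=1)


@dataclass
class PermutationResult:
    """Outcome of a permutation comparison of one global property."""

    property: str
    observed: float  # prop(A) - prop(B)
    null: np.ndarray = field(repr=False)
    p: float = np.nan
    n_perm: int = 0
    n_undefined: int = 0
    seed: int | None = None
    unreliable: bool = False


def _corr_and_weight(X: np.ndarray, tau: float) -> tuple[np.ndarray, np.ndarray]:
    r = np.corrcoef(X, rowvar=False)
    np.fill_diagonal(r, 0.0)
    w = np.abs(r) ** 3
    if tau > 0:
        w[np.abs(r) < tau] = 0.0
    np.fill_diagonal(w, 0.0)
    return r, w


def build_network(
    expression: pd.DataFrame,
    sample_ids: Sequence[str] | None = None,
    group: str = "",
    tau: float = 0.0,
) -> CoexpressionNetwork:
    """Signed-correlation, |r|^3-weighted network from a sample group.

    Genes with zero variance within the group are excluded with a
    warning (their correlations are undefined).  ``tau`` zeroes edges
    with ``|r| < tau`` (default 0: complete weighted graph).
    """
    sub = expression if sample_ids is None else expression.loc[list(sample_ids)]
    if len(sub) < 3:
        raise ValueError("need at least 3 samples to estimate correlations")
    X = sub.to_numpy(float)
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.all():
        dropped = [g for g, k in zip(sub.columns, keep) if not k]
        log.warning("excluding zero-variance genes: %s", dropped)
        X = X[:, keep]
    genes = [g for g, k in zip(sub.columns, keep) if k]
    if len(genes) < 3:
        raise ValueError("fewer than 3 genes with nonzero variance")
    r, w = _corr_and_weight(X, tau)
    return CoexpressionNetwork(
        genes=genes, corr=r, weight=w, group=group, n_samples=len(sub), tau=tau
    )


# -- global properties (array kernels shared with the permutation loop) ----


def _density(W: np.ndarray) -> float:
    n = W.shape[0]
    if n < 2:
        raise UndefinedPropertyError("density needs at least 2 nodes")
    return float(W.sum(axis=1).mean() / (n - 1))


def _local_clustering(W: np.ndarray) -> np.ndarray:
    if W.shape[0] < 3:
        raise UndefinedPropertyError("clustering needs at least 3 nodes")
    num = np.einsum("ij,jk,ki->i", W, W, W)  # ordered (j,k): triangles twice
    k = W.sum(axis=1)
    denom = k**2 - (W**2).sum(axis=1)
    out = np.full(W.shape[0], np.nan)
    ok = denom > 0
    out[ok] = num[ok] / denom[ok]
    return out


def _clustering_global(W: np.ndarray) -> float:
    local = _local_clustering(W)
    ok = ~np.isnan(local)
    if not ok.any():
        raise UndefinedPropertyError("all local clustering denominators are zero")
    n_excluded = int((~ok).sum())
    if n_excluded:
        log.info("clustering: %d node(s) with degree < 2 excluded", n_excluded)
    return float(local[ok].mean())


def _assortativity(W: np.ndarray) -> float:
    iu, ju = np.triu_indices(W.shape[0], k=1)
    mask = W[iu, ju] > 0
    if mask.sum() < 2:
        raise UndefinedPropertyError("assortativity needs at least 2 edges")
    k = W.sum(axis=1)  # weighted degrees
    ji = k[iu[mask]]
    ki = k[ju[mask]]
    M = float(mask.sum())
    mean_jk = (ji * ki).mean()
    mean_half_sum = (0.5 * (ji + ki)).mean()
    mean_half_sq = (0.5 * (ji**2 + ki**2)).mean()
    denom = mean_half_sq - mean_half_sum**2
    num = mean_jk - mean_half_sum**2
    scale = max(mean_half_sq, 1.0)
    if abs(denom) <= 1e-12 * scale:
        raise UndefinedPropertyError(
            "assortativity undefined: all endpoint degrees equal (regular graph)"
        )
    return float(num / denom)


_KERNELS = {
    "density": _density,
    "clustering": _clustering_global,
    "assortativity": _assortativity,
}


def density(network: CoexpressionNetwork) -> float:
    """Mean weighted degree over n - 1."""
    return _density(network.weight)


def local_clustering(network: CoexpressionNetwork) -> np.ndarray:
    """Weighted local clustering per node; NaN where the denominator is 0."""
    return _local_clustering(network.weight)


def clustering_global(network: CoexpressionNetwork) -> float:
    """Node-mean weighted clustering coefficient."""
    return _clustering_global(network.weight)


def assortativity(network: CoexpressionNetwork) -> float:
    """Newman degree-correlation over the (thresholded) edge list."""
    return _assortativity(network.weight)


def network_properties(network: CoexpressionNetwork) -> dict[str, float]:
    """All three global properties; undefined ones are NaN."""
    out = {}
    for name in PROPERTIES:
        try:
            out[name] = _KERNELS[name](network.weight)
        except UndefinedPropertyError:
            out[name] = np.nan
    return out


def compare_networks(
    expression: pd.DataFrame,
    group_a_ids: Sequence[str],
    group_b_ids: Sequence[str],
    property: str = "density",
    n_perm: int = 1000,
    seed: int | None = None,
    tau: float = 0.0,
) -> PermutationResult:
    """Permutation test for a global-property difference between groups.

    The observed statistic is ``prop(A) - prop(B)``.  Each permutation
    reassigns the pooled samples to two pseudo-groups of the original
    sizes, rebuilds both networks and recomputes the difference;
    permutations where the property is undefined for either pseudo-group
    are recorded and excluded (the p denominator shrinks accordingly,
    and the result is flagged unreliable beyond 20% exclusions).
    """
    if property not in PROPERTIES:
        raise ValueError(f"property must be one of {PROPERTIES}")
    kernel = _KERNELS[property]
    a = list(group_a_ids)
    b = list(group_b_ids)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("both groups need at least 3 samples")

    Xa = expression.loc[a].to_numpy(float)
    Xb = expression.loc[b].to_numpy(float)
    obs = kernel(_corr_and_weight(Xa, tau)[1]) - kernel(_corr_and_weight(Xb, tau)[1])

    pooled = expression.loc[a + b].to_numpy(float)
    n_a = len(a)
    n_tot = len(a) + len(b)
    rng = np.random.default_rng(seed)
    null = np.full(n_perm, np.nan)
    n_undefined = 0
    for i in range(n_perm):
        perm = rng.permutation(n_tot)
        Pa = pooled[perm[:n_a]]
        Pb = pooled[perm[n_a:]]
        try:
            null[i] = (
                kernel(_corr_and_weight(Pa, tau)[1])
                - kernel(_corr_and_weight(Pb, tau)[1])
            )
        except UndefinedPropertyError:
            n_undefined += 1
    valid = null[~np.isnan(null)]
    n_valid = valid.size
    if n_valid == 0:
        raise UndefinedPropertyError("property undefined in every permutation")
    p = (1.0 + np.count_nonzero(np.abs(valid) >= abs(obs))) / (n_valid + 1.0)
    unreliable = n_undefined > 0.2 * n_perm
    if unreliable:
        log.warning(
            "%s: %d/%d permutations undefined; p-value unreliable",
            property, n_undefined, n_perm,
        )
    return PermutationResult(
        property=property,
        observed=float(obs),
        null=null,
        p=float(p),
        n_perm=n_perm,
        n_undefined=n_undefined,
        seed=seed,
        unreliable=unreliable,
    )


def project_reference(
    reference: CoexpressionNetwork,
    expression: pd.DataFrame,
    sample_ids: Sequence[str],
    group: str = "",
) -> CoexpressionNetwork:
    """Recompute weights for another group on the reference edge set.

    The edge set (pairs with positive reference weight) is fixed from the
    reference network — typically the "male" phenotype, whose structure
    the paired "female" data is plotted on — while correlations, weights
    and signs come from the other group's samples.  Intended for export
    and visual comparison; group statistics are normally computed from
    each group's own full network.
    """
    sub = expression.loc[list(sample_ids)]
    missing = [g for g in reference.genes if g not in sub.columns]
    if missing:
        raise ValueError(f"projection group lacks genes: {missing}")
    sub = sub[reference.genes]
    r, w = _corr_and_weight(sub.to_numpy(float), tau=0.0)
    mask = reference.weight > 0
    w = np.where(mask, w, 0.0)  # r kept in full for annotation, as in build
    return CoexpressionNetwork(
        genes=list(reference.genes),
        corr=r,
        weight=w,
        group=group or f"{reference.group}-structure",
        n_samples=len(sub),
        tau=reference.tau,
    )


# -- export ----------------------------------------------------------------


def to_edge_list(network: CoexpressionNetwork) -> pd.DataFrame:
    """Long edge table (gene_i, gene_j, r, weight, sign) for all pairs
    with positive weight."""
    iu, ju = np.triu_indices(network.n_genes, k=1)
    rows = []
    for i, j in zip(iu, ju):
        w = network.weight[i, j]
        if w <= 0:
            continue
        r = network.corr[i, j]
        rows.append(
            (network.genes[i], network.genes[j], r, w, int(np.sign(r)))
        )
    return pd.DataFrame(rows, columns=["gene_i", "gene_j", "r", "weight", "sign"])


def to_networkx(network: CoexpressionNetwork) -> nx.Graph:
    g = nx.Graph()
    deg = network.weighted_degree()
    for gene, d in zip(network.genes, deg):
        g.add_node(gene, degree=float(d))
    for _, row in to_edge_list(network).iterrows():
        g.add_edge(
            row["gene_i"], row["gene_j"],
            weight=float(row["weight"]), sign=int(row["sign"]),
        )
    return g


def write_graphml(network: CoexpressionNetwork, path) -> None:
    nx.write_graphml(to_networkx(network), path)


def properties_table(
    expression: pd.DataFrame,
    design: pd.DataFrame,
    n_perm: int = 1000,
    seed: int | None = None,
    tau: float = 0.0,
    projection: str = "own",
) -> pd.DataFrame:
    """Global properties of the six single-factor networks plus
    permutation p-values for each male/female pairing.

    ``projection="own"`` (default) computes female-group statistics from
    the female group's own full network; ``"male-reference"`` computes
    them on the male-structure projection instead.  Permutation p-values
    always compare own full networks.
    """
    if projection not in ("own", "male-reference"):
        raise ValueError("projection must be 'own' or 'male-reference'")
    d = design.set_index("sample_id").loc[expression.index]
    columns: dict[str, dict[str, float]] = {}
    pvals: dict[str, dict[str, float]] = {}
    for fi, factor in enumerate(FACTORS):
        male_level = MALE_LEVEL[factor]
        levels = list(dict.fromkeys(d[factor]))
        female_level = next(l for l in levels if l != male_level)
        ids_m = list(expression.index[(d[factor] == male_level).to_numpy()])
        ids_f = list(expression.index[(d[factor] == female_level).to_numpy()])
        net_m = build_network(expression, ids_m, group=male_level, tau=tau)
        if projection == "male-reference":
            net_f = project_reference(net_m, expression, ids_f, group=female_level)
        else:
            net_f = build_network(expression, ids_f, group=female_level, tau=tau)
        columns[female_level] = network_properties(net_f)
        columns[male_level] = network_properties(net_m)
        pcol = {}
        for prop in PROPERTIES:
            sub_seed = None if seed is None else (int(seed) + fi) % (2**31)
            res = compare_networks(
                expression, ids_m, ids_f, prop,
                n_perm=n_perm, seed=sub_seed, tau=tau,
            )
            pcol[prop] = res.p
        pvals[f"{factor}_p"] = pcol
    ordered: dict[str, dict[str, float]] = {}
    for factor in FACTORS:
        male_level = MALE_LEVEL[factor]
        female_level = next(
            l for l in dict.fromkeys(d[factor]) if l != male_level
        )
        ordered[female_level] = columns[female_level]
        ordered[male_level] = columns[male_level]
        ordered[f"{factor}_p"] = pvals[f"{factor}_p"]
    table = pd.DataFrame(ordered).reindex(list(PROPERTIES))
    table.index.name = "property"
    return table
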