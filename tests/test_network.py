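"""|r|^3 co-expression networks: weight construction, global graph
properties against independent oracles, permutation comparison, and
reference projection."""

import numpy as np
import pandas as pd
import pytest

import fcgnet
from fcgnet.errors import UndefinedPropertyError
from fcgnet.network import (
    assortativity,
    build_network,
    clustering_global,
    compare_networks,
    density,
    local_clustering,
    network_properties,
    project_reference,
    properties_table,
    to_edge_list,
)
from conftest import make_weight_network, random_weight_matrix


# ---------------------------------------------------------------------------
# independent oracles


def clustering_brute_force(W):
    """Literal triple loop over ordered (j, k) pairs."""
    n = W.shape[0]
    values = []
    for i in range(n):
        num = 0.0
        for j in range(n):
            if j == i:
                continue
            for k in range(n):
                if k == i or k == j:
                    continue
                num += W[i, j] * W[j, k] * W[k, i]
        s = sum(W[i, j] for j in range(n) if j != i)
        s2 = sum(W[i, j] ** 2 for j in range(n) if j != i)
        denom = s**2 - s2
        if denom > 0:
            values.append(num / denom)
    return float(np.mean(values))


def assortativity_doubled_pearson(W):
    """Pearson correlation of endpoint weighted degrees over the
    symmetrized (doubled) edge list — the known identity form."""
    k = W.sum(axis=1)
    xs, ys = [], []
    n = W.shape[0]
    for i in range(n):
        for j in range(n):
            if i != j and W[i, j] > 0:
                xs.append(k[i])
                ys.append(k[j])
    return float(np.corrcoef(xs, ys)[0, 1])


# ---------------------------------------------------------------------------
# weight construction


def test_weights_are_cubed_absolute_correlations():
    rng = np.random.default_rng(0)
    base = rng.normal(size=24)
    expr = pd.DataFrame(
        {
            "a": base,
            "b": base * 2 + 1,  # r = +1
            "c": -0.8 * base + rng.normal(0, 0.6, 24),
            "d": rng.normal(size=24),
        },
        index=[f"s{i}" for i in range(24)],
    )
    net = build_network(expr)
    i = {g: k for k, g in enumerate(net.genes)}
    assert net.weight[i["a"], i["b"]] == pytest.approx(1.0)
    r_ac = np.corrcoef(expr["a"], expr["c"])[0, 1]
    assert net.weight[i["a"], i["c"]] == pytest.approx(abs(r_ac) ** 3)
    assert net.corr[i["a"], i["c"]] == pytest.approx(r_ac)
    assert net.corr[i["a"], i["c"]] < 0  # sign stored separately
    assert (net.weight >= 0).all() and (net.weight <= 1).all()
    np.testing.assert_allclose(net.weight, net.weight.T)


def test_r_half_gives_weight_one_eighth():
    assert abs(0.5) ** 3 == pytest.approx(0.125)
    assert abs(-0.8) ** 3 == pytest.approx(0.512)


def test_tau_threshold_zeroes_weak_edges():
    rng = np.random.default_rng(1)
    expr = pd.DataFrame(
        rng.normal(size=(30, 5)), index=[f"s{i}" for i in range(30)],
        columns=list("abcde"),
    )
    net = build_network(expr, tau=0.9)
    assert net.weight.sum() == 0.0  # random data: no |r| >= 0.9


def test_zero_variance_gene_excluded():
    rng = np.random.default_rng(2)
    expr = pd.DataFrame(
        {
            "a": rng.normal(size=10),
            "b": rng.normal(size=10),
            "c": rng.normal(size=10),
            "flat": np.ones(10),
        },
        index=[f"s{i}" for i in range(10)],
    )
    net = build_network(expr)
    assert "flat" not in net.genes and len(net.genes) == 3


# ---------------------------------------------------------------------------
# closed-form property cases


def test_density_closed_forms():
    complete = make_weight_network(1.0 - np.eye(5))
    assert density(complete) == pytest.approx(1.0)
    empty = make_weight_network(np.zeros((4, 4)))
    assert density(empty) == 0.0
    w = np.zeros((3, 3))
    w[0, 1] = w[1, 0] = w[0, 2] = w[2, 0] = w[1, 2] = w[2, 1] = 0.5
    assert density(make_weight_network(w)) == pytest.approx(0.5)


def test_clustering_closed_forms():
    triangle = make_weight_network(1.0 - np.eye(3))
    assert clustering_global(triangle) == pytest.approx(1.0)
    # path a-b-c: node b has no triangle; a and c have degree 1 (excluded)
    w = np.zeros((3, 3))
    w[0, 1] = w[1, 0] = w[1, 2] = w[2, 1] = 1.0
    net = make_weight_network(w)
    local = local_clustering(net)
    assert local[1] == 0.0
    assert np.isnan(local[0]) and np.isnan(local[2])
    assert clustering_global(net) == 0.0


def test_assortativity_closed_forms():
    # star K_{1,3}: every edge joins the hub (degree 3) to a leaf (degree 1)
    star = np.zeros((4, 4))
    star[0, 1:] = star[1:, 0] = 1.0
    assert assortativity(make_weight_network(star)) == pytest.approx(-1.0)
    # path P3: M=2, sum jk = 4, sum (j+k)/2 = 3, sum (j^2+k^2)/2 = 5
    path = np.zeros((3, 3))
    path[0, 1] = path[1, 0] = path[1, 2] = path[2, 1] = 1.0
    assert assortativity(make_weight_network(path)) == pytest.approx(-1.0)
    # cycle C4 is regular: denominator 0 -> undefined, not 0
    cycle = np.zeros((4, 4))
    for i in range(4):
        cycle[i, (i + 1) % 4] = cycle[(i + 1) % 4, i] = 1.0
    with pytest.raises(UndefinedPropertyError):
        assortativity(make_weight_network(cycle))


def test_all_zero_clustering_is_undefined():
    with pytest.raises(UndefinedPropertyError):
        clustering_global(make_weight_network(np.zeros((4, 4))))


# ---------------------------------------------------------------------------
# oracle equivalence and invariances


def test_clustering_matches_brute_force():
    rng = np.random.default_rng(3)
    for _ in range(25):
        W = random_weight_matrix(rng, 6)
        net = make_weight_network(W)
        assert clustering_global(net) == pytest.approx(
            clustering_brute_force(W), abs=1e-12
        )


def test_assortativity_matches_doubled_pearson():
    rng = np.random.default_rng(4)
    for _ in range(25):
        W = random_weight_matrix(rng, 7)
        # sparsify so degrees differ
        W[W < 0.4] = 0.0
        net = make_weight_network(W)
        try:
            ours = assortativity(net)
        except UndefinedPropertyError:
            continue
        assert ours == pytest.approx(assortativity_doubled_pearson(W), abs=1e-9)


def test_properties_invariant_under_relabeling():
    rng = np.random.default_rng(5)
    W = random_weight_matrix(rng, 8)
    W[W < 0.3] = 0.0
    perm = rng.permutation(8)
    net = make_weight_network(W)
    net_p = make_weight_network(W[np.ix_(perm, perm)])
    assert density(net) == pytest.approx(density(net_p), rel=1e-12)
    assert clustering_global(net) == pytest.approx(
        clustering_global(net_p), rel=1e-12
    )
    assert assortativity(net) == pytest.approx(assortativity(net_p), rel=1e-9)


def test_density_and_clustering_monotone_in_weights():
    rng = np.random.default_rng(6)
    W = random_weight_matrix(rng, 6)
    net = make_weight_network(W)
    W2 = W.copy()
    W2[0, 1] = W2[1, 0] = min(W[0, 1] + 0.3, 1.0)
    net2 = make_weight_network(W2)
    assert density(net2) > density(net)
    assert clustering_global(net2) >= clustering_global(net) - 1e-12


def test_complete_graph_assortativity_is_sampling_constant():
    """Over *all* pairs the endpoint-degree correlation is exactly
    -1/(n-1) whatever the weights (finite-population identity) — the
    reason informative assortativity needs a threshold."""
    rng = np.random.default_rng(7)
    W = random_weight_matrix(rng, 9)
    assert assortativity(make_weight_network(W)) == pytest.approx(
        -1.0 / 8.0, abs=1e-9
    )


# ---------------------------------------------------------------------------
# permutation comparison


def _group_expr(rng, n, genes=6):
    return pd.DataFrame(
        rng.normal(size=(n, genes)),
        index=[f"s{i}" for i in range(n)],
        columns=[f"g{i}" for i in range(genes)],
    )


def test_identical_groups_give_p_one():
    rng = np.random.default_rng(8)
    expr = _group_expr(rng, 10)
    ids = list(expr.index)
    res = compare_networks(expr, ids, ids, "density", n_perm=99, seed=0)
    assert res.observed == 0.0
    assert res.p == 1.0


def test_permutation_reproducible_given_seed():
    rng = np.random.default_rng(9)
    expr = _group_expr(rng, 20)
    ids = list(expr.index)
    a = compare_networks(expr, ids[:10], ids[10:], "density", n_perm=200, seed=42)
    b = compare_networks(expr, ids[:10], ids[10:], "density", n_perm=200, seed=42)
    assert a.p == b.p
    np.testing.assert_array_equal(a.null, b.null)
    assert 0 < a.p <= 1


def test_planted_module_increases_male_density():
    """The default male-only module makes gonadal-male networks denser
    than gonadal-female ones, detectably by permutation."""
    cfg = fcgnet.default_config(n_per_group=10, seed=17)
    design, _, _, _, truth = fcgnet.generate_dataset(cfg)
    expr = np.power(2.0, truth.latent_log2)
    d = design.set_index("sample_id")
    males = list(expr.index[(d["gonadal_sex"] == "testes").to_numpy()])
    females = list(expr.index[(d["gonadal_sex"] == "ovaries").to_numpy()])
    net_m = build_network(expr, males)
    net_f = build_network(expr, females)
    assert density(net_m) > density(net_f)
    res = compare_networks(expr, males, females, "density", n_perm=200, seed=1)
    assert res.observed > 0
    assert res.p < 0.05


# ---------------------------------------------------------------------------
# projection onto a reference structure


def test_projecting_group_onto_itself_is_identity():
    rng = np.random.default_rng(10)
    expr = _group_expr(rng, 12)
    ids = list(expr.index)
    net = build_network(expr, ids, tau=0.3)
    proj = project_reference(net, expr, ids)
    np.testing.assert_allclose(proj.weight, net.weight, atol=1e-12)
    np.testing.assert_allclose(proj.corr, net.corr, atol=1e-12)


def test_projection_keeps_only_reference_edges():
    rng = np.random.default_rng(11)
    expr_a = _group_expr(rng, 15)
    expr_b = pd.DataFrame(
        rng.normal(size=(15, 6)),
        index=[f"t{i}" for i in range(15)],
        columns=expr_a.columns,
    )
    both = pd.concat([expr_a, expr_b])
    ref = build_network(both, list(expr_a.index), tau=0.4)
    proj = project_reference(ref, both, list(expr_b.index))
    assert ((ref.weight == 0) >= (proj.weight == 0)).all() or (
        proj.weight[ref.weight == 0] == 0
    ).all()


def test_projection_with_empty_reference_has_no_edges():
    rng = np.random.default_rng(12)
    expr = _group_expr(rng, 12)
    ref = build_network(expr, list(expr.index), tau=0.999)
    proj = project_reference(ref, expr, list(expr.index))
    assert proj.weight.sum() == 0.0
    assert to_edge_list(proj).empty


def test_projection_gene_mismatch_errors():
    rng = np.random.default_rng(13)
    expr = _group_expr(rng, 10)
    ref = build_network(expr, list(expr.index))
    with pytest.raises(ValueError, match="lacks genes"):
        project_reference(ref, expr[["g0", "g1", "g2"]], list(expr.index))


# ---------------------------------------------------------------------------
# table + export


def test_properties_table_layout(expression, dataset):
    design = dataset[0]
    table = properties_table(expression, design, n_perm=50, seed=0)
    assert list(table.index) == ["density", "clustering", "assortativity"]
    assert {"XX", "XY-", "ovaries", "testes", "blank", "testosterone"} <= set(
        table.columns
    )
    p_cols = [c for c in table.columns if c.endswith("_p")]
    assert len(p_cols) == 3
    assert ((table[p_cols] > 0) & (table[p_cols] <= 1)).all().all()


def test_graphml_and_edge_list_roundtrip(tmp_path, expression):
    import networkx as nx

    net = build_network(expression, list(expression.index[:12]))
    edges = to_edge_list(net)
    assert set(edges.columns) == {"gene_i", "gene_j", "r", "weight", "sign"}
    assert ((edges["weight"] > 0) & (edges["weight"] <= 1)).all()
    path = tmp_path / "net.graphml"
    fcgnet.network.write_graphml(net, path)
    g = nx.read_graphml(path)
    assert g.number_of_nodes() == net.n_genes
    assert g.number_of_edges() == len(edges)
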