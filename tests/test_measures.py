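"""Measure values against closed forms and independent brute-force oracles."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netcentral import (
    abh,
    betweenness_normalized,
    closeness_normalized,
    degree_stats,
    ecd,
    eigenvector_centrality,
    enumerate_labeled_graphs,
    make_complete,
    make_ring,
    make_star,
    measure_all,
    nbc,
    ncc,
    ndc,
    nde,
    ndv,
    ngc,
    nhd,
    nht,
    nnc,
    perturb_star,
    relabel,
    spectral_summary,
)
from netcentral.measures import MEASURE_IDS, DisconnectedGraphError, TOLERANCES, dv_max


def graph(edges, n=None):
    g = nx.Graph()
    if n is not None:
        g.add_nodes_from(range(n))
    g.add_edges_from(edges)
    return g


PRINTED = [(0, 1), (0, 3), (0, 4), (0, 5), (1, 2)]  # rewired 6-star
PATH4 = [(0, 1), (1, 2), (2, 3)]


# ---------------------------------------------------------------------------
# ingredients


def test_degree_stats_counts():
    s = degree_stats(perturb_star(6))
    assert s.dmax == 4
    assert s.mean == pytest.approx(5 / 3)
    assert s.histogram == {4: 1, 2: 1, 1: 4}
    assert sum(s.histogram.values()) == 6
    assert sum(s.degrees) == 2 * 5


def test_assortativity_star_exact_minus_one():
    assert degree_stats(make_star(5)).assortativity == pytest.approx(-1.0)


def test_assortativity_path4_closed_form():
    # Pearson over the 6 orientation pairs of the 3 path edges
    assert degree_stats(graph(PATH4)).assortativity == pytest.approx(-0.5)


def test_assortativity_conventions():
    assert degree_stats(make_ring(6)).assortativity == 1.0  # regular: 0/0 -> 1
    assert degree_stats(nx.empty_graph(4)).assortativity is None


def test_betweenness_closed_forms():
    star = betweenness_normalized(make_star(5))
    assert star.values[0] == pytest.approx(1.0)
    assert star.values[1:] == pytest.approx((0, 0, 0, 0))
    assert betweenness_normalized(graph([(0, 1), (1, 2)])).values == pytest.approx(
        (0, 1, 0)
    )
    assert max(betweenness_normalized(make_complete(5)).values) == 0.0
    with pytest.raises(ValueError):
        betweenness_normalized(nx.empty_graph(2))


def test_closeness_closed_forms():
    assert closeness_normalized(make_complete(4)).values == pytest.approx((1,) * 4)
    star = closeness_normalized(make_star(5))
    assert star.values[0] == pytest.approx(1.0)
    assert star.values[1] == pytest.approx(4 / 7)  # leaf distance sum 1 + 2*3
    with pytest.raises(DisconnectedGraphError):
        closeness_normalized(graph([(0, 1)], n=4))


def test_closeness_component_scaled_policy():
    g = graph([(0, 1), (0, 2), (0, 3)], n=5)
    c = closeness_normalized(g, disconnected="component-scaled")
    assert c.values[0] == pytest.approx(3 / 4)  # (3/3) * (3/4)
    assert c.values[4] == 0.0


def test_eigenvector_closed_forms():
    assert eigenvector_centrality(make_complete(5)).values == pytest.approx(
        (1 / math.sqrt(5),) * 5
    )
    v = eigenvector_centrality(graph([(0, 1)], n=5)).values
    assert v == pytest.approx((2**-0.5, 2**-0.5, 0, 0, 0))
    star = eigenvector_centrality(make_star(5)).values
    assert star[0] == pytest.approx(2**-0.5)
    assert star[1] == pytest.approx(1 / (2 * math.sqrt(2)))


def test_spectral_summary():
    assert spectral_summary(nx.empty_graph(3)).natural_connectivity == pytest.approx(
        0.0
    )
    s = spectral_summary(make_complete(4))
    expected = math.log((math.e**3 + 3 / math.e) / 4)
    assert s.natural_connectivity == pytest.approx(expected)
    assert s.natural_connectivity == pytest.approx(s.complete_reference)
    assert sum(s.eigenvalues) == pytest.approx(0.0, abs=1e-9)  # trace zero
    edge = spectral_summary(graph([(0, 1)]))
    assert edge.natural_connectivity == pytest.approx(math.log(math.cosh(1)))


# ---------------------------------------------------------------------------
# the 11 measures: closed-form and printed values


@pytest.mark.parametrize(
    "fn,g,expected",
    [
        # assortativity-based hubness
        (abh, graph([(0, 1), (0, 2)], n=4), 1.0),
        (abh, make_ring(6), 0.0),
        (abh, graph(PATH4), 0.75),
        # eigenvector dispersion
        (ecd, make_complete(5), 0.0),
        (ecd, graph([(0, 1)], n=5), 0.75),  # closed form (n-2)/(n-1)
        (ecd, nx.empty_graph(4), 0.0),
        # betweenness centralization
        (nbc, graph(PRINTED), 0.82),
        (nbc, make_ring(10), 0.0),
        (nbc, graph([(0, 1), (1, 2)]), 1.0),
        # closeness centralization
        (ncc, make_star(7), 1.0),
        (ncc, make_complete(6), 0.0),
        (ncc, graph([(0, 1), (1, 2)]), 1.0),
        # degree centralization
        (ndc, graph(PRINTED), 0.7),
        (ndc, make_star(9), 1.0),
        # degree entropy
        (nde, make_ring(8), 0.0),
        (nde, nx.empty_graph(1), 0.0),
        # degree variance
        (ndv, make_star(5), 1.0),
        (ndv, make_star(7), 0.9375),  # (150/49)/(160/49)
        (ndv, make_ring(10), 0.0),
        # Gini
        (ngc, make_star(12), 0.5),
        (ngc, graph([(0, 1)], n=5), 1.0),
        (ngc, make_complete(6), 0.0),
        # hub dominance
        (nhd, make_star(8), 1.0),
        (nhd, make_complete(20), 1.0),
        (nhd, make_ring(21), 0.1),
        # hub formation tendency
        (nht, make_star(9), 1.0),
        (nht, make_complete(5), 8 / 11),
        (nht, graph([(0, 1)], n=5), 1.0),
        # natural connectivity
        (nnc, make_complete(6), 0.0),
        (nnc, nx.empty_graph(4), 0.0),
        (nnc, graph([(0, 1)]), 0.0),  # K2 is complete
    ],
)
def test_measure_values(fn, g, expected):
    assert fn(g).value == pytest.approx(expected, abs=1e-6)


def test_saturated_counterexample_values():
    # saturating node 3 of the rewired 6-star drops both path- and
    # degree-based centralization
    from netcentral import saturate

    y = saturate(graph(PRINTED), 3)
    assert nbc(y).value == pytest.approx(0.36)
    assert ndc(y).value == pytest.approx(0.6)


def test_nde_star10_two_bin_entropy():
    # oracle: direct two-bin entropy (1/10, 9/10) over ln 10
    expected = -(0.1 * math.log(0.1) + 0.9 * math.log(0.9)) / math.log(10)
    assert nde(make_star(10)).value == pytest.approx(expected, abs=1e-12)
    assert round(nde(make_star(10)).value, 5) == 0.14118


def test_ngc_star_half_for_any_order():
    for n in (3, 4, 7, 25):
        assert ngc(make_star(n)).value == pytest.approx(0.5, abs=1e-12)


def test_degenerate_conventions_flagged():
    assert abh(nx.empty_graph(1)).degenerate
    assert nnc(nx.empty_graph(4)).degenerate
    assert ndc(nx.empty_graph(2)).degenerate
    assert not ndc(make_star(4)).degenerate


def test_measure_all():
    vals = measure_all(make_star(6))
    assert set(vals) == set(MEASURE_IDS)
    assert vals["NDC"].value == pytest.approx(1.0)
    assert vals["NGC"].value == pytest.approx(0.5)
    ring = measure_all(make_ring(10), ("NBC", "NCC", "NDC"))
    assert all(v.value == pytest.approx(0.0) for v in ring.values())
    # NCC on a disconnected graph is an explicit undefined marker
    split = measure_all(graph([(0, 1), (2, 3)]), ("NCC",))
    assert math.isnan(split["NCC"].value)
    assert "disconnected" in split["NCC"].note
    with pytest.raises(KeyError):
        measure_all(make_star(4), ("XYZ",))


# ---------------------------------------------------------------------------
# independent oracles


def brute_betweenness(g):
    """Normalized betweenness by explicit shortest-path enumeration."""
    n = g.number_of_nodes()
    nodes = list(g.nodes())
    raw = dict.fromkeys(nodes, 0.0)
    for s, t in itertools.combinations(nodes, 2):
        try:
            paths = list(nx.all_shortest_paths(g, s, t))
        except nx.NetworkXNoPath:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            raw[v] += sum(v in p for p in paths) / len(paths)
    scale = (n - 1) * (n - 2) / 2
    return [raw[v] / scale for v in nodes]


def test_betweenness_matches_brute_force_enumeration():
    graphs = [g for g in enumerate_labeled_graphs(4)]
    rng = np.random.default_rng(7)
    for n in (5, 6):
        for _ in range(12):
            graphs.append(nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(2**31))))
    checked = 0
    for g in graphs:
        if g.number_of_nodes() < 3:
            continue
        got = betweenness_normalized(g).values
        assert got == pytest.approx(brute_betweenness(g), abs=1e-12)
        checked += 1
    assert checked > 60


def test_gini_matches_sorted_degree_formulation():
    # oracle: G = sum_i (2i - n - 1) d_(i) / (n^2 dbar), degrees ascending
    for g in enumerate_labeled_graphs(5):
        if g.number_of_edges() == 0 or g.number_of_nodes() < 3:
            continue
        d = np.sort([d for _, d in g.degree()])
        n = len(d)
        sorted_gini = float(
            np.sum((2 * np.arange(1, n + 1) - n - 1) * d) / (n**2 * d.mean())
        )
        assert ngc(g).value == pytest.approx(sorted_gini / ((n - 2) / n), abs=1e-12)


def test_eigenvector_matches_power_iteration():
    rng = np.random.default_rng(11)
    count = 0
    for n in (4, 5, 6):
        for _ in range(10):
            g = nx.gnp_random_graph(n, 0.6, seed=int(rng.integers(2**31)))
            if not nx.is_connected(g):
                continue
            oracle = nx.eigenvector_centrality(g, max_iter=10000, tol=1e-12)
            v = np.array([oracle[u] for u in g.nodes()])
            v /= np.linalg.norm(v)
            got = np.array(eigenvector_centrality(g).values)
            assert got == pytest.approx(v, abs=1e-6)
            count += 1
    assert count >= 15


@pytest.mark.parametrize("n", [3, 4, 5, 6])
def test_degree_variance_maximum_matches_brute_force(n):
    """dv_max(n) equals the exhaustive maximum over all labeled graphs."""
    pairs = list(itertools.combinations(range(n), 2))
    best = 0.0
    for mask in range(1 << len(pairs)):
        deg = [0] * n
        for i, (a, b) in enumerate(pairs):
            if mask >> i & 1:
                deg[a] += 1
                deg[b] += 1
        mean = sum(deg) / n
        best = max(best, sum((d - mean) ** 2 for d in deg) / n)
    assert best == pytest.approx(dv_max(n), abs=1e-12)


# ---------------------------------------------------------------------------
# properties: range and isomorphism invariance


def random_graph(draw_n, edge_bits):
    g = nx.Graph()
    g.add_nodes_from(range(draw_n))
    pairs = list(itertools.combinations(range(draw_n), 2))
    g.add_edges_from(p for i, p in enumerate(pairs) if edge_bits >> i & 1)
    return g


@settings(max_examples=120, derandomize=True)
@given(n=st.integers(1, 6), bits=st.integers(0, 2**15 - 1))
def test_measures_bounded_in_unit_interval(n, bits):
    g = random_graph(n, bits)
    for mid, mv in measure_all(g).items():
        if math.isnan(mv.value):  # NCC on disconnected input
            continue
        assert -1e-9 <= mv.value <= 1 + 1e-9, mid


@settings(max_examples=80, derandomize=True)
@given(
    n=st.integers(2, 6),
    bits=st.integers(0, 2**15 - 1),
    perm_seed=st.integers(0, 2**16),
)
def test_measures_isomorphism_invariant(n, bits, perm_seed):
    g = random_graph(n, bits)
    perm = dict(
        zip(range(n), np.random.default_rng(perm_seed).permutation(n).tolist())
    )
    h = relabel(g, perm)
    va, vb = measure_all(g), measure_all(h)
    for mid in MEASURE_IDS:
        if math.isnan(va[mid].value):
            assert math.isnan(vb[mid].value)
            continue
        assert va[mid].value == pytest.approx(vb[mid].value, abs=TOLERANCES[mid]), mid
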