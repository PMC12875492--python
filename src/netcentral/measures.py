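"""The 11 normalized centralization measures and their ingredients.

Every measure maps a simple undirected graph to a value in [0, 1]: 0 for
maximally homogeneous topologies (empty, complete, regular — depending on
the measure) and 1, or close to it, when a single hub dominates.  Each
measure divides a raw heterogeneity statistic by its maximum over graphs of
the same order, so values are comparable across network sizes.

Measure ids and definitions
---------------------------
ABH  assortativity-based hubness, (1 - r)/2 with r the degree assortativity
NBC  betweenness centralization, sum of (max - value) over normalized node
     betweenness, divided by n - 1 (the star-graph maximum)
NCC  closeness centralization, (2n-3) * sum(max - value) / ((n-1)(n-2))
NDC  degree centralization (Freeman), n(dmax - dbar) / ((n-1)(n-2))
ECD  variance of L2-normalized eigenvector centrality over (n-1)/n^2
NDE  Shannon entropy of the degree histogram over ln(n)
NDV  degree variance over its maximum DVmax(n) (star for n < 7, two-hub
     graph for n >= 7)
NGC  Gini coefficient of the degree sequence over its maximum (n-2)/n
NHD  hub dominance, dmax / (n-1)
NHT  hub formation tendency, (sum d^2 / sum d) / ((m+1)/2)
NNC  natural-connectivity centralization, (lmax - lbar)/lmax with lbar the
     log-mean-exp of the adjacency spectrum and lmax its complete-graph value

Degenerate graphs (too few nodes, no edges) are mapped to 0 by convention;
each returned :class:`MeasureValue` flags when such a convention fired.

Floating-point tolerance: comparisons against the boundary values 0 and 1
use 1e-9 for the rational-arithmetic measures and 1e-6 for the two
eigenvalue-based measures (ECD, NNC); see :data:`TOLERANCES`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.special import logsumexp

__all__ = [
    "MEASURE_IDS",
    "TOLERANCES",
    "CentralityVector",
    "DegreeStats",
    "DisconnectedGraphError",
    "MeasureValue",
    "SpectralSummary",
    "abh",
    "betweenness_normalized",
    "closeness_normalized",
    "degree_stats",
    "ecd",
    "eigenvector_centrality",
    "measure_all",
    "nbc",
    "ncc",
    "ndc",
    "nde",
    "ndv",
    "ngc",
    "nhd",
    "nht",
    "nnc",
    "spectral_summary",
]

MEASURE_IDS = (
    "ABH",
    "ECD",
    "NBC",
    "NCC",
    "NDC",
    "NDE",
    "NDV",
    "NGC",
    "NHD",
    "NHT",
    "NNC",
)

#: boundary-comparison tolerance per measure (eigen-based measures are looser)
TOLERANCES: dict[str, float] = {
    m: (1e-6 if m in ("ECD", "NNC") else 1e-9) for m in MEASURE_IDS
}


class DisconnectedGraphError(ValueError):
    """Raised when a distance-based quantity is requested on a disconnected
    graph without an explicit convention for unreachable pairs."""


@dataclass(frozen=True)
class DegreeStats:
    """Degree-sequence summary shared by the degree-based measures."""

    degrees: tuple[int, ...]
    dmax: int
    mean: float
    variance: float  # population variance
    histogram: dict[int, int]  # degree value -> node count, observed values only
    assortativity: float | None  # None when m = 0 (undefined)


@dataclass(frozen=True)
class CentralityVector:
    kind: str  # betweenness | closeness | eigenvector
    values: tuple[float, ...]
    max: float
    mean: float


@dataclass(frozen=True)
class SpectralSummary:
    eigenvalues: tuple[float, ...]
    natural_connectivity: float  # ln((1/n) sum exp(lambda_i))
    complete_reference: float  # same quantity for the complete graph on n nodes


@dataclass(frozen=True)
class MeasureValue:
    """One measure's normalized score with provenance metadata."""

    measure: str
    value: float
    degenerate: bool = False  # a small-n / m=0 convention fired
    note: str = ""

    def __float__(self) -> float:
        return self.value


def _adjacency(g: nx.Graph) -> np.ndarray:
    return nx.to_numpy_array(g, nodelist=list(g.nodes()))


def degree_stats(g: nx.Graph) -> DegreeStats:
    """Degree summary including the degree assortativity coefficient.

    Assortativity is the Pearson correlation of endpoint-degree pairs taken
    over both orientations of every edge.  For regular-endpoint graphs the
    correlation is 0/0; the convention here is r = 1 (a regular graph is
    perfectly assortative), which is what P1b compliance of ABH requires.
    For m = 0 the coefficient is undefined and reported as None.
    """
    deg = dict(g.degree())
    degrees = tuple(deg[v] for v in g.nodes())
    n = len(degrees)
    d = np.asarray(degrees, dtype=float)
    mean = float(d.mean()) if n else 0.0
    variance = float(np.mean((d - mean) ** 2)) if n else 0.0
    hist: dict[int, int] = {}
    for k in degrees:
        hist[k] = hist.get(k, 0) + 1
    if g.number_of_edges() == 0:
        r = None
    else:
        x = np.empty(2 * g.number_of_edges())
        y = np.empty_like(x)
        for i, (u, v) in enumerate(g.edges()):
            x[2 * i], y[2 * i] = deg[u], deg[v]
            x[2 * i + 1], y[2 * i + 1] = deg[v], deg[u]
        sx = x.std()
        if sx == 0.0:  # both marginals identical for undirected graphs
            r = 1.0
        else:
            r = float(np.dot(x - x.mean(), y - y.mean()) / (len(x) * sx * x.std()))
            r = min(1.0, max(-1.0, r))
    return DegreeStats(degrees, max(degrees, default=0), mean, variance, hist, r)


def betweenness_normalized(g: nx.Graph) -> CentralityVector:
    """Shortest-path betweenness divided by (n-1)(n-2)/2, endpoints excluded.

    Defined on disconnected graphs: pairs with no connecting path simply
    contribute nothing.
    """
    n = g.number_of_nodes()
    if n < 3:
        raise ValueError("betweenness_normalized: requires n >= 3")
    b = nx.betweenness_centrality(g, normalized=True)
    vals = tuple(b[v] for v in g.nodes())
    return CentralityVector("betweenness", vals, max(vals), sum(vals) / n)


def closeness_normalized(
    g: nx.Graph, *, disconnected: str = "raise"
) -> CentralityVector:
    """Closeness centrality C(i) = (n-1) / sum_j dist(i, j).

    ``disconnected`` policy:

    - ``"raise"`` (default): a disconnected input signals
      :class:`DisconnectedGraphError`; extract the largest component first.
    - ``"component-scaled"``: the Wasserman–Faust convention — closeness is
      computed within each node's component and scaled by
      (component size - 1)/(n - 1); isolated nodes get 0.  On connected
      graphs both policies coincide.
    """
    n = g.number_of_nodes()
    if n < 3:
        raise ValueError("closeness_normalized: requires n >= 3")
    if disconnected not in ("raise", "component-scaled"):
        raise ValueError(f"unknown disconnected policy {disconnected!r}")
    if disconnected == "raise" and not nx.is_connected(g):
        raise DisconnectedGraphError(
            "closeness is undefined on disconnected graphs; "
            "use largest_component() or disconnected='component-scaled'"
        )
    c = nx.closeness_centrality(g, wf_improved=True)
    vals = tuple(c[v] for v in g.nodes())
    return CentralityVector("closeness", vals, max(vals), sum(vals) / n)


def eigenvector_centrality(g: nx.Graph) -> CentralityVector:
    """Principal adjacency eigenvector, entrywise nonnegative, L2 norm 1.

    Computed by full symmetric eigendecomposition.  When the spectral radius
    is attained in several components the deterministic eigensolver output is
    post-processed entrywise to be nonnegative (component blocks have
    disjoint support, so the absolute value is still a unit eigenvector).
    """
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("eigenvector_centrality: requires n >= 2")
    if g.number_of_edges() == 0:
        raise ValueError("eigenvector_centrality: no spectrum for an empty graph")
    _, vecs = np.linalg.eigh(_adjacency(g))
    v = np.abs(vecs[:, -1])
    v[v < 1e-12] = 0.0
    v /= np.linalg.norm(v)
    vals = tuple(float(x) for x in v)
    return CentralityVector("eigenvector", vals, max(vals), sum(vals) / n)


def spectral_summary(g: nx.Graph) -> SpectralSummary:
    """Adjacency spectrum and natural connectivity via stable log-sum-exp.

    The complete-graph reference is ln((e^(n-1) + (n-1)e^-1)/n), the natural
    connectivity of K_n (spectrum {n-1} + {-1 repeated n-1 times}).
    """
    n = g.number_of_nodes()
    if n < 1:
        raise ValueError("spectral_summary: requires n >= 1")
    lam = np.linalg.eigvalsh(_adjacency(g))
    nat = float(logsumexp(lam) - math.log(n))
    if n == 1:
        ref = 0.0
    else:
        ref = float(logsumexp([n - 1.0, -1.0 + math.log(n - 1)]) - math.log(n))
    return SpectralSummary(tuple(float(x) for x in lam), nat, ref)


def _clip01(x: float) -> float:
    return float(min(1.0, max(0.0, x)))


def _value(measure: str, value: float) -> MeasureValue:
    return MeasureValue(measure, _clip01(value))


def _degenerate(measure: str, note: str) -> MeasureValue:
    return MeasureValue(measure, 0.0, degenerate=True, note=note)


def abh(g: nx.Graph) -> MeasureValue:
    """Assortativity-based hubness (1 - r)/2; 0 for n < 2 or m = 0.

    Stars have r = -1 exactly (ABH = 1); regular graphs have r = 1 by the
    zero-variance convention (ABH = 0).
    """
    if g.number_of_nodes() < 2 or g.number_of_edges() == 0:
        return _degenerate("ABH", "n < 2 or m = 0")
    r = degree_stats(g).assortativity
    return _value("ABH", (1.0 - r) / 2.0)


def ecd(g: nx.Graph) -> MeasureValue:
    """Eigenvector-centrality dispersion; 0 for n < 2 and for m = 0.

    Numerator: population variance of the L2-normalized principal
    eigenvector.  Denominator: its supremum (n-1)/n^2 over graphs of order
    n, approached (not attained) by one-edge graphs with isolated nodes.
    """
    n = g.number_of_nodes()
    if n < 2:
        return _degenerate("ECD", "n < 2")
    if g.number_of_edges() == 0:
        return _degenerate("ECD", "m = 0: no principal eigenvector")
    v = np.asarray(eigenvector_centrality(g).values)
    num = float(np.mean((v - v.mean()) ** 2))
    return _value("ECD", num / ((n - 1) / n**2))


def nbc(g: nx.Graph) -> MeasureValue:
    """Normalized betweenness centralization; 0 for n < 3."""
    n = g.number_of_nodes()
    if n < 3:
        return _degenerate("NBC", "n < 3")
    c = betweenness_normalized(g)
    return _value("NBC", sum(c.max - x for x in c.values) / (n - 1))


def ncc(g: nx.Graph, *, disconnected: str = "raise") -> MeasureValue:
    """Normalized closeness centralization; 0 for n < 3.

    Requires a connected graph by default; see
    :func:`closeness_normalized` for the ``disconnected`` policies.
    """
    n = g.number_of_nodes()
    if n < 3:
        return _degenerate("NCC", "n < 3")
    c = closeness_normalized(g, disconnected=disconnected)
    return _value(
        "NCC", (2 * n - 3) * sum(c.max - x for x in c.values) / ((n - 1) * (n - 2))
    )


def ndc(g: nx.Graph) -> MeasureValue:
    """Normalized degree (Freeman) centralization; 0 for n < 3."""
    n = g.number_of_nodes()
    if n < 3:
        return _degenerate("NDC", "n < 3")
    s = degree_stats(g)
    return _value("NDC", n * (s.dmax - s.mean) / ((n - 1) * (n - 2)))


def nde(g: nx.Graph) -> MeasureValue:
    """Normalized degree entropy; 0 for n < 2.

    Shannon entropy of the degree histogram over observed degree values
    (0*ln 0 := 0), normalized by ln(n).
    """
    n = g.number_of_nodes()
    if n < 2:
        return _degenerate("NDE", "n < 2")
    h = 0.0
    for count in degree_stats(g).histogram.values():
        p = count / n
        h -= p * math.log(p)
    return _value("NDE", h / math.log(n))


def dv_max(n: int) -> float:
    """Maximum population degree variance over graphs of order ``n >= 3``.

    Attained by the star for n < 7 and by the two-hub graph (two mutually
    adjacent nodes linked to all others) for n >= 7.
    """
    return max(
        (n - 1) * (n - 2) ** 2 / n**2,
        ((2 * n**3 - 6 * n) - (4 * n - 6) ** 2) / n**2,
    )


def ndv(g: nx.Graph) -> MeasureValue:
    """Normalized degree variance; 0 for n < 3."""
    n = g.number_of_nodes()
    if n < 3:
        return _degenerate("NDV", "n < 3")
    return _value("NDV", degree_stats(g).variance / dv_max(n))


def ngc(g: nx.Graph) -> MeasureValue:
    """Normalized Gini coefficient of the degree sequence; 0 for n < 3 or m = 0.

    Raw Gini: sum_ij |d_i - d_j| / (2 n^2 dbar); maximum (n-2)/n is attained
    by the one-edge graph with n-2 isolated nodes.
    """
    n = g.number_of_nodes()
    if n < 3:
        return _degenerate("NGC", "n < 3")
    if g.number_of_edges() == 0:
        return _degenerate("NGC", "m = 0: zero mean degree")
    d = np.asarray(degree_stats(g).degrees, dtype=float)
    gini = float(np.abs(d[:, None] - d[None, :]).sum()) / (2 * n**2 * d.mean())
    return _value("NGC", gini / ((n - 2) / n))


def nhd(g: nx.Graph) -> MeasureValue:
    """Normalized hub dominance dmax/(n-1); 0 for n < 2 or m = 0."""
    n = g.number_of_nodes()
    if n < 2 or g.number_of_edges() == 0:
        return _degenerate("NHD", "n < 2 or m = 0")
    return _value("NHD", degree_stats(g).dmax / (n - 1))


def nht(g: nx.Graph) -> MeasureValue:
    """Normalized hub-formation tendency; 0 for n < 2 or m = 0.

    Raw statistic: sum d^2 / sum d; its maximum over graphs with m edges is
    (m+1)/2, attained by the star with m = n - 1.
    """
    if g.number_of_nodes() < 2 or g.number_of_edges() == 0:
        return _degenerate("NHT", "n < 2 or m = 0")
    d = np.asarray(degree_stats(g).degrees, dtype=float)
    m = g.number_of_edges()
    return _value("NHT", (float((d**2).sum()) / float(d.sum())) / ((m + 1) / 2))


def nnc(g: nx.Graph) -> MeasureValue:
    """Normalized natural-connectivity centralization; 0 for m = 0.

    (lmax - lbar)/lmax with lbar the graph's natural connectivity and lmax
    that of the complete graph on the same n, so NNC is exactly 0 on K_n.
    """
    if g.number_of_edges() == 0:
        return _degenerate("NNC", "m = 0")
    s = spectral_summary(g)
    return _value(
        "NNC", (s.complete_reference - s.natural_connectivity) / s.complete_reference
    )


_MEASURES = {
    "ABH": abh,
    "ECD": ecd,
    "NBC": nbc,
    "NCC": ncc,
    "NDC": ndc,
    "NDE": nde,
    "NDV": ndv,
    "NGC": ngc,
    "NHD": nhd,
    "NHT": nht,
    "NNC": nnc,
}


def measure_all(
    g: nx.Graph, measure_ids: tuple[str, ...] | list[str] | None = None
) -> dict[str, MeasureValue]:
    """Apply each requested measure to ``g``.

    NCC on a disconnected graph is reported as an explicit NaN-valued
    "undefined" entry rather than silently skipped; callers that want a
    number should extract the largest component first.
    """
    ids = MEASURE_IDS if measure_ids is None else tuple(measure_ids)
    unknown = set(ids) - set(MEASURE_IDS)
    if unknown:
        raise KeyError(f"unknown measure ids: {sorted(unknown)}")
    out: dict[str, MeasureValue] = {}
    for mid in ids:
        try:
            out[mid] = _MEASURES[mid](g)
        except DisconnectedGraphError:
            out[mid] = MeasureValue(
                mid, math.nan, degenerate=True, note="undefined on disconnected input"
            )
    return out
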