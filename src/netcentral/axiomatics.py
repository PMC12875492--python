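"""Postulate battery: six axioms of centralization, counterexamples, compliance matrix.

The six postulates (P1–P6) pin down what any normalized centralization
measure C should do on extremal inputs:

P1a  single-node graph: C = 0
P1b  complete graph: C = 0
P1c  edgeless graph: C = 0
P2   star graph: C = 1
P3   isomorphic graphs get equal values
P4   without a saturated node (degree n-1), C < 1
P5   if a saturated node already exists, saturating another node never
     increases C (the existing hub becomes less unique)
P6   if no saturated node exists, saturating one never decreases C (the new
     hub becomes dominant)

"Satisfied" is operational: no violation found over the scan corpus plus
the registry of known counterexamples.  Universal satisfaction is not
decidable by testing; the check marks in the compliance matrix therefore
mean "no counterexample known", exactly as in the literature where they
rest on proofs.  Violations, by contrast, are constructive: every
``violated`` verdict carries a witness graph that reproduces it — except
the single ``asserted-violated`` entry (ECD under P4), where the measure's
supremum is approached but not attained at any finite order, so no finite
witness exists (ECD on the one-edge graph with n-2 isolated nodes equals
(n-2)/(n-1), increasing toward 1).

The default scan corpus is every *connected* labeled graph on up to 5
nodes.  The postulate framework, like the evaluation it supports, is scoped
to connected networks; the registry carries the known disconnected
counterexamples.  Scanning disconnected graphs as well
(``include_disconnected=True``) turns up additional P4 violations — e.g.
NHT = 1 on a one-edge graph with isolated nodes, and NDV = 1 on K4 plus an
isolated node — that the connected-scope matrix does not record.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .graph_core import enumerate_labeled_graphs, is_saturated, relabel, saturate
from .graph_core import make_complete, make_star
from .measures import MEASURE_IDS, TOLERANCES, _MEASURES, ncc

__all__ = [
    "AXIOM_IDS",
    "AxiomVerdict",
    "AxiomVerdictMatrix",
    "CounterexampleEntry",
    "CounterexampleRegistry",
    "axiom_corpus",
    "builtin_counterexamples",
    "check_p1",
    "check_p2",
    "check_p3",
    "check_p4",
    "check_p5",
    "check_p6",
    "clear_cache",
    "run_axiom_battery",
]

AXIOM_IDS = ("P1a", "P1b", "P1c", "P2", "P3", "P4", "P5", "P6")
#: the six axioms as counted in the compliance matrix (P1 = P1a & P1b & P1c)
AXIOM_GROUPS = ("P1", "P2", "P3", "P4", "P5", "P6")

SATISFIED = "satisfied-in-corpus"
VIOLATED = "violated"
ASSERTED = "asserted-violated"


@dataclass(frozen=True)
class AxiomVerdict:
    measure: str
    axiom: str
    status: str
    witness: tuple[tuple[int, int], ...] | None = None
    witness_n: int | None = None
    saturation_node: int | None = None
    detail: str = ""

    @property
    def violated(self) -> bool:
        return self.status in (VIOLATED, ASSERTED)


@dataclass(frozen=True)
class CounterexampleEntry:
    measure: str
    axiom: str  # P4, P5 or P6
    edges: tuple[tuple[int, int], ...]
    n: int
    saturation_node: int | None = None  # preferred node for P5/P6
    asserted: bool = False  # no finite witness exists; violation by supremum argument
    note: str = ""

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        g.add_edges_from(self.edges)
        return g


@dataclass
class CounterexampleRegistry:
    entries: list[CounterexampleEntry] = field(default_factory=list)

    def for_measure(self, measure: str) -> list[CounterexampleEntry]:
        return [e for e in self.entries if e.measure == measure]


@dataclass
class AxiomVerdictMatrix:
    """measures x axioms grid with per-measure satisfied counts."""

    verdicts: dict[tuple[str, str], AxiomVerdict]
    measures: tuple[str, ...]

    def verdict(self, measure: str, axiom: str) -> AxiomVerdict:
        return self.verdicts[(measure, axiom)]

    def group_satisfied(self, measure: str, group: str) -> bool:
        parts = ("P1a", "P1b", "P1c") if group == "P1" else (group,)
        return all(not self.verdicts[(measure, p)].violated for p in parts)

    @property
    def satisfied_counts(self) -> dict[str, int]:
        return {
            m: sum(self.group_satisfied(m, g) for g in AXIOM_GROUPS)
            for m in self.measures
        }

    def to_dataframe(self):
        """Compliance grid as a pandas DataFrame (rows = measures)."""
        import pandas as pd

        rows = {}
        for m in self.measures:
            row = {
                g: ("✓" if self.group_satisfied(m, g) else "✗")
                for g in AXIOM_GROUPS
            }
            row["# Satisfied"] = self.satisfied_counts[m]
            rows[m] = row
        return pd.DataFrame.from_dict(rows, orient="index")

    def to_json_dict(self) -> dict:
        return {
            "axioms": list(AXIOM_GROUPS),
            "satisfied_counts": self.satisfied_counts,
            "verdicts": [
                {
                    "measure": v.measure,
                    "axiom": v.axiom,
                    "status": v.status,
                    "witness_edges": list(map(list, v.witness)) if v.witness else None,
                    "witness_n": v.witness_n,
                    "saturation_node": v.saturation_node,
                    "detail": v.detail,
                }
                for v in self.verdicts.values()
            ],
        }


# ---------------------------------------------------------------------------
# cached evaluation

_CACHE: dict[tuple, dict[str, float]] = {}


def clear_cache() -> None:
    _CACHE.clear()


def _key(g: nx.Graph) -> tuple:
    return (g.number_of_nodes(), frozenset(frozenset(e) for e in g.edges()))


def _values(g: nx.Graph) -> dict[str, float]:
    """All 11 measure values for ``g``, cached by edge set.

    NCC uses the component-scaled closeness convention so that the battery
    and the registry can evaluate it on disconnected witnesses; on connected
    graphs this coincides with the standard definition.
    """
    k = _key(g)
    out = _CACHE.get(k)
    if out is None:
        out = {}
        for mid in MEASURE_IDS:
            if mid == "NCC":
                out[mid] = ncc(g, disconnected="component-scaled").value
            else:
                out[mid] = _MEASURES[mid](g).value
        _CACHE[k] = out
    return out


def _edges(g: nx.Graph) -> tuple[tuple[int, int], ...]:
    return tuple(sorted(tuple(sorted(e)) for e in g.edges()))


# ---------------------------------------------------------------------------
# corpus

def axiom_corpus(max_n: int = 5, *, include_disconnected: bool = False) -> list[nx.Graph]:
    """All labeled graphs on 1..max_n nodes used by the P3–P6 scans.

    By default only connected graphs are scanned (772 graphs for
    ``max_n=5``); the registry supplies the known disconnected witnesses.
    """
    if not 1 <= max_n <= 6:
        raise ValueError("axiom_corpus: 1 <= max_n <= 6")
    corpus = []
    for n in range(1, max_n + 1):
        for g in enumerate_labeled_graphs(n):
            if include_disconnected or n == 1 or nx.is_connected(g):
                corpus.append(g)
    return corpus


# ---------------------------------------------------------------------------
# individual checks

def _sat_split(g: nx.Graph) -> tuple[list, list]:
    n = g.number_of_nodes()
    sat = [v for v in g.nodes() if g.degree(v) == n - 1]
    unsat = [v for v in g.nodes() if g.degree(v) < n - 1]
    return sat, unsat


def check_p1(measure: str) -> dict[str, AxiomVerdict]:
    """P1a/P1b/P1c: zero on the 1-node graph, complete graphs n=2..8 and
    empty graphs n=1..8."""
    tol = TOLERANCES[measure]
    out: dict[str, AxiomVerdict] = {}

    single = nx.empty_graph(1)
    if abs(_values(single)[measure]) > tol:
        out["P1a"] = AxiomVerdict(measure, "P1a", VIOLATED, _edges(single), 1)
    else:
        out["P1a"] = AxiomVerdict(measure, "P1a", SATISFIED)

    out["P1b"] = AxiomVerdict(measure, "P1b", SATISFIED)
    for n in range(2, 9):
        g = make_complete(n)
        if abs(_values(g)[measure]) > tol:
            out["P1b"] = AxiomVerdict(
                measure, "P1b", VIOLATED, _edges(g), n,
                detail=f"complete graph n={n} gives {_values(g)[measure]:.6g}",
            )
            break

    out["P1c"] = AxiomVerdict(measure, "P1c", SATISFIED)
    for n in range(1, 9):
        g = nx.empty_graph(n)
        if abs(_values(g)[measure]) > tol:
            out["P1c"] = AxiomVerdict(measure, "P1c", VIOLATED, _edges(g), n)
            break
    return out


def check_p2(measure: str) -> AxiomVerdict:
    """P2: exactly 1 on stars n=3..10 (crosses the NDV normalizer switch at n=7)."""
    tol = TOLERANCES[measure]
    for n in range(3, 11):
        g = make_star(n)
        v = _values(g)[measure]
        if abs(v - 1.0) > tol:
            return AxiomVerdict(
                measure, "P2", VIOLATED, _edges(g), n,
                detail=f"star n={n} gives {v:.6g}",
            )
    return AxiomVerdict(measure, "P2", SATISFIED)


def check_p3(measure: str, corpus: list[nx.Graph], seed: int = 0) -> AxiomVerdict:
    """P3: invariance under 5 seeded random relabelings per corpus graph."""
    tol = TOLERANCES[measure]
    rng = np.random.default_rng(seed)
    for g in corpus:
        v0 = _values(g)[measure]
        nodes = list(g.nodes())
        for _ in range(5):
            perm = dict(zip(nodes, rng.permutation(nodes)))
            h = relabel(g, perm)
            if abs(_values(h)[measure] - v0) > tol:
                return AxiomVerdict(
                    measure, "P3", VIOLATED, _edges(g), g.number_of_nodes()
                )
    return AxiomVerdict(measure, "P3", SATISFIED)


def check_p4(measure: str, corpus: list[nx.Graph]) -> AxiomVerdict:
    """P4: value < 1 on every corpus graph lacking a saturated node."""
    tol = TOLERANCES[measure]
    for g in corpus:
        sat, _ = _sat_split(g)
        if sat or g.number_of_nodes() < 2:
            continue
        v = _values(g)[measure]
        if v >= 1.0 - tol:
            return AxiomVerdict(
                measure, "P4", VIOLATED, _edges(g), g.number_of_nodes(),
                detail=f"value {v:.6g} without a saturated node",
            )
    return AxiomVerdict(measure, "P4", SATISFIED)


def check_p5(measure: str, corpus: list[nx.Graph]) -> AxiomVerdict:
    """P5: with a saturated node present, saturating another node never
    increases the value."""
    tol = TOLERANCES[measure]
    for g in corpus:
        sat, unsat = _sat_split(g)
        if not sat or not unsat:
            continue
        vg = _values(g)[measure]
        for v in unsat:
            y = saturate(g, v)
            if _values(y)[measure] > vg + tol:
                return AxiomVerdict(
                    measure, "P5", VIOLATED, _edges(g), g.number_of_nodes(), v,
                    detail=f"{vg:.6g} -> {_values(y)[measure]:.6g}",
                )
    return AxiomVerdict(measure, "P5", SATISFIED)


def check_p6(measure: str, corpus: list[nx.Graph]) -> AxiomVerdict:
    """P6: with no saturated node, saturating a node never decreases the value."""
    tol = TOLERANCES[measure]
    for g in corpus:
        sat, unsat = _sat_split(g)
        if sat or g.number_of_nodes() < 2:
            continue
        vg = _values(g)[measure]
        for v in unsat:
            y = saturate(g, v)
            if _values(y)[measure] < vg - tol:
                return AxiomVerdict(
                    measure, "P6", VIOLATED, _edges(g), g.number_of_nodes(), v,
                    detail=f"{vg:.6g} -> {_values(y)[measure]:.6g}",
                )
    return AxiomVerdict(measure, "P6", SATISFIED)


# ---------------------------------------------------------------------------
# registry

def builtin_counterexamples() -> CounterexampleRegistry:
    """Registry of the known counterexample graphs, one per violated cell
    whose witness lies outside the default connected scan corpus (plus the
    printed witnesses that also happen to lie inside it)."""
    E = CounterexampleEntry
    star7_plus = tuple(sorted((0, i) for i in range(1, 7))) + ((1, 2),)
    k5_minus = tuple(
        sorted(
            (i, j)
            for i in range(5)
            for j in range(i + 1, 5)
            if (i, j) not in ((0, 1), (2, 3))
        )
    )
    entries = [
        E("ABH", "P4", ((0, 1), (0, 2)), 4,
          note="two edges on one endpoint + isolated node: r = -1, ABH = 1"),
        E("ABH", "P5", ((0, 1), (0, 2), (0, 3), (0, 4), (2, 3), (3, 4)), 5),
        E("ABH", "P6", ((0, 1), (0, 2)), 5,
          note="two edges on one endpoint + 2 isolated nodes"),
        E("ECD", "P4", (), 0, asserted=True,
          note="supremum only: ECD(one-edge graph on n nodes) = (n-2)/(n-1) "
               "increases toward 1 but no finite graph attains it"),
        E("ECD", "P5", ((0, 3), (0, 4), (0, 2), (1, 3), (1, 2), (1, 4), (2, 3), (3, 4)), 5),
        E("ECD", "P6", ((0, 1), (1, 2), (2, 3)), 5),
        E("NBC", "P6", ((0, 1), (0, 3), (0, 4), (0, 5), (1, 2)), 6, 3,
          note="NBC 0.82 -> 0.36 after saturating node 3"),
        E("NCC", "P6", ((0, 1), (0, 2), (0, 3)), 5),
        E("NDC", "P6", ((0, 1), (0, 3), (0, 4), (0, 5), (1, 2)), 6, 3,
          note="NDC 0.7 -> 0.6 after saturating node 3"),
        E("NDE", "P5", ((0, 3), (0, 2), (1, 3), (1, 4), (2, 3), (3, 4)), 5),
        E("NDE", "P6", ((0, 1),), 5, note="one-edge graph with isolated nodes"),
        E("NDV", "P5", star7_plus, 7,
          note="star on 7 nodes plus edge (1,2); saturating node 1 yields the "
               "two-hub variance maximizer"),
        E("NDV", "P6", ((0, 1), (0, 2), (1, 3), (1, 4)), 5),
        E("NGC", "P4", ((0, 1),), 5,
          note="one-edge graph with isolated nodes attains NGC = 1"),
        E("NGC", "P5", k5_minus, 5, note="degree sequence {3,3,3,3,4}"),
        E("NGC", "P6", ((0, 1),), 5),
        E("NHT", "P5", ((0, 1), (0, 3), (0, 2), (1, 2), (1, 3), (1, 4), (2, 4), (3, 4)), 5),
        E("NHT", "P6", ((0, 1),), 5),
    ]
    return CounterexampleRegistry(entries)


class RegistryError(RuntimeError):
    """A registry entry failed to reproduce its claimed violation."""


def evaluate_entry(entry: CounterexampleEntry) -> AxiomVerdict:
    """Re-check a registry entry and return the violated verdict it encodes.

    Raises :class:`RegistryError` if the claimed violation does not
    reproduce — registry entries must be constructive (except asserted ones).
    """
    if entry.asserted:
        return AxiomVerdict(entry.measure, entry.axiom, ASSERTED, detail=entry.note)
    g = entry.graph()
    tol = TOLERANCES[entry.measure]
    vg = _values(g)[entry.measure]
    sat, unsat = _sat_split(g)
    if entry.axiom == "P4":
        if sat:
            raise RegistryError(f"{entry}: P4 witness has a saturated node")
        if vg < 1.0 - tol:
            raise RegistryError(f"{entry}: value {vg} below 1")
        return AxiomVerdict(
            entry.measure, "P4", VIOLATED, entry.edges, entry.n, detail=entry.note
        )
    if entry.axiom == "P5" and (not sat or not unsat):
        raise RegistryError(f"{entry}: P5 witness needs saturated and non-saturated nodes")
    if entry.axiom == "P6" and sat:
        raise RegistryError(f"{entry}: P6 witness must have no saturated node")
    candidates = (
        [entry.saturation_node]
        if entry.saturation_node is not None
        else (unsat if entry.axiom == "P5" else list(g.nodes()))
    )
    for v in candidates:
        vy = _values(saturate(g, v))[entry.measure]
        if entry.axiom == "P5" and vy > vg + tol:
            return AxiomVerdict(
                entry.measure, "P5", VIOLATED, entry.edges, entry.n, v,
                detail=f"{vg:.6g} -> {vy:.6g}",
            )
        if entry.axiom == "P6" and vy < vg - tol:
            return AxiomVerdict(
                entry.measure, "P6", VIOLATED, entry.edges, entry.n, v,
                detail=f"{vg:.6g} -> {vy:.6g}",
            )
    raise RegistryError(f"{entry}: no saturation reproduces the violation")


# ---------------------------------------------------------------------------
# battery

def run_axiom_battery(
    measure_ids: tuple[str, ...] | None = None,
    corpus: list[nx.Graph] | None = None,
    registry: CounterexampleRegistry | None = None,
    seed: int = 0,
) -> AxiomVerdictMatrix:
    """Full P1–P6 scan for every measure, merged with the registry.

    A registry violation overrides a satisfied-in-corpus verdict (the corpus
    cannot see witnesses outside it, e.g. disconnected or larger graphs); it
    never overrides a violation the corpus already found.
    """
    ids = tuple(measure_ids) if measure_ids is not None else MEASURE_IDS
    if corpus is None:
        corpus = axiom_corpus()
    if not corpus:
        raise ValueError("run_axiom_battery: corpus must be nonempty")
    if registry is None:
        registry = builtin_counterexamples()

    verdicts: dict[tuple[str, str], AxiomVerdict] = {}
    for m in ids:
        verdicts.update({(m, a): v for a, v in check_p1(m).items()})
        verdicts[(m, "P2")] = check_p2(m)
        verdicts[(m, "P3")] = check_p3(m, corpus, seed)
        verdicts[(m, "P4")] = check_p4(m, corpus)
        verdicts[(m, "P5")] = check_p5(m, corpus)
        verdicts[(m, "P6")] = check_p6(m, corpus)

    for entry in registry.entries:
        if entry.measure not in ids:
            continue
        key = (entry.measure, entry.axiom)
        if not verdicts[key].violated:
            verdicts[key] = evaluate_entry(entry)

    return AxiomVerdictMatrix(verdicts, ids)
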