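"""File I/O, run configuration, and the real-network triplet pipeline.

The primary on-disk format is a whitespace-delimited edge list: one edge
per line (two tokens), '#' comment lines ignored, and single-token lines
declaring isolated nodes.  GML and GraphML are accepted through networkx.

The triplet pipeline computes the three best-performing centralization
measures — NBC, NCC, NDC — together with a degree summary.  Path-based
measures are undefined on disconnected graphs, so a disconnected input is
reduced to its largest connected component first and the report says so.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import yaml

from .graph_core import largest_component
from .measures import MEASURE_IDS, degree_stats, measure_all

log = logging.getLogger("netcentral")

__all__ = [
    "GraphFormatError",
    "RunConfig",
    "TripletReport",
    "read_graph",
    "triplet_report",
    "write_edge_list",
]


class GraphFormatError(ValueError):
    """Unparseable graph input; carries the offending line number."""


def _simplify(g: nx.Graph, origin: str) -> nx.Graph:
    loops = list(nx.selfloop_edges(g))
    if loops:
        log.warning("%s: dropped %d self-loop(s)", origin, len(loops))
        g.remove_edges_from(loops)
    return g


def read_edge_list(path: str | Path) -> nx.Graph:
    """Read the whitespace edge-list format described in the module docstring."""
    g = nx.Graph()
    seen = set()
    dup = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) == 1:
                g.add_node(tokens[0])
            elif len(tokens) == 2:
                key = frozenset(tokens)
                if key in seen or tokens[0] == tokens[1]:
                    dup += 1
                else:
                    seen.add(key)
                g.add_edge(*tokens)
            else:
                raise GraphFormatError(
                    f"{path}:{lineno}: expected 1 or 2 tokens, got {len(tokens)}"
                )
    if dup:
        log.warning("%s: ignored %d duplicate edge/self-loop line(s)", path, dup)
    return _simplify(g, str(path))


def read_graph(path: str | Path, fmt: str = "edgelist") -> nx.Graph:
    """Read a simple undirected graph; ``fmt`` in {edgelist, gml, graphml}.

    Duplicate edges and self-loops are dropped with a logged warning; node
    labels are preserved as read.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "edgelist":
        return read_edge_list(path)
    if fmt == "gml":
        return _simplify(nx.Graph(nx.read_gml(path, label="id")), str(path))
    if fmt == "graphml":
        return _simplify(nx.Graph(nx.read_graphml(path)), str(path))
    raise ValueError(f"unknown format {fmt!r}; expected edgelist, gml or graphml")


def write_edge_list(g: nx.Graph, path: str | Path) -> None:
    """Write a graph in the primary edge-list format (isolated nodes as
    single-token lines)."""
    with open(path, "w") as fh:
        for u, v in g.edges():
            fh.write(f"{u} {v}\n")
        for v in g.nodes():
            if g.degree(v) == 0:
                fh.write(f"{v}\n")


@dataclass
class RunConfig:
    """All tunables of the two batteries; defaults run with zero configuration."""

    measures: tuple[str, ...] = MEASURE_IDS
    w_axiomatic: float = 0.5
    w_numerical: float = 0.5
    n_grid: tuple[int, ...] = (5, 10, 20, 50, 100, 200)
    theta_high: float = 0.9
    theta_low: float = 0.05
    corpus_max_n: int = 5
    include_disconnected: bool = False
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["measures"] = list(self.measures)
        d["n_grid"] = list(self.n_grid)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "measures" in d:
            d["measures"] = tuple(d["measures"])
        if "n_grid" in d:
            d["n_grid"] = tuple(d["n_grid"])
        return cls(**d)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        """Load YAML (JSON is a YAML subset, so both parse)."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def dump(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class TripletReport:
    """Per-graph NBC/NCC/NDC values with a degree summary."""

    name: str
    n: int
    m: int
    dmin: int
    dmean: float
    dmax: int
    lcc_size: int
    used_lcc: bool
    nbc: float
    ncc: float
    ndc: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def triplet_report(g: nx.Graph, name: str = "") -> TripletReport:
    """Compute the NBC/NCC/NDC triplet, reducing to the LCC when needed."""
    n, m = g.number_of_nodes(), g.number_of_edges()
    stats = degree_stats(g)
    lcc = largest_component(g)
    used_lcc = lcc.number_of_nodes() < n
    if used_lcc:
        log.info(
            "%s: disconnected input, using largest component (%d of %d nodes)",
            name or "graph", lcc.number_of_nodes(), n,
        )
    vals = measure_all(lcc, ("NBC", "NCC", "NDC"))
    return TripletReport(
        name=name,
        n=n,
        m=m,
        dmin=min(stats.degrees, default=0),
        dmean=stats.mean,
        dmax=stats.dmax,
        lcc_size=lcc.number_of_nodes(),
        used_lcc=used_lcc,
        nbc=vals["NBC"].value,
        ncc=vals["NCC"].value,
        ndc=vals["NDC"].value,
    )


def dump_json(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2)
        fh.write("\n")
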