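"""Reading and writing social networks.

Three interchange formats are supported:

* **edge list + membership table** — an edge file with one edge per row
  (whitespace or comma separated) and a CSV membership table
  ``vertex,labels`` where ``labels`` is a ``;``-separated list (an empty
  field means the vertex belongs to no community);
* **GraphML** — via :mod:`networkx`, with community membership in a
  ``communities`` string vertex attribute (``;``-separated);
* **JSON** — a dict mirroring the :class:`~netintervene.network.SocialNetwork`
  fields exactly.
"""

from __future__ import annotations

import csv
import json
import warnings
from pathlib import Path
from typing import Iterable, Tuple, Union

import networkx as nx

from .network import Graph, SocialNetwork, canonical_edge

__all__ = [
    "read_network",
    "write_network",
    "network_to_json",
    "network_from_json",
    "read_graphml",
    "write_graphml",
]

PathLike = Union[str, Path]


class FormatError(ValueError):
    """A malformed row in an edge-list or membership file."""


def _split_row(line: str) -> list:
    if "," in line:
        return [f.strip() for f in line.split(",")]
    return line.split()


def _read_edge_rows(path: PathLike) -> Iterable[Tuple[int, str, str]]:
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = _split_row(line)
            if len(fields) != 2 or not all(fields):
                raise FormatError(
                    f"{path}: line {lineno}: expected two vertex fields, got {line!r}"
                )
            yield lineno, fields[0], fields[1]


def _read_membership_rows(path: PathLike):
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if row[0].lstrip().startswith("#"):
                continue
            if row[0].strip().lower() == "vertex":  # header
                continue
            if len(row) not in (1, 2) or not row[0].strip():
                raise FormatError(
                    f"{path}: line {lineno}: expected 'vertex,labels', got {row!r}"
                )
            vertex = row[0].strip()
            labels_field = row[1].strip() if len(row) == 2 else ""
            labels = [x.strip() for x in labels_field.split(";") if x.strip()]
            yield lineno, vertex, labels


def read_network(
    edge_source: PathLike,
    membership_source: PathLike | None = None,
    directed: bool = False,
    strict: bool = False,
    labels: Iterable[str] | None = None,
) -> SocialNetwork:
    """Read a social network from an edge list plus a membership table.

    Vertices present only in the membership table become isolated vertices.
    In ``strict`` mode an edge referencing a vertex absent from the membership
    table is an error; otherwise such vertices get an empty membership.
    Duplicate edges (including an undirected edge given in both orientations)
    collapse to one canonical edge with a warning.
    """
    membership: dict = {}
    declared: set = set()
    declared_labels: set | None = None
    if membership_source is not None:
        with open(membership_source, "r", encoding="utf-8") as fh:
            first = fh.readline()
        if first.startswith("# labels:"):
            declared_labels = {
                x.strip() for x in first[len("# labels:"):].split(";") if x.strip()
            }
        for _lineno, vertex, vlabels in _read_membership_rows(membership_source):
            membership[vertex] = vlabels
            declared.add(vertex)

    vertices = set(declared)
    edges = set()
    for lineno, u, v in _read_edge_rows(edge_source):
        if strict and membership_source is not None:
            for w in (u, v):
                if w not in declared:
                    raise FormatError(
                        f"{edge_source}: line {lineno}: edge references "
                        f"undeclared vertex {w!r}"
                    )
        e = canonical_edge(u, v, directed)
        if e in edges:
            warnings.warn(f"duplicate edge {e} collapsed on read", stacklevel=2)
        edges.add(e)
        vertices.update((u, v))

    if labels is None:
        labels = set().union(*(set(ls) for ls in membership.values()), set())
        if declared_labels is not None:
            labels |= declared_labels
    graph = Graph.build(vertices, edges, directed=directed)
    return SocialNetwork(graph, labels, membership)


def write_network(
    net: SocialNetwork,
    edge_dest: PathLike,
    membership_dest: PathLike,
) -> None:
    """Write the edge list and membership table that :func:`read_network` inverts."""
    with open(edge_dest, "w", encoding="utf-8") as fh:
        fh.write("# source target\n")
        for u, v in net.graph.sorted_edges():
            fh.write(f"{u} {v}\n")
    with open(membership_dest, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# labels: {';'.join(sorted(net.labels))}\n")
        writer = csv.writer(fh)
        writer.writerow(["vertex", "labels"])
        for v in net.graph.sorted_vertices():
            writer.writerow([v, ";".join(sorted(net.membership(v)))])


def network_to_json(net: SocialNetwork) -> dict:
    return {
        "directed": net.directed,
        "vertices": list(net.graph.sorted_vertices()),
        "edges": [list(e) for e in net.graph.sorted_edges()],
        "labels": sorted(net.labels),
        "membership": {
            v: sorted(net.membership(v)) for v in net.graph.sorted_vertices()
        },
    }


def network_from_json(data: dict) -> SocialNetwork:
    graph = Graph.build(data["vertices"], data["edges"], directed=data["directed"])
    return SocialNetwork(graph, data["labels"], data["membership"])


def write_graphml(net: SocialNetwork, dest: PathLike) -> None:
    """Export to GraphML with a ``communities`` string vertex attribute."""
    g = nx.DiGraph() if net.directed else nx.Graph()
    for v in net.graph.sorted_vertices():
        g.add_node(v, communities=";".join(sorted(net.membership(v))))
    g.add_edges_from(net.graph.sorted_edges())
    g.graph["labels"] = ";".join(sorted(net.labels))
    nx.write_graphml(g, str(dest))


def read_graphml(source: PathLike) -> SocialNetwork:
    g = nx.read_graphml(str(source))
    directed = g.is_directed()
    membership = {
        str(v): [x for x in str(data.get("communities", "")).split(";") if x]
        for v, data in g.nodes(data=True)
    }
    labels_attr = str(g.graph.get("labels", ""))
    labels = set(x for x in labels_attr.split(";") if x)
    labels |= set().union(*(set(ls) for ls in membership.values()), set())
    graph = Graph.build((str(v) for v in g.nodes), g.edges, directed=directed)
    return SocialNetwork(graph, labels, membership)


def save_network(net: SocialNetwork, directory: PathLike, name: str = "network") -> None:
    """Write ``<name>.edges`` and ``<name>.communities.csv`` under ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_network(net, directory / f"{name}.edges", directory / f"{name}.communities.csv")


def load_network(directory: PathLike, name: str = "network", directed: bool = False) -> SocialNetwork:
    directory = Path(directory)
    return read_network(
        directory / f"{name}.edges",
        directory / f"{name}.communities.csv",
        directed=directed,
    )
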