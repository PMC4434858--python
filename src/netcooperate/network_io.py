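"""Metabolic networks and the two plain-text dialects that encode them.

A metabolic network is modelled as a directed graph whose nodes are
compound identifiers (opaque non-empty strings; KEGG compound IDs are a
common convention) and whose edges run from substrate to product.  Two
file dialects are supported:

* **edge list** — one directed edge per row, substrate in column 1 and
  product in column 2, delimited by tabs, commas, or runs of whitespace;
* **adjacency matrix** — tab-delimited, a header row of column compound
  labels, each body row a row label followed by numeric cells; any
  nonzero cell ``(i, j)`` is the edge ``label_i -> label_j``.

Blank lines and lines starting with ``#`` are ignored in both dialects.
Isolated compounds (no in- or out-edge) are representable only in the
adjacency dialect; the edge-list dialect cannot carry them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .errors import (
    EmptyInputError,
    NetworkParseError,
    SerializationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MetabolicNetwork",
    "parse_edge_list",
    "parse_adjacency_matrix",
    "parse_network",
    "write_edge_list",
    "write_adjacency_matrix",
    "sniff_dialect",
]

_DELIMITERS: Mapping[str, str | None] = {
    "tab": "\t",
    "comma": ",",
    "space": None,  # str.split() semantics: any whitespace run
}


@dataclass(frozen=True)
class MetabolicNetwork:
    """A directed compound graph: the unit of input for all analyses.

    Parameters
    ----------
    name
        Label used in reports (typically the species or file stem).
    nodes
        All compound identifiers, including isolated ones.
    edges
        Set of ``(substrate, product)`` pairs.  Every endpoint must be a
        member of ``nodes``; duplicates collapse under set semantics.
    """

    name: str
    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", frozenset(self.nodes))
        object.__setattr__(self, "edges", frozenset(tuple(e) for e in self.edges))
        if not self.nodes:
            raise ValueError("a metabolic network must contain at least one compound")
        for node in self.nodes:
            if not isinstance(node, str) or not node.strip() or node != node.strip():
                raise ValueError(f"invalid compound label: {node!r}")
        for edge in self.edges:
            if len(edge) != 2:
                raise ValueError(f"edge is not a (substrate, product) pair: {edge!r}")
            for endpoint in edge:
                if endpoint not in self.nodes:
                    raise ValueError(f"edge endpoint {endpoint!r} is not a declared compound")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def successors(self) -> dict[str, list[str]]:
        """Adjacency map with deterministically (lexicographically) sorted
        neighbour lists; every node appears as a key."""
        adj: dict[str, list[str]] = {node: [] for node in self.nodes}
        for substrate, product in sorted(self.edges):
            adj[substrate].append(product)
        return adj

    def isolated_nodes(self) -> frozenset[str]:
        touched = {u for e in self.edges for u in e}
        return self.nodes - touched

    def relabeled(self, mapping: Mapping[str, str], name: str | None = None) -> "MetabolicNetwork":
        """Apply a node-label bijection; labels absent from ``mapping`` keep
        their name."""
        ren = {n: mapping.get(n, n) for n in self.nodes}
        if len(set(ren.values())) != len(ren):
            raise ValueError("relabeling must be injective on the node set")
        return MetabolicNetwork(
            name=name if name is not None else self.name,
            nodes=frozenset(ren.values()),
            edges=frozenset((ren[u], ren[v]) for u, v in self.edges),
        )

    def graph_equal(self, other: "MetabolicNetwork") -> bool:
        """Structural equality: same nodes and same edges, names ignored."""
        return self.nodes == other.nodes and self.edges == other.edges


def _data_lines(text: str) -> list[tuple[int, str]]:
    """(1-based line number, content) for non-blank, non-comment lines."""
    out = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        out.append((lineno, raw.rstrip("\n")))
    return out


def _detect_delimiter(first_line: str) -> str:
    if "\t" in first_line:
        return "tab"
    if "," in first_line:
        return "comma"
    return "space"


def parse_edge_list(
    text: str,
    delimiter: str = "auto",
    name: str = "network",
    case_fold: bool = False,
) -> MetabolicNetwork:
    """Parse an edge-list file: one directed substrate→product edge per row.

    ``delimiter`` is one of ``tab``, ``comma``, ``space`` or ``auto``
    (detected from the first data line: tab, then comma, then any
    whitespace run).  Columns beyond the first two are ignored with a
    warning.  Duplicate rows collapse to a single edge.
    """
    if delimiter not in ("auto", *_DELIMITERS):
        raise ValueError(f"unknown delimiter {delimiter!r}")
    rows = _data_lines(text)
    if not rows:
        raise EmptyInputError("no data rows found", source=name)
    if delimiter == "auto":
        delimiter = _detect_delimiter(rows[0][1].strip())
    sep = _DELIMITERS[delimiter]

    edges: set[tuple[str, str]] = set()
    extra_column_rows = 0
    for lineno, line in rows:
        fields = [f.strip() for f in line.split(sep)]
        fields = [f for f in fields if f]
        if len(fields) < 2:
            raise NetworkParseError(
                f"expected at least 2 {delimiter}-delimited fields, got {len(fields)}",
                line=lineno,
                source=name,
            )
        if len(fields) > 2:
            extra_column_rows += 1
        substrate, product = fields[0], fields[1]
        if case_fold:
            substrate, product = substrate.upper(), product.upper()
        edges.add((substrate, product))
    if extra_column_rows:
        logger.warning(
            "%s: ignored columns beyond the first two on %d row(s)", name, extra_column_rows
        )
    nodes = frozenset(u for e in edges for u in e)
    return MetabolicNetwork(name=name, nodes=nodes, edges=frozenset(edges))


def parse_adjacency_matrix(
    text: str,
    name: str = "network",
    case_fold: bool = False,
) -> MetabolicNetwork:
    """Parse a tab-delimited adjacency matrix.

    The first row holds the column compound labels (with or without a
    leading corner label); each body row is a row label followed by
    numeric cells.  A nonzero cell at ``(row i, column j)`` encodes the
    edge ``label_i -> label_j``.  Row and column labels all become
    nodes, so isolated compounds survive a zero matrix.
    """
    rows = _data_lines(text)
    if not rows:
        raise EmptyInputError("no data rows found", source=name)
    header_lineno, header_line = rows[0]
    header = [f.strip() for f in header_line.split("\t")]
    header = [f for f in header if f]
    if not header:
        raise NetworkParseError("empty header row", line=header_lineno, source=name)
    body = rows[1:]

    widths = {len(line.split("\t")) for _, line in body}
    if len(widths) > 1:
        bad = next(
            lineno for lineno, line in body if len(line.split("\t")) != len(body[0][1].split("\t"))
        )
        raise NetworkParseError("ragged rows in adjacency matrix", line=bad, source=name)
    body_width = widths.pop() if widths else len(header) + 1

    # The header may or may not carry a corner label over the row-label
    # column; accept both variants.
    if body_width == len(header) + 1:
        col_labels = header
    elif body_width == len(header) and len(header) >= 2:
        col_labels = header[1:]
    else:
        raise NetworkParseError(
            f"header has {len(header)} labels but body rows have {body_width} fields",
            line=header_lineno,
            source=name,
        )
    if case_fold:
        col_labels = [c.upper() for c in col_labels]
    if len(set(col_labels)) != len(col_labels):
        raise NetworkParseError("duplicate column labels", line=header_lineno, source=name)

    edges: set[tuple[str, str]] = set()
    row_labels: list[str] = []
    for lineno, line in body:
        fields = line.split("\t")
        row_label = fields[0].strip()
        if not row_label:
            raise NetworkParseError("empty row label", line=lineno, source=name)
        if case_fold:
            row_label = row_label.upper()
        if row_label in row_labels:
            raise NetworkParseError(f"duplicate row label {row_label!r}", line=lineno, source=name)
        row_labels.append(row_label)
        cells = fields[1:]
        if len(cells) != len(col_labels):
            raise NetworkParseError(
                f"expected {len(col_labels)} cells, got {len(cells)}", line=lineno, source=name
            )
        for col_label, cell in zip(col_labels, cells):
            try:
                value = float(cell)
            except ValueError:
                raise NetworkParseError(
                    f"non-numeric cell {cell.strip()!r}", line=lineno, source=name
                ) from None
            if value != 0:
                edges.add((row_label, col_label))
    nodes = frozenset(col_labels) | frozenset(row_labels)
    return MetabolicNetwork(name=name, nodes=nodes, edges=frozenset(edges))


def write_edge_list(net: MetabolicNetwork, delimiter: str = "tab") -> str:
    """Serialize to edge-list text, edges in lexicographic order.

    Raises :class:`SerializationError` for an edge-free network: the
    edge-list dialect cannot express isolated compounds.  Networks that
    mix edges with isolated nodes are written with the isolated nodes
    dropped (and a warning logged).
    """
    if delimiter not in _DELIMITERS:
        raise ValueError(f"unknown delimiter {delimiter!r}")
    if not net.edges:
        raise SerializationError(
            f"network {net.name!r} has no edges; the edge-list dialect cannot "
            "represent isolated compounds (use the adjacency-matrix dialect)"
        )
    dropped = net.isolated_nodes()
    if dropped:
        logger.warning(
            "%s: %d isolated compound(s) not expressible in edge-list output: %s",
            net.name,
            len(dropped),
            ", ".join(sorted(dropped)),
        )
    sep = _DELIMITERS[delimiter] or " "
    lines = [f"{u}{sep}{v}" for u, v in sorted(net.edges)]
    return "\n".join(lines) + "\n"


def write_adjacency_matrix(net: MetabolicNetwork, corner_label: str = "compound") -> str:
    """Serialize to a tab-delimited 0/1 adjacency matrix with sorted labels."""
    labels = sorted(net.nodes)
    lines = ["\t".join([corner_label, *labels])]
    edge_set = net.edges
    for row in labels:
        cells = ["1" if (row, col) in edge_set else "0" for col in labels]
        lines.append("\t".join([row, *cells]))
    return "\n".join(lines) + "\n"


def sniff_dialect(text: str) -> str:
    """Guess ``"adjacency"`` or ``"edge_list"`` from file content.

    A file looks like an adjacency matrix when it has a header plus at
    least one body row, all rows have the same tab-delimited width, and
    every body cell after the row label is numeric.  Anything else is
    treated as an edge list.  An explicit format flag always overrides
    this heuristic.
    """
    rows = _data_lines(text)
    if len(rows) < 2:
        return "edge_list"
    split_rows = [line.split("\t") for _, line in rows]
    widths = {len(r) for r in split_rows}
    header_ok = False
    if len(widths) == 1 and len(split_rows[0]) >= 2:
        header_ok = True
    elif widths == {len(split_rows[0]), len(split_rows[0]) + 1}:
        # corner-less header: body rows one field wider than the header
        header_ok = all(len(r) == len(split_rows[0]) + 1 for r in split_rows[1:])
    if not header_ok:
        return "edge_list"
    for r in split_rows[1:]:
        for cell in r[1:]:
            try:
                float(cell)
            except ValueError:
                return "edge_list"
    return "adjacency"


def parse_network(
    text: str,
    fmt: str = "auto",
    delimiter: str = "auto",
    name: str = "network",
    case_fold: bool = False,
) -> MetabolicNetwork:
    """Parse with an explicit format, or sniff when ``fmt="auto"``."""
    if fmt == "auto":
        fmt = sniff_dialect(text)
    if fmt == "edge_list":
        return parse_edge_list(text, delimiter=delimiter, name=name, case_fold=case_fold)
    if fmt == "adjacency":
        return parse_adjacency_matrix(text, name=name, case_fold=case_fold)
    raise ValueError(f"unknown network format {fmt!r}")
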