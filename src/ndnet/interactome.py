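"""Protein-protein interaction tables and undirected interaction networks.

Interaction evidence arrives as tab-separated tables in either a minimal
``generic`` dialect (``symbol_a``/``symbol_b``) or the tab-dialect used by
curated interaction databases (official symbol and organism columns for both
interactors plus an experimental-system label).  Parsing preserves the rows
as-is; network construction collapses duplicate and reversed pairs to single
undirected edges and drops self-interactions, which are excluded from all
degree-based analyses.

Hub analysis is deliberately simple and unweighted: a hub is a node of
maximal degree (number of distinct partners), and the *first shell* of a
protein is its direct-neighbor set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, NamedTuple, Sequence, Union

import networkx as nx
import pandas as pd

from .seed_registry import GeneSet

__all__ = [
    "InteractionRecord",
    "InteractionNetwork",
    "DegreeRank",
    "parse_interactions",
    "build_network",
    "induced_subnetwork",
    "rank_by_degree",
    "first_shell",
    "partner_index",
    "write_edge_list",
    "write_graphml",
]

Source = Union[str, Path, IO[str]]

HUMAN = "Homo sapiens"

_BIOGRID_COLUMNS = {
    "symbol_a": "Official Symbol Interactor A",
    "symbol_b": "Official Symbol Interactor B",
    "organism_a": "Organism Name Interactor A",
    "organism_b": "Organism Name Interactor B",
    "evidence": "Experimental System",
}


@dataclass(frozen=True)
class InteractionRecord:
    """One row of an interaction table, before any network-level filtering."""

    symbol_a: str
    symbol_b: str
    organism_a: str | None = None
    organism_b: str | None = None
    evidence: str | None = None
    source_line: int = 0

    def __post_init__(self) -> None:
        if not self.symbol_a or not self.symbol_b:
            raise ValueError("interaction record with empty interactor symbol")


@dataclass
class InteractionNetwork:
    """Undirected simple graph of protein partners, keyed by gene symbol.

    ``n_self_dropped`` and ``n_duplicates_collapsed`` account for rows removed
    during construction; evidence labels are retained as the edge attribute
    ``evidence`` (a sorted tuple) for reporting.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)
    n_self_dropped: int = 0
    n_duplicates_collapsed: int = 0
    isolated_seed: frozenset[str] = frozenset()

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset(e) for e in self.graph.edges}

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree(self, symbol: str) -> int:
        return int(self.graph.degree[symbol])


def parse_interactions(
    source: Source,
    dialect: str = "generic",
    organism: str | None = HUMAN,
) -> list[InteractionRecord]:
    """Parse an interaction TSV into records, one per data row.

    ``dialect`` is ``"generic"`` (columns ``symbol_a``, ``symbol_b``, optional
    ``evidence``) or ``"biogrid_tab"`` (official-symbol/organism columns).
    Self-pairs and duplicates are preserved here — filtering is
    :func:`build_network`'s job.  For the ``biogrid_tab`` dialect, rows whose
    interactors are not both from ``organism`` are dropped (pass
    ``organism=None`` to disable); the generic dialect has no organism
    columns and is passed through.
    """
    if dialect not in ("generic", "biogrid_tab"):
        raise ValueError(f"unknown interaction dialect {dialect!r}")
    df = pd.read_csv(source, sep="\t", dtype=str)
    records: list[InteractionRecord] = []
    if dialect == "generic":
        for col in ("symbol_a", "symbol_b"):
            if col not in df.columns:
                raise ValueError(
                    f"generic interaction table lacks required column {col!r}"
                )
        for i, row in enumerate(df.itertuples(index=False), start=2):
            ev = getattr(row, "evidence", None)
            records.append(
                InteractionRecord(
                    symbol_a=str(row.symbol_a).upper(),
                    symbol_b=str(row.symbol_b).upper(),
                    evidence=None if ev is None or pd.isna(ev) else str(ev),
                    source_line=i,
                )
            )
        return records

    for key in ("symbol_a", "symbol_b", "evidence"):
        col = _BIOGRID_COLUMNS[key]
        if col not in df.columns:
            raise ValueError(
                f"biogrid_tab interaction table lacks required column {col!r}"
            )
    has_org = all(
        _BIOGRID_COLUMNS[k] in df.columns for k in ("organism_a", "organism_b")
    )
    for i, (_, row) in enumerate(df.iterrows(), start=2):
        org_a = row.get(_BIOGRID_COLUMNS["organism_a"]) if has_org else None
        org_b = row.get(_BIOGRID_COLUMNS["organism_b"]) if has_org else None
        if organism is not None and has_org and not (org_a == organism and org_b == organism):
            continue
        records.append(
            InteractionRecord(
                symbol_a=str(row[_BIOGRID_COLUMNS["symbol_a"]]).upper(),
                symbol_b=str(row[_BIOGRID_COLUMNS["symbol_b"]]).upper(),
                organism_a=org_a,
                organism_b=org_b,
                evidence=row[_BIOGRID_COLUMNS["evidence"]],
                source_line=i,
            )
        )
    return records


def build_network(records: Iterable[InteractionRecord]) -> InteractionNetwork:
    """Build the undirected simple network from interaction records.

    (A, B) and (B, A) collapse to a single edge; self-pairs are dropped.
    Multi-evidence edges collapse to one unweighted edge with the evidence
    labels merged into the edge's ``evidence`` attribute.
    """
    g = nx.Graph()
    n_self = 0
    n_dup = 0
    for rec in records:
        if rec.symbol_a == rec.symbol_b:
            n_self += 1
            continue
        if g.has_edge(rec.symbol_a, rec.symbol_b):
            n_dup += 1
            if rec.evidence:
                ev = set(g.edges[rec.symbol_a, rec.symbol_b]["evidence"])
                ev.add(rec.evidence)
                g.edges[rec.symbol_a, rec.symbol_b]["evidence"] = tuple(sorted(ev))
        else:
            g.add_edge(
                rec.symbol_a,
                rec.symbol_b,
                evidence=(rec.evidence,) if rec.evidence else (),
            )
    return InteractionNetwork(graph=g, n_self_dropped=n_self, n_duplicates_collapsed=n_dup)


def induced_subnetwork(
    net: InteractionNetwork, genes: GeneSet | Iterable[str]
) -> InteractionNetwork:
    """Subnetwork on the seed symbols: edges with *both* endpoints in the seed.

    Seed nodes present in ``net`` but retaining no within-seed edge are kept
    as nodes and flagged in ``isolated_seed``.
    """
    symbols = genes.symbols if isinstance(genes, GeneSet) else {s.upper() for s in genes}
    keep = symbols & net.nodes
    sub = nx.Graph(net.graph.subgraph(keep))
    isolated = frozenset(n for n in sub.nodes if sub.degree[n] == 0)
    return InteractionNetwork(graph=sub, isolated_seed=isolated)


class DegreeRank(NamedTuple):
    symbol: str
    degree: int
    is_co_hub: bool


def rank_by_degree(net: InteractionNetwork) -> list[DegreeRank]:
    """Nodes sorted by degree descending (ties lexicographic by symbol).

    Every node sharing the maximal degree is marked as a co-hub; a
    single-hub summary corresponds to the common case of a unique maximum.
    """
    degs = sorted(net.graph.degree, key=lambda sd: (-sd[1], sd[0]))
    if not degs:
        return []
    dmax = degs[0][1]
    return [DegreeRank(s, int(d), int(d) == dmax) for s, d in degs]


def first_shell(net: InteractionNetwork, symbol: str) -> set[str]:
    """Direct-neighbor set of ``symbol`` (never contains ``symbol`` itself)."""
    symbol = symbol.upper()
    if symbol not in net.graph:
        raise KeyError(f"symbol {symbol!r} is not a node of the network")
    return set(net.graph.neighbors(symbol))


def partner_index(
    net: InteractionNetwork, candidates: Iterable[str] | None = None
) -> dict[str, set[str]]:
    """Map each node (or each of ``candidates``) to its partner set."""
    nodes = net.nodes if candidates is None else {c.upper() for c in candidates}
    return {n: set(net.graph.neighbors(n)) for n in nodes if n in net.graph}


def _annotate(
    net: InteractionNetwork,
    seed: GeneSet | None,
    detected_b_cell: Iterable[str] | None,
) -> nx.Graph:
    g = net.graph.copy()
    seed_syms = seed.symbols if seed is not None else frozenset()
    det = {s.upper() for s in detected_b_cell} if detected_b_cell is not None else frozenset()
    for n in g.nodes:
        g.nodes[n]["is_seed"] = n in seed_syms
        g.nodes[n]["degree"] = int(g.degree[n])
        g.nodes[n]["detected_b_cell"] = n in det
    return g


def write_edge_list(net: InteractionNetwork, path: str | Path) -> None:
    """Export the edge set as a sorted two-column TSV (deterministic order)."""
    rows = sorted(tuple(sorted(e)) for e in net.graph.edges)
    pd.DataFrame(rows, columns=["symbol_a", "symbol_b"]).to_csv(
        path, sep="\t", index=False
    )


def write_graphml(
    net: InteractionNetwork,
    path: str | Path,
    seed: GeneSet | None = None,
    detected_b_cell: Iterable[str] | None = None,
) -> None:
    """Export as GraphML with node attributes is_seed, degree, detected_b_cell.

    Evidence tuples are flattened to ``;``-joined strings for GraphML typing.
    """
    g = _annotate(net, seed, detected_b_cell)
    for u, v, data in g.edges(data=True):
        if "evidence" in data:
            data["evidence"] = ";".join(data["evidence"])
    nx.write_graphml(g, str(path))
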