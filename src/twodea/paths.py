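"""Shortest-path analytics on the signed interaction graph.

A path ``u1 -r1-> u2 -r2-> ... -rL-> u(L+1)`` has length ``L`` (edge count)
and type ``T = r1 * r2 * ... * rL``, i.e. the net sign of the chain.  The
shortest path between a pair is *consistent* if no alternative path of the
same minimal length carries the opposite type; inconsistent pairs have an
ambiguous net effect and are treated as sign-neutral (they contribute zero
wherever a formula multiplies by ``T``).

The workhorse is a signed breadth-first search over ``(node, sign)`` states:
a node first reached at layer ``d`` with both signs is inconsistent.  For
phenotype influence scores the module additionally enumerates simple paths
inside submap-induced subgraphs (capped at a configurable maximum length,
since curated submaps may contain cycles) to produce the path/element
counts those scores are built from.
"""

from __future__ import annotations

import dataclasses
import logging
from collections import Counter, defaultdict
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from .mim import BioType, MIMGraph

logger = logging.getLogger("twodea.paths")

__all__ = [
    "PathRecord",
    "PathTable",
    "SubmapPathStats",
    "signed_bfs",
    "shortest_paths_from",
    "upstream_within",
    "submap_path_stats",
    "on_path_elements",
    "count_paths",
    "DEFAULT_MAX_PATH_LEN",
]

#: cap on enumerated simple-path length (edges) inside submap subgraphs
DEFAULT_MAX_PATH_LEN = 8


@dataclasses.dataclass(frozen=True)
class PathRecord:
    """Shortest-path summary for one ordered pair."""

    source: str
    target: str
    length: int
    sign: int | None  # +1 / -1, or None when inconsistent

    @property
    def consistent(self) -> bool:
        return self.sign is not None


def signed_bfs(
    graph: MIMGraph,
    source: str,
    max_depth: int | None = None,
    reverse: bool = False,
) -> dict[str, tuple[int, int | None]]:
    """Breadth-first search tracking the achievable net sign at minimal depth.

    Returns ``{node: (L, T)}`` for every node reachable from ``source``
    within ``max_depth`` edges (``T is None`` marks an inconsistent pair).
    With ``reverse=True`` edges are traversed backwards, yielding shortest
    paths *into* ``source``.
    """
    graph.element(source)
    if max_depth is not None and max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    adjacency = graph.in_edges if reverse else graph.out_edges

    result: dict[str, tuple[int, int | None]] = {}
    finalized = {source}
    frontier: dict[str, frozenset] = {source: frozenset({1})}
    depth = 0
    while frontier and (max_depth is None or depth < max_depth):
        nxt: dict[str, set] = defaultdict(set)
        for node, signs in frontier.items():
            for edge in adjacency(node):
                nbr = edge.source if reverse else edge.target
                if nbr in finalized:
                    continue
                for s in signs:
                    nxt[nbr].add(s * edge.relation)
        depth += 1
        frontier = {}
        for node, signs in nxt.items():
            finalized.add(node)
            sign = next(iter(signs)) if len(signs) == 1 else None
            result[node] = (depth, sign)
            frontier[node] = frozenset(signs)
    return result


def shortest_paths_from(
    graph: MIMGraph, source: str, max_depth: int | None = None
) -> list[PathRecord]:
    """All shortest-path records out of ``source`` (one per reachable node;
    unreachable pairs are simply absent)."""
    return [
        PathRecord(source, target, length, sign)
        for target, (length, sign) in sorted(
            signed_bfs(graph, source, max_depth).items()
        )
    ]


def upstream_within(
    graph: MIMGraph, target: str, max_depth: int = 2
) -> dict[str, tuple[int, int | None]]:
    """Shortest paths *into* ``target``: ``{u: (L(SP_{u,target}), T)}`` for
    every ``u`` within ``max_depth`` edges upstream.  The depth-2 default is
    the horizon the influence-score recursion consults."""
    return signed_bfs(graph, target, max_depth=max_depth, reverse=True)


class PathTable:
    """Precomputed shortest-path records, keyed by ``(source, target)``.

    Supports the precompute-once workflow: build from a graph, persist as
    TSV, reload, and feed to the influence-score builders.
    """

    def __init__(self, records: Iterable[PathRecord] = ()):
        self._records: dict[tuple[str, str], PathRecord] = {}
        for rec in records:
            self._records[(rec.source, rec.target)] = rec
        self._by_target: dict[str, list[PathRecord]] | None = None

    @classmethod
    def from_graph(
        cls,
        graph: MIMGraph,
        sources: Iterable[str] | None = None,
        max_depth: int | None = None,
    ) -> "PathTable":
        table = cls()
        for u in sorted(sources) if sources is not None else graph.element_ids():
            for rec in shortest_paths_from(graph, u, max_depth):
                table._records[(rec.source, rec.target)] = rec
        return table

    def get(self, source: str, target: str) -> PathRecord | None:
        return self._records.get((source, target))

    def sources_to(self, target: str, max_length: int | None = None) -> list[PathRecord]:
        if self._by_target is None:
            by_target: dict[str, list[PathRecord]] = defaultdict(list)
            for rec in self._records.values():
                by_target[rec.target].append(rec)
            self._by_target = dict(by_target)
        recs = self._by_target.get(target, [])
        if max_length is not None:
            recs = [r for r in recs if r.length <= max_length]
        return recs

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[PathRecord]:
        return iter(
            self._records[k] for k in sorted(self._records)
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PathTable):
            return NotImplemented
        return self._records == other._records

    def to_tsv(self, dest: str | Path) -> None:
        with open(dest, "w", encoding="utf-8") as fh:
            fh.write("source\ttarget\tlength\ttype\tconsistent\n")
            for rec in self:
                t = "0" if rec.sign is None else str(rec.sign)
                fh.write(
                    f"{rec.source}\t{rec.target}\t{rec.length}\t{t}\t"
                    f"{'true' if rec.consistent else 'false'}\n"
                )

    @classmethod
    def from_tsv(cls, source: str | Path) -> "PathTable":
        records = []
        with open(source, encoding="utf-8") as fh:
            header = fh.readline()
            if not header.startswith("source\ttarget"):
                raise ValueError(f"{source}: not a path table")
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                u, v, length, t, consistent = line.rstrip("\n").split("\t")
                sign = int(t) if consistent == "true" else None
                records.append(PathRecord(u, v, int(length), sign))
        return cls(records)


# ----------------------------------------------------------------------
# submap path enumeration (phenotype influence support)


@dataclasses.dataclass
class SubmapPathStats:
    """Counted-path statistics on the submap subgraph of a phenotype.

    ``n_paths`` is the number of counted (simple, length-capped) paths from
    any submap element to the phenotype; ``paths_through[u]`` counts those
    passing through ``u`` (as source or intermediate); ``on_path[u]`` is the
    set of elements on counted paths starting at ``u`` (including ``u``,
    excluding the phenotype); ``n_connected`` counts submap elements with at
    least one counted path.
    """

    phenotype: str
    n_paths: int
    paths_through: dict
    on_path: dict

    @property
    def n_connected(self) -> int:
        return len(self.on_path)


def _simple_paths_to(
    sub: MIMGraph, source: str, sink: str, max_len: int
) -> Iterator[list[str]]:
    """DFS enumeration of simple paths ``source -> sink`` with at most
    ``max_len`` edges in the (small) submap subgraph."""
    stack: list[tuple[str, list[str]]] = [(source, [source])]
    while stack:
        node, path = stack.pop()
        edges = len(path) - 1
        for edge in sub.out_edges(node):
            nbr = edge.target
            if nbr == sink:
                if edges + 1 <= max_len:
                    yield path + [sink]
            elif nbr not in path and edges + 1 < max_len:
                stack.append((nbr, path + [nbr]))


def submap_path_stats(
    graph: MIMGraph, v: str, max_len: int = DEFAULT_MAX_PATH_LEN
) -> SubmapPathStats:
    """Enumerate counted paths to phenotype ``v`` inside its submap(s).

    Paths are simple (no node revisits) and capped at ``max_len`` edges so
    that cyclic submaps terminate; the cap is a declared parameter of the
    method, not an implementation detail.
    """
    if graph.element(v).bio_type is not BioType.PHENOTYPE:
        raise ValueError(f"element {v!r} is not a phenotype")
    members = graph.submap_neighbours(v)
    stats = SubmapPathStats(v, 0, Counter(), {})
    if not members:
        return stats
    sub = graph.induced_subgraph(set(members) | {v})
    for u in sorted(members):
        reached: set = set()
        for path in _simple_paths_to(sub, u, v, max_len):
            stats.n_paths += 1
            for node in path[:-1]:
                stats.paths_through[node] += 1
            reached.update(path[:-1])
        if reached:
            stats.on_path[u] = frozenset(reached)
    return stats


def on_path_elements(
    graph: MIMGraph, v: str, max_len: int = DEFAULT_MAX_PATH_LEN
) -> dict[str, frozenset]:
    """Per submap element ``u``: the elements lying on counted ``u -> v``
    paths (including ``u``, excluding ``v``).  Elements with no path to the
    phenotype are absent from the result."""
    return dict(submap_path_stats(graph, v, max_len).on_path)


def count_paths(
    graph: MIMGraph, v: str, max_len: int = DEFAULT_MAX_PATH_LEN
) -> tuple[int, dict, int, dict]:
    """Eq.-style counts for phenotype ``v``: ``(N_P, {u: N_Pu}, N_V,
    {u: N_Vu})`` on the submap-induced subgraph."""
    stats = submap_path_stats(graph, v, max_len)
    n_vu = {u: len(nodes) for u, nodes in stats.on_path.items()}
    return stats.n_paths, dict(stats.paths_through), stats.n_connected, n_vu
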