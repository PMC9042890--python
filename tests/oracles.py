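"""Independent reference implementations used as test oracles.

Everything here is deliberately written against networkx path enumeration
and literal formula transliteration, sharing no code with the package's
BFS/aggregation machinery.
"""

from __future__ import annotations

import numpy as np
import networkx as nx

from twodea.mim import BioType, InteractionClass, MIMGraph


def to_networkx(graph: MIMGraph) -> nx.MultiDiGraph:
    G = nx.MultiDiGraph()
    G.add_nodes_from(graph.element_ids())
    for ia in graph.interactions():
        G.add_edge(ia.source, ia.target, sign=ia.relation)
    return G


def shortest_path_oracle(
    graph: MIMGraph, cutoff: int = 6
) -> dict[tuple[str, str], tuple[int, int | None]]:
    """``(u, v) -> (L, T or None)`` by exhaustive enumeration of all simple
    paths with at most ``cutoff`` edges, reduced to minimal length and sign
    agreement."""
    G = to_networkx(graph)
    result: dict[tuple[str, str], tuple[int, int | None]] = {}
    for u in G:
        for v in G:
            if u == v:
                continue
            best: int | None = None
            signs: set[int] = set()
            for edge_path in nx.all_simple_edge_paths(G, u, v, cutoff=cutoff):
                length = len(edge_path)
                sign = 1
                for s, t, key in edge_path:
                    sign *= G.edges[s, t, key]["sign"]
                if best is None or length < best:
                    best, signs = length, {sign}
                elif length == best:
                    signs.add(sign)
            if best is not None:
                result[(u, v)] = (best, signs.pop() if len(signs) == 1 else None)
    return result


def _net_direct_sign(graph: MIMGraph, u: str, v: str, iclass: InteractionClass) -> float:
    total = sum(
        ia.relation
        for ia in graph.in_edges(v)
        if ia.source == u and ia.iclass is iclass
    )
    return float(np.sign(total))


def _aggregate_oracle(
    base: dict[str, float],
    exclude: frozenset,
    v: str,
    sp: dict,
    all_ids: list[str],
) -> dict[str, float]:
    out: dict[str, float] = {}
    for u in all_ids:
        if u == v or u in exclude:
            continue
        total = 0.0
        for k, score in base.items():
            rec = sp.get((u, k))
            if rec is None:
                continue
            length, sign = rec
            if length > 2 or sign is None:
                continue
            total += score * sign / 2**length
        if total != 0.0:
            out[u] = total
    return out


def regulator_influence_oracle(
    graph: MIMGraph, v: str, iclass: InteractionClass, sp: dict
) -> dict[str, float]:
    """Literal evaluation of the piecewise transcriptional/catalytic
    influence formula."""
    regulators = (
        graph.transcription_factors(v)
        if iclass is InteractionClass.TRANSCRIPTIONAL
        else graph.synthesizing_enzymes(v)
    )
    base = {}
    for u in regulators:
        s = _net_direct_sign(graph, u, v, iclass)
        if s != 0.0:
            base[u] = s
    column = dict(base)
    for u, raw in _aggregate_oracle(
        base, regulators, v, sp, graph.element_ids()
    ).items():
        clamped = max(-1.0, min(1.0, raw))
        if clamped != 0.0:
            column[u] = clamped
    return column


def phenotype_influence_oracle(
    graph: MIMGraph, v: str, sp: dict, max_len: int = 8
) -> dict[str, float]:
    """Literal evaluation of the phenotype influence formula on the
    submap-induced subgraph, with simple paths capped at ``max_len`` edges
    and the final division by the column's maximum magnitude."""
    members = graph.submap_neighbours(v)
    if not members:
        return {}
    sub = graph.induced_subgraph(set(members) | {v})
    G = to_networkx(sub)

    n_paths = 0
    through: dict[str, int] = {}
    on_path: dict[str, set] = {}
    for u in sorted(members):
        reached: set = set()
        for edge_path in nx.all_simple_edge_paths(G, u, v, cutoff=max_len):
            n_paths += 1
            nodes = [edge_path[0][0]] + [e[1] for e in edge_path[:-1]]
            for w in nodes:
                through[w] = through.get(w, 0) + 1
            reached.update(nodes)
        if reached:
            on_path[u] = reached
    if n_paths == 0:
        return {}

    sub_sp = shortest_path_oracle(sub, cutoff=len(G))
    base: dict[str, float] = {}
    for u in on_path:
        rec = sub_sp.get((u, v))
        if rec is None or rec[1] is None:
            continue
        raw = rec[1] * (through[u] / n_paths + len(on_path[u]) / len(on_path))
        if raw != 0.0:
            base[u] = raw
    if not base:
        return {}
    cap = max(abs(s) for s in base.values())
    column = dict(base)
    for u, raw in _aggregate_oracle(base, members, v, sp, graph.element_ids()).items():
        capped = max(-cap, min(cap, raw))
        if capped != 0.0:
            column[u] = capped
    norm = max(abs(s) for s in column.values())
    return {u: s / norm for u, s in column.items()}


def regression_es_oracle(i: np.ndarray, fc: np.ndarray, k: float = 2.0) -> float:
    """ES as the least-squares slope through the origin of the diagonal
    projection (x = FC*|I|, y = |FC|*I) augmented with two baseline points
    (+sqrt(k/2), 0) and (-sqrt(k/2), 0)."""
    i = np.asarray(i, float)
    fc = np.asarray(fc, float)
    x = np.concatenate([fc * np.abs(i), [np.sqrt(k / 2), -np.sqrt(k / 2)]])
    y = np.concatenate([np.abs(fc) * i, [0.0, 0.0]])
    slope, *_ = np.linalg.lstsq(x[:, None], y, rcond=None)
    return float(slope[0])


def bh_oracle(p: np.ndarray) -> np.ndarray:
    """Step-up Benjamini-Hochberg by the textbook recipe."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running = min(running, p[idx] * m / rank_from_top)
        adjusted[idx] = running
    return adjusted
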