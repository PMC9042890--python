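"""Context-specific influence scores on the interaction map.

An influence score ``I(u, v)`` in ``[-1, 1]`` quantifies the hypothesized
directed effect of element ``u`` on element ``v``: ``+1`` a strong positive
effect, ``-1`` a strong negative effect, ``0`` (absent entry) no effect.
Three contexts route the underlying paths differently:

* **transcriptional** — effect of ``u`` on the transcription of gene ``v``,
  routed through ``v``'s transcription factors.  A TF's own influence is
  the sign of its edge into ``v`` (+1 induction, -1 suppression); any other
  element aggregates the TF influences it can reach within two steps,
  halved per step: ``sum_k I(k,v) * T(SP_{u,k}) / 2^L(SP_{u,k})`` over TFs
  ``k`` with ``L <= 2``, hard-clamped to ``[-1, 1]``.
* **catalytic** — effect on the synthesis of metabolite ``v``, identically
  structured with ``v``'s enzymes (+1 synthesis, -1 consumption) in place
  of the TFs.
* **phenotype** — topological inclusion of submap element ``u`` in the
  curated paths regulating phenotype ``v``: the base score is
  ``T(SP_{u,v}) * (N_Pu/N_P + N_Vu/N_V)`` from the counted-path statistics;
  non-submap elements aggregate as above with their magnitude capped at the
  largest base magnitude, and the finished column is divided by its maximum
  absolute value so it spans ``[-1, 1]``.

Pairs whose shortest path is sign-inconsistent contribute zero.  Self
influence ``I(v, v)`` is never computed or stored.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Mapping

from .mim import BioType, MIMGraph
from .paths import (
    DEFAULT_MAX_PATH_LEN,
    PathTable,
    signed_bfs,
    submap_path_stats,
    upstream_within,
)

logger = logging.getLogger("twodea.influence")

__all__ = [
    "CONTEXTS",
    "InfluenceTable",
    "transcriptional_influence",
    "catalytic_influence",
    "phenotype_influence",
    "build_influence",
]

CONTEXTS = ("transcriptional", "catalytic", "phenotype")

#: recursion horizon: aggregated scores only consult shortest paths of <= 2 edges
AGGREGATION_DEPTH = 2


class InfluenceTable:
    """Sparse ``(u, v) -> score`` table for one context.

    Zero scores are never stored (absent means "no effect").  ``base_pairs``
    records which entries come from the piecewise base case (direct
    regulators / submap members) versus step-wise aggregation.
    """

    def __init__(
        self,
        context: str,
        columns: Mapping[str, Mapping[str, float]] | None = None,
        base_pairs: Iterable[tuple[str, str]] = (),
    ):
        if context not in CONTEXTS:
            raise ValueError(f"unknown influence context {context!r}")
        self.context = context
        self._columns: dict[str, dict[str, float]] = {}
        if columns:
            for v, col in columns.items():
                self._columns[v] = {u: float(s) for u, s in col.items() if s != 0.0}
        self._base = set(base_pairs)
        self._rows: dict[str, dict[str, float]] | None = None

    # ------------------------------------------------------------------

    def set_column(
        self, v: str, column: Mapping[str, float], base: Iterable[str] = ()
    ) -> None:
        self._columns[v] = {u: float(s) for u, s in column.items() if s != 0.0}
        self._base |= {(u, v) for u in base}
        self._rows = None

    def targets(self) -> list[str]:
        return sorted(self._columns)

    def column(self, v: str) -> dict[str, float]:
        return dict(self._columns.get(v, {}))

    def get(self, u: str, v: str) -> float:
        return self._columns.get(v, {}).get(u, 0.0)

    def row(self, u: str) -> dict[str, float]:
        return dict(self._transposed().get(u, {}))

    def sources(self) -> list[str]:
        return sorted(self._transposed())

    def _transposed(self) -> dict[str, dict[str, float]]:
        if self._rows is None:
            rows: dict[str, dict[str, float]] = defaultdict(dict)
            for v, col in self._columns.items():
                for u, s in col.items():
                    rows[u][v] = s
            self._rows = dict(rows)
        return self._rows

    def provenance(self, u: str, v: str) -> str | None:
        if self.get(u, v) == 0.0:
            return None
        return "base" if (u, v) in self._base else "aggregated"

    def __len__(self) -> int:
        return sum(len(col) for col in self._columns.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InfluenceTable):
            return NotImplemented
        # empty columns (targets with no regulators) carry no scores and
        # are not preserved by the sparse serializations
        return self.context == other.context and {
            v: col for v, col in self._columns.items() if col
        } == {v: col for v, col in other._columns.items() if col}

    # ------------------------------------------------------------------
    # persistence (TSV and sparse-triplet JSON; both round-trip exactly)

    def to_tsv(self, dest: str | Path) -> None:
        with open(dest, "w", encoding="utf-8") as fh:
            fh.write(f"# context: {self.context}\n")
            fh.write("source\ttarget\tcontext\tscore\n")
            for v in self.targets():
                for u in sorted(self._columns[v]):
                    fh.write(
                        f"{u}\t{v}\t{self.context}\t"
                        f"{self._columns[v][u]!r}\n"
                    )

    @classmethod
    def from_tsv(cls, source: str | Path) -> "InfluenceTable":
        columns: dict[str, dict[str, float]] = defaultdict(dict)
        context = None
        with open(source, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("# context:"):
                    context = line.partition(":")[2].strip()
                    continue
                if not line.strip() or line.startswith(("#", "source\t")):
                    continue
                u, v, ctx, score = line.split("\t")
                context = context or ctx
                columns[v][u] = float(score)
        if context is None:
            raise ValueError(f"{source}: not an influence table (no context)")
        return cls(context, columns)

    def to_json(self, dest: str | Path) -> None:
        triplets = [
            [u, v, self._columns[v][u]]
            for v in self.targets()
            for u in sorted(self._columns[v])
        ]
        with open(dest, "w", encoding="utf-8") as fh:
            json.dump({"context": self.context, "scores": triplets}, fh)
            fh.write("\n")

    @classmethod
    def from_json(cls, source: str | Path) -> "InfluenceTable":
        with open(source, encoding="utf-8") as fh:
            doc = json.load(fh)
        columns: dict[str, dict[str, float]] = defaultdict(dict)
        for u, v, score in doc["scores"]:
            columns[v][u] = float(score)
        return cls(doc["context"], columns)


# ----------------------------------------------------------------------
# column builders


def _net_edge_signs(graph: MIMGraph, v: str, iclass_value: str) -> dict[str, float]:
    """Net sign of direct in-edges of class ``iclass_value`` into ``v``.

    Parallel edges of opposite sign from the same source cancel to zero and
    are dropped (logged): the map then asserts no net direct effect.
    """
    net: dict[str, int] = defaultdict(int)
    for edge in graph.in_edges(v):
        if edge.iclass.value == iclass_value:
            net[edge.source] += edge.relation
    base: dict[str, float] = {}
    for u, total in net.items():
        if total > 0:
            base[u] = 1.0
        elif total < 0:
            base[u] = -1.0
        else:
            logger.info("opposite parallel edges %s->%s cancel; no entry", u, v)
    return base


def _upstream_records(
    graph: MIMGraph, k: str, paths: PathTable | None
) -> Iterable[tuple[str, int, int | None]]:
    """``(u, L, T)`` for all ``u`` with ``L(SP_{u,k}) <= 2``."""
    if paths is not None:
        for rec in paths.sources_to(k, max_length=AGGREGATION_DEPTH):
            yield rec.source, rec.length, rec.sign
    else:
        for u, (length, sign) in upstream_within(graph, k, AGGREGATION_DEPTH).items():
            yield u, length, sign


def _aggregate(
    graph: MIMGraph,
    v: str,
    base: Mapping[str, float],
    exclude: frozenset,
    paths: PathTable | None,
) -> dict[str, float]:
    """Step-wise aggregation: for each ``u`` outside the base regulator set
    but within two steps of a base regulator ``k``, sum
    ``I(k,v) * T(SP_{u,k}) / 2^L``.  The piecewise definition is exclusive,
    so every member of the base set (``exclude``) is skipped even when its
    own base score is zero.  Inconsistent shortest paths (``T`` ambiguous)
    contribute nothing."""
    agg: dict[str, float] = defaultdict(float)
    for k, score in base.items():
        for u, length, sign in _upstream_records(graph, k, paths):
            if u == v or u in exclude:
                continue
            if sign is None:
                logger.debug("inconsistent SP %s->%s skipped", u, k)
                continue
            agg[u] += score * sign / (2 ** length)
    return dict(agg)


def _clamp(x: float) -> float:
    return max(-1.0, min(1.0, x))


def transcriptional_influence(
    graph: MIMGraph, v: str, paths: PathTable | None = None
) -> tuple[dict[str, float], frozenset]:
    """Influence of every connected element on the transcription of gene
    ``v``.  Returns ``(column, base_regulators)``; empty when ``v`` has no
    transcription factors."""
    graph.element(v)
    base = _net_edge_signs(graph, v, "transcriptional")
    column = dict(base)
    for u, raw in _aggregate(
        graph, v, base, graph.transcription_factors(v), paths
    ).items():
        clamped = _clamp(raw)
        if clamped != 0.0:
            column[u] = clamped
    column.pop(v, None)
    return column, frozenset(base)


def catalytic_influence(
    graph: MIMGraph, v: str, paths: PathTable | None = None
) -> tuple[dict[str, float], frozenset]:
    """Influence of every connected element on the synthesis of metabolite
    ``v`` (+1 synthesis, -1 consumption at the base case)."""
    graph.element(v)
    base = _net_edge_signs(graph, v, "catalytic")
    column = dict(base)
    for u, raw in _aggregate(
        graph, v, base, graph.synthesizing_enzymes(v), paths
    ).items():
        clamped = _clamp(raw)
        if clamped != 0.0:
            column[u] = clamped
    column.pop(v, None)
    return column, frozenset(base)


def phenotype_influence(
    graph: MIMGraph,
    v: str,
    paths: PathTable | None = None,
    max_path_len: int = DEFAULT_MAX_PATH_LEN,
) -> tuple[dict[str, float], frozenset]:
    """Influence of every connected element on phenotype ``v``.

    Submap members score by their topological inclusion in counted paths to
    ``v``; other elements aggregate over submap members within two steps,
    capped at the largest base magnitude.  The finished column is divided by
    its maximum absolute value, so a nonempty column always contains at
    least one entry of magnitude 1.
    """
    stats = submap_path_stats(graph, v, max_path_len)
    if stats.n_paths == 0:
        logger.warning("phenotype %s has no curated submap regulators", v)
        return {}, frozenset()

    members = graph.submap_neighbours(v)
    sub = graph.induced_subgraph(set(members) | {v})
    to_v = signed_bfs(sub, v, reverse=True)

    base: dict[str, float] = {}
    for u in stats.on_path:
        length_sign = to_v.get(u)
        if length_sign is None:
            continue  # path longer than BFS horizon cannot happen (no cap here)
        _, sign = length_sign
        if sign is None:
            logger.info("inconsistent submap SP %s->%s contributes 0", u, v)
            continue
        raw = sign * (
            stats.paths_through[u] / stats.n_paths
            + len(stats.on_path[u]) / stats.n_connected
        )
        if raw != 0.0:
            base[u] = raw

    if not base:
        return {}, frozenset()

    cap = max(abs(s) for s in base.values())
    column = dict(base)
    for u, raw in _aggregate(graph, v, base, members, paths).items():
        capped = max(-cap, min(cap, raw))
        if capped != 0.0:
            column[u] = capped
    column.pop(v, None)

    norm = max(abs(s) for s in column.values())
    column = {u: s / norm for u, s in column.items()}
    return column, frozenset(base)


_DEFAULT_TARGET_TYPES = {
    "transcriptional": BioType.GENE,
    "catalytic": BioType.METABOLITE,
    "phenotype": BioType.PHENOTYPE,
}

_BUILDERS = {
    "transcriptional": transcriptional_influence,
    "catalytic": catalytic_influence,
    "phenotype": phenotype_influence,
}


def build_influence(
    graph: MIMGraph,
    context: str,
    targets: Iterable[str] | str = "all",
    paths: PathTable | None = None,
    max_path_len: int = DEFAULT_MAX_PATH_LEN,
) -> InfluenceTable:
    """Build the full sparse influence table for one context.

    ``targets="all"`` selects every element of the context's natural type
    (genes / metabolites / phenotypes).  Column order is deterministic
    (sorted ids), so rebuilt and reloaded tables compare equal.
    """
    if context not in CONTEXTS:
        raise ValueError(f"unknown influence context {context!r}")
    if isinstance(targets, str):
        if targets != "all":
            raise ValueError("targets must be an id collection or 'all'")
        target_ids = graph.elements_of_type(_DEFAULT_TARGET_TYPES[context])
    else:
        target_ids = sorted(targets)

    table = InfluenceTable(context)
    builder = _BUILDERS[context]
    for v in target_ids:
        if context == "phenotype":
            column, base = builder(graph, v, paths, max_path_len)
        else:
            column, base = builder(graph, v, paths)
        table.set_column(v, column, base)
    return table
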