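"""Signed molecular interaction map (MIM): data model, readers and writers.

A molecular interaction map is the "bottom layer" of a disease map: the
aggregation of all curated submaps plus regulatory interactions
(transcription factors, miRNAs, lncRNAs, enzymes) into one signed, typed
directed graph.  In the reduced activity-flow form every interaction is a
triple ``(source, relation, target)`` with ``relation`` either ``+1``
(activation, synthesis, induction) or ``-1`` (inhibition, consumption,
suppression).  Elements carry a biological type and a (possibly empty) set
of submap memberships; both annotations drive the context-specific
influence-score calculations downstream.

Two on-disk dialects are supported:

* JSON — ``{"elements": [{"id", "name", "type", "submaps", "xrefs"}]}`` and
  ``{"interactions": [{"source", "sign", "target", "class"}]}``.  The field
  names are this package's own documented schema; the upstream disease-map
  servers publish similar element/interaction JSON pairs but do not document
  a canonical schema, so an adapter layer may be needed for real dumps.
* TSV — a 4-column interaction table (``source  sign  target  class``) with
  a companion element table (``id  name  type  submaps``); header row
  required, ``#`` lines ignored, submaps ``;``-separated.
"""

from __future__ import annotations

import dataclasses
import enum
import hashlib
import json
import logging
from collections import Counter, defaultdict
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

logger = logging.getLogger("twodea.mim")

__all__ = [
    "BioType",
    "InteractionClass",
    "Element",
    "Interaction",
    "MIMGraph",
    "MIMError",
    "MIMLoadError",
    "ValidationReport",
    "load_mim",
    "save_mim",
    "canonical_json",
    "validate",
]


class MIMError(Exception):
    """Base class for map-related errors."""


class MIMLoadError(MIMError):
    """A map file failed to parse or violated a structural invariant."""


class BioType(str, enum.Enum):
    """Biological type of a map element."""

    GENE = "gene"
    PROTEIN = "protein"
    METABOLITE = "metabolite"
    PHENOTYPE = "phenotype"
    COMPLEX = "complex"
    MIRNA = "miRNA"
    LNCRNA = "lncRNA"
    OTHER = "other"

    @classmethod
    def coerce(cls, value: object) -> "BioType":
        """Map a raw type string to a :class:`BioType`.

        Unknown types map to :attr:`OTHER` with a logged warning; they are
        never dropped silently.
        """
        text = str(value).strip()
        for member in cls:
            if member.value.lower() == text.lower():
                return member
        logger.warning("unknown biological type %r mapped to 'other'", value)
        return cls.OTHER


class InteractionClass(str, enum.Enum):
    """Regulatory class of an interaction.

    ``transcriptional`` edges into a gene define its transcription-factor
    set, ``catalytic`` edges into a metabolite define its enzyme set
    (synthesis ``+1`` / consumption ``-1``); everything else is ``generic``
    signalling.
    """

    TRANSCRIPTIONAL = "transcriptional"
    CATALYTIC = "catalytic"
    GENERIC = "generic"

    @classmethod
    def coerce(cls, value: object) -> "InteractionClass":
        if value is None or str(value).strip() == "":
            logger.warning("interaction without class defaulted to 'generic'")
            return cls.GENERIC
        text = str(value).strip().lower()
        for member in cls:
            if member.value == text:
                return member
        logger.warning("unknown interaction class %r defaulted to 'generic'", value)
        return cls.GENERIC


# class priority when duplicate (source, sign, target) rows disagree
_CLASS_PRIORITY = {
    InteractionClass.TRANSCRIPTIONAL: 0,
    InteractionClass.CATALYTIC: 1,
    InteractionClass.GENERIC: 2,
}


@dataclasses.dataclass(frozen=True)
class Element:
    """A node of the map: molecule, complex, RNA species or phenotype."""

    id: str
    name: str
    bio_type: BioType
    submaps: frozenset = frozenset()
    xrefs: Mapping[str, str] = dataclasses.field(default_factory=dict)


@dataclasses.dataclass(frozen=True)
class Interaction:
    """A signed directed edge ``source --relation--> target``."""

    source: str
    relation: int
    target: str
    iclass: InteractionClass = InteractionClass.GENERIC

    def key(self) -> tuple:
        return (self.source, self.relation, self.target)


@dataclasses.dataclass
class LoadReport:
    """Row accounting for a (possibly lenient) load."""

    n_element_rows: int = 0
    n_interaction_rows: int = 0
    n_loaded: int = 0
    n_duplicates: int = 0
    violations: list = dataclasses.field(default_factory=list)


@dataclasses.dataclass
class ValidationReport:
    n_elements: int
    n_interactions: int
    by_bio_type: Counter
    by_sign: Counter
    violations: list

    @property
    def ok(self) -> bool:
        return not self.violations


class MIMGraph:
    """Signed, typed molecular interaction graph with regulator caches.

    The constructor validates structural invariants (unique ids, resolvable
    endpoints, legal signs, no self-loops) and builds adjacency indices plus
    per-target regulator caches:

    * ``transcription_factors(v)`` — sources of transcriptional in-edges;
    * ``synthesizing_enzymes(v)`` — sources of catalytic in-edges (synthesis
      carries ``+1``, consumption ``-1``; consuming enzymes are included);
    * ``submap_neighbours(v)`` — the union of members of every submap that
      contains ``v``, excluding ``v`` itself.

    Interactions have set semantics over ``(source, relation, target)``:
    exact duplicates collapse, while ``(s,+1,t)`` and ``(s,-1,t)`` may
    coexist.  Duplicates with conflicting classes resolve to the most
    specific class (transcriptional > catalytic > generic) and are logged.
    """

    def __init__(
        self,
        elements: Iterable[Element],
        interactions: Iterable[Interaction],
        load_report: LoadReport | None = None,
    ):
        self._elements: dict[str, Element] = {}
        for el in elements:
            if el.id in self._elements:
                raise MIMLoadError(f"duplicate element id {el.id!r}")
            self._elements[el.id] = el

        dedup: dict[tuple, Interaction] = {}
        n_dups = 0
        for ia in interactions:
            if ia.relation not in (-1, 1):
                raise MIMLoadError(
                    f"interaction {ia.source!r}->{ia.target!r} has illegal "
                    f"relation {ia.relation!r} (must be -1 or +1)"
                )
            for endpoint in (ia.source, ia.target):
                if endpoint not in self._elements:
                    raise MIMLoadError(
                        f"interaction {ia.source!r}->{ia.target!r} references "
                        f"unknown element id {endpoint!r}"
                    )
            if ia.source == ia.target:
                raise MIMLoadError(f"self-loop on element {ia.source!r} rejected")
            prev = dedup.get(ia.key())
            if prev is None:
                dedup[ia.key()] = ia
            else:
                n_dups += 1
                if _CLASS_PRIORITY[ia.iclass] < _CLASS_PRIORITY[prev.iclass]:
                    logger.warning(
                        "duplicate edge %s->%s: class %s overrides %s",
                        ia.source, ia.target, ia.iclass.value, prev.iclass.value,
                    )
                    dedup[ia.key()] = ia
        self._interactions: list[Interaction] = [
            dedup[k] for k in sorted(dedup, key=lambda k: (k[0], k[2], k[1]))
        ]

        self._out: dict[str, list[Interaction]] = defaultdict(list)
        self._in: dict[str, list[Interaction]] = defaultdict(list)
        for ia in self._interactions:
            self._out[ia.source].append(ia)
            self._in[ia.target].append(ia)

        self._submap_members: dict[str, set] = defaultdict(set)
        for el in self._elements.values():
            for sm in el.submaps:
                self._submap_members[sm].add(el.id)

        self._tf: dict[str, frozenset] = {}
        self._enz: dict[str, frozenset] = {}
        for v in self._elements:
            self._tf[v] = frozenset(
                ia.source for ia in self._in.get(v, ())
                if ia.iclass is InteractionClass.TRANSCRIPTIONAL
            )
            self._enz[v] = frozenset(
                ia.source for ia in self._in.get(v, ())
                if ia.iclass is InteractionClass.CATALYTIC
            )

        self._name_index: dict[str, list[str]] = defaultdict(list)
        for eid in sorted(self._elements):
            self._name_index[self._elements[eid].name.lower()].append(eid)

        self.load_report = load_report
        if load_report is not None:
            load_report.n_duplicates += n_dups
            load_report.n_loaded = len(self._interactions)

    # ------------------------------------------------------------------
    # basic accessors

    @property
    def n_elements(self) -> int:
        return len(self._elements)

    @property
    def n_interactions(self) -> int:
        return len(self._interactions)

    def __contains__(self, eid: str) -> bool:
        return eid in self._elements

    def element(self, eid: str) -> Element:
        try:
            return self._elements[eid]
        except KeyError:
            raise KeyError(f"element id {eid!r} not in map") from None

    def element_ids(self) -> list[str]:
        return sorted(self._elements)

    def elements(self) -> Iterator[Element]:
        for eid in sorted(self._elements):
            yield self._elements[eid]

    def interactions(self) -> Sequence[Interaction]:
        return tuple(self._interactions)

    def out_edges(self, u: str) -> Sequence[Interaction]:
        return tuple(self._out.get(u, ()))

    def in_edges(self, v: str) -> Sequence[Interaction]:
        return tuple(self._in.get(v, ()))

    def elements_of_type(self, bio_type: BioType) -> list[str]:
        return sorted(
            eid for eid, el in self._elements.items() if el.bio_type is bio_type
        )

    def phenotypes(self) -> list[str]:
        return self.elements_of_type(BioType.PHENOTYPE)

    def submap_members(self, submap: str) -> frozenset:
        return frozenset(self._submap_members.get(submap, ()))

    # ------------------------------------------------------------------
    # regulator sets

    def transcription_factors(self, v: str) -> frozenset:
        self.element(v)
        return self._tf[v]

    def synthesizing_enzymes(self, v: str) -> frozenset:
        self.element(v)
        return self._enz[v]

    def submap_neighbours(self, v: str) -> frozenset:
        """Elements sharing a submap with ``v``, excluding ``v``."""
        el = self.element(v)
        members: set = set()
        for sm in el.submaps:
            members |= self._submap_members[sm]
        members.discard(v)
        return frozenset(members)

    def regulator_sets(self, v: str) -> tuple[frozenset, frozenset, frozenset]:
        """Return ``(TF_v, E_v, V_s(v))`` for element ``v``."""
        return (
            self.transcription_factors(v),
            self.synthesizing_enzymes(v),
            self.submap_neighbours(v),
        )

    # ------------------------------------------------------------------
    # symbol matching (data-file identifiers)

    def match_symbol(self, symbol: str) -> str | None:
        """Resolve a data-file symbol: exact id first, then name
        (case-insensitive).  Ambiguous names resolve to the lowest id and
        are logged."""
        if symbol in self._elements:
            return symbol
        hits = self._name_index.get(symbol.lower(), [])
        if not hits:
            return None
        if len(hits) > 1:
            logger.warning(
                "symbol %r matches %d elements; using %s", symbol, len(hits), hits[0]
            )
        return hits[0]

    # ------------------------------------------------------------------
    # derived graphs

    def induced_subgraph(self, node_ids: Iterable[str]) -> "MIMGraph":
        keep = set(node_ids)
        missing = keep - set(self._elements)
        if missing:
            raise KeyError(f"unknown element ids {sorted(missing)!r}")
        els = [self._elements[eid] for eid in sorted(keep)]
        ias = [
            ia for ia in self._interactions
            if ia.source in keep and ia.target in keep
        ]
        return MIMGraph(els, ias)

    # ------------------------------------------------------------------
    # serialization

    def to_json_objects(self) -> tuple[dict, dict]:
        elements = [
            {
                "id": el.id,
                "name": el.name,
                "type": el.bio_type.value,
                "submaps": sorted(el.submaps),
                "xrefs": dict(sorted(el.xrefs.items())),
            }
            for el in self.elements()
        ]
        interactions = [
            {
                "source": ia.source,
                "sign": ia.relation,
                "target": ia.target,
                "class": ia.iclass.value,
            }
            for ia in sorted(
                self._interactions, key=lambda ia: (ia.source, ia.target, ia.relation)
            )
        ]
        return {"elements": elements}, {"interactions": interactions}

    def checksum(self) -> str:
        return hashlib.sha256(canonical_json(self).encode("utf-8")).hexdigest()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MIMGraph):
            return NotImplemented
        return canonical_json(self) == canonical_json(other)


# ----------------------------------------------------------------------
# loading


def _parse_sign(raw: object, where: str) -> int:
    try:
        value = int(str(raw).strip())
    except (TypeError, ValueError):
        raise MIMLoadError(f"{where}: relation {raw!r} is not an integer") from None
    if value not in (-1, 1):
        raise MIMLoadError(f"{where}: relation {value} outside {{-1, +1}}")
    return value


def _element_from_record(rec: Mapping, where: str) -> Element:
    try:
        eid = str(rec["id"])
        name = str(rec.get("name", eid))
    except KeyError as exc:
        raise MIMLoadError(f"{where}: element record missing field {exc}") from None
    submaps = rec.get("submaps", ())
    if isinstance(submaps, str):
        submaps = [s for s in submaps.split(";") if s.strip()]
    return Element(
        id=eid,
        name=name,
        bio_type=BioType.coerce(rec.get("type", "other")),
        submaps=frozenset(str(s).strip() for s in submaps),
        xrefs=dict(rec.get("xrefs", {}) or {}),
    )


def _interaction_from_record(rec: Mapping, where: str) -> Interaction:
    for field in ("source", "target"):
        if field not in rec:
            raise MIMLoadError(f"{where}: interaction record missing {field!r}")
    return Interaction(
        source=str(rec["source"]),
        relation=_parse_sign(rec.get("sign", rec.get("relation")), where),
        target=str(rec["target"]),
        iclass=InteractionClass.coerce(rec.get("class", rec.get("iclass"))),
    )


def _read_tsv_rows(path: Path) -> tuple[list[str], list[tuple[int, list[str]]]]:
    header: list[str] | None = None
    rows: list[tuple[int, list[str]]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = [f.strip() for f in fields]
            else:
                rows.append((lineno, fields))
    if header is None:
        raise MIMLoadError(f"{path}: empty table (no header row)")
    return header, rows


def _tsv_records(path: Path) -> list[tuple[str, dict]]:
    header, rows = _read_tsv_rows(Path(path))
    records = []
    for lineno, fields in rows:
        if len(fields) < len(header):
            fields = fields + [""] * (len(header) - len(fields))
        rec = dict(zip(header, (f.strip() for f in fields)))
        records.append((f"{path}:{lineno}", rec))
    return records


def load_mim(
    elements_source: str | Path,
    interactions_source: str | Path,
    fmt: str = "json",
    strict: bool = True,
) -> MIMGraph:
    """Load a map from an element table and an interaction table.

    Parameters
    ----------
    fmt:
        ``"json"`` or ``"tsv"`` (see module docstring for the dialects).
    strict:
        When ``True`` (default) any structural violation raises
        :class:`MIMLoadError`.  When ``False`` offending interaction rows
        are dropped and recorded in ``graph.load_report.violations`` so that
        ``input rows == loaded edges + duplicates + violations`` always
        holds.
    """
    elements_source = Path(elements_source)
    interactions_source = Path(interactions_source)
    report = LoadReport()

    if fmt == "json":
        try:
            with open(elements_source, encoding="utf-8") as fh:
                el_doc = json.load(fh)
            with open(interactions_source, encoding="utf-8") as fh:
                ia_doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise MIMLoadError(f"invalid JSON: {exc}") from exc
        el_records = [
            (f"{elements_source}#{i}", rec)
            for i, rec in enumerate(el_doc.get("elements", []))
        ]
        ia_records = [
            (f"{interactions_source}#{i}", rec)
            for i, rec in enumerate(ia_doc.get("interactions", []))
        ]
    elif fmt == "tsv":
        el_records = _tsv_records(elements_source)
        ia_records = _tsv_records(interactions_source)
    else:
        raise ValueError(f"unknown map format {fmt!r}")

    report.n_element_rows = len(el_records)
    report.n_interaction_rows = len(ia_records)

    elements = [_element_from_record(rec, where) for where, rec in el_records]
    known = {el.id for el in elements}

    interactions: list[Interaction] = []
    for where, rec in ia_records:
        try:
            ia = _interaction_from_record(rec, where)
            if ia.source not in known or ia.target not in known:
                dangling = ia.source if ia.source not in known else ia.target
                raise MIMLoadError(
                    f"{where}: interaction {ia.source!r}->{ia.target!r} "
                    f"references unknown element id {dangling!r}"
                )
            if ia.source == ia.target:
                raise MIMLoadError(f"{where}: self-loop on {ia.source!r} rejected")
        except MIMLoadError as exc:
            if strict:
                raise
            report.violations.append(str(exc))
            continue
        interactions.append(ia)

    return MIMGraph(elements, interactions, load_report=report)


def save_mim(
    graph: MIMGraph,
    elements_dest: str | Path,
    interactions_dest: str | Path,
    fmt: str = "json",
) -> None:
    """Write a map in canonical order (elements by id, interactions by
    ``(source, target, sign)``) so that saves are byte-stable."""
    el_doc, ia_doc = graph.to_json_objects()
    if fmt == "json":
        with open(elements_dest, "w", encoding="utf-8") as fh:
            json.dump(el_doc, fh, indent=1, sort_keys=True)
            fh.write("\n")
        with open(interactions_dest, "w", encoding="utf-8") as fh:
            json.dump(ia_doc, fh, indent=1, sort_keys=True)
            fh.write("\n")
    elif fmt == "tsv":
        with open(elements_dest, "w", encoding="utf-8") as fh:
            fh.write("id\tname\ttype\tsubmaps\n")
            for rec in el_doc["elements"]:
                fh.write(
                    f"{rec['id']}\t{rec['name']}\t{rec['type']}\t"
                    f"{';'.join(rec['submaps'])}\n"
                )
        with open(interactions_dest, "w", encoding="utf-8") as fh:
            fh.write("source\tsign\ttarget\tclass\n")
            for rec in ia_doc["interactions"]:
                fh.write(
                    f"{rec['source']}\t{rec['sign']}\t{rec['target']}\t"
                    f"{rec['class']}\n"
                )
    else:
        raise ValueError(f"unknown map format {fmt!r}")


def canonical_json(graph: MIMGraph) -> str:
    """Canonical single-string serialization used for round-trip checks and
    checksums; identical graphs serialize to identical bytes regardless of
    input row order."""
    el_doc, ia_doc = graph.to_json_objects()
    return json.dumps(
        {"elements": el_doc["elements"], "interactions": ia_doc["interactions"]},
        sort_keys=True,
        separators=(",", ":"),
        ensure_ascii=True,
    )


# ----------------------------------------------------------------------
# validation


def validate(graph: MIMGraph) -> ValidationReport:
    """Census and consistency report for a loaded graph.

    Reports element counts per biological type, edge counts per sign, and a
    list of violations: load-time violations (when the graph was loaded
    leniently), adjacency/interaction inconsistencies, and phenotypes that
    are isolated (no submap members and no incoming edges).
    """
    by_bio_type: Counter = Counter()
    for el in graph.elements():
        by_bio_type[el.bio_type.value] += 1
    by_sign: Counter = Counter()
    for ia in graph.interactions():
        by_sign[ia.relation] += 1

    violations: list[str] = []
    if graph.load_report is not None:
        violations.extend(graph.load_report.violations)

    adj_edges = set()
    for u in graph.element_ids():
        for ia in graph.out_edges(u):
            adj_edges.add(ia.key())
    table_edges = {ia.key() for ia in graph.interactions()}
    for key in sorted(adj_edges ^ table_edges):
        violations.append(f"adjacency index out of sync for edge {key!r}")

    for v in graph.phenotypes():
        if not graph.submap_neighbours(v) and not graph.in_edges(v):
            violations.append(f"isolated phenotype {v!r} (no submap members, no in-edges)")

    return ValidationReport(
        n_elements=graph.n_elements,
        n_interactions=graph.n_interactions,
        by_bio_type=by_bio_type,
        by_sign=by_sign,
        violations=violations,
    )
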