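"""Synthetic interaction maps and differential-change datasets.

These generators emulate, at reduced scale, the composition of a curated
disease-map interaction layer — transcription factors wired to genes,
enzymes to metabolites, a generic signalling layer, and phenotypes whose
curated submaps contain a small connected regulator subgraph — together
with differential-change tables of the ``symbol / FC / padj`` shape that
differential-expression pipelines export.  Every generator is a pure
function of its spec and seed.

Fold changes are on the log2 scale throughout.  p-values are *synthetic*:
responders draw adjusted p below the significance threshold and
non-responders above it, which satisfies the filtering contract but does
not model a real differential-expression test.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable

import numpy as np
import pandas as pd

from .mim import BioType, Element, Interaction, InteractionClass, MIMGraph

logger = logging.getLogger("twodea.synthetic")

__all__ = [
    "NetworkSpec",
    "SignalSpec",
    "GenerationError",
    "make_network",
    "make_null_dces",
    "make_planted_dces",
]


class GenerationError(Exception):
    """The requested synthetic dataset is infeasible."""


@dataclasses.dataclass
class NetworkSpec:
    """Composition of a synthetic interaction map.

    Defaults give a ~50-node map (8 TFs, 24 genes, 4 enzymes, 6 metabolites,
    3 phenotypes, 6 signalling proteins) with 30% negative edges —
    proportions chosen to echo a curated map's mix of regulator classes at
    desk scale.
    """

    n_tfs: int = 8
    n_genes: int = 24
    n_enzymes: int = 4
    n_metabolites: int = 6
    n_phenotypes: int = 3
    n_signal: int = 6
    tf_per_gene: tuple = (1, 3)        # inclusive range
    enzymes_per_metabolite: tuple = (1, 2)
    generic_density: float = 0.08      # P(edge) for the signalling layer
    negative_fraction: float = 0.3
    submap_size: tuple = (3, 6)        # regulators per phenotype submap
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_tfs", "n_genes", "n_enzymes", "n_metabolites", "n_phenotypes"):
            if getattr(self, name) < 1:
                raise GenerationError(f"{name} must be positive")
        if not 0.0 <= self.negative_fraction <= 1.0:
            raise GenerationError("negative_fraction must lie in [0, 1]")
        if not 0.0 < self.generic_density <= 1.0:
            raise GenerationError("generic_density must lie in (0, 1]")
        if self.submap_size[0] < 1 or self.submap_size[0] > self.submap_size[1]:
            raise GenerationError("submap_size range is empty")
        if self.submap_size[1] > self.n_genes + self.n_signal:
            raise GenerationError("submaps larger than the available regulator pool")


def _sign(rng: np.random.Generator, neg_fraction: float) -> int:
    return -1 if rng.random() < neg_fraction else 1


def make_network(spec: NetworkSpec = NetworkSpec()) -> MIMGraph:
    """Generate a layered signed digraph from a :class:`NetworkSpec`.

    Layers: TFs -> genes (transcriptional), enzymes -> metabolites
    (catalytic, synthesis or consumption), a generic signalling layer
    (genes/proteins -> TFs/enzymes, TF -> TF), and per-phenotype submaps
    whose members form an acyclic connected subgraph feeding the phenotype.
    Deterministic per seed; the result always passes ``mim.validate`` with
    zero violations and every phenotype has a nonempty submap neighbourhood.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    tfs = [f"TF{i:03d}" for i in range(spec.n_tfs)]
    genes = [f"G{i:03d}" for i in range(spec.n_genes)]
    enzymes = [f"ENZ{i:03d}" for i in range(spec.n_enzymes)]
    metabolites = [f"MET{i:03d}" for i in range(spec.n_metabolites)]
    phenotypes = [f"PHE{i:03d}" for i in range(spec.n_phenotypes)]
    signal = [f"SIG{i:03d}" for i in range(spec.n_signal)]

    submaps: dict[str, set] = {eid: set() for eid in (
        tfs + genes + enzymes + metabolites + phenotypes + signal
    )}
    interactions: list[Interaction] = []
    edge_keys: set = set()

    def add_edge(source: str, relation: int, target: str, iclass: InteractionClass) -> None:
        key = (source, relation, target)
        if source != target and key not in edge_keys:
            edge_keys.add(key)
            interactions.append(Interaction(source, relation, target, iclass))

    # transcriptional layer: every gene gets 1..3 TF regulators
    lo, hi = spec.tf_per_gene
    for g in genes:
        count = int(rng.integers(lo, min(hi, spec.n_tfs) + 1))
        for tf in rng.choice(spec.n_tfs, size=count, replace=False):
            add_edge(tfs[tf], _sign(rng, spec.negative_fraction), g,
                     InteractionClass.TRANSCRIPTIONAL)

    # catalytic layer: synthesis (+1) or consumption (-1) edges
    lo, hi = spec.enzymes_per_metabolite
    for met in metabolites:
        count = int(rng.integers(lo, min(hi, spec.n_enzymes) + 1))
        for enz in rng.choice(spec.n_enzymes, size=count, replace=False):
            add_edge(enzymes[enz], _sign(rng, spec.negative_fraction), met,
                     InteractionClass.CATALYTIC)

    # generic signalling layer feeding the regulators
    sources = genes + signal + tfs
    sinks = tfs + enzymes + signal
    for s in sources:
        for t in sinks:
            if s != t and rng.random() < spec.generic_density:
                add_edge(s, _sign(rng, spec.negative_fraction), t,
                         InteractionClass.GENERIC)

    # phenotype submaps: ordered members, forward edges only (acyclic),
    # every member keeps a path to the phenotype
    pool = genes + signal
    lo, hi = spec.submap_size
    for p_idx, phe in enumerate(phenotypes):
        size = int(rng.integers(lo, hi + 1))
        members = [pool[i] for i in rng.choice(len(pool), size=size, replace=False)]
        sm = f"SM{p_idx:03d}"
        submaps[phe].add(sm)
        for eid in members:
            submaps[eid].add(sm)
        for i, eid in enumerate(members):
            later = members[i + 1:]
            if later and rng.random() < 0.5:
                target = later[int(rng.integers(len(later)))]
            else:
                target = phe
            add_edge(eid, _sign(rng, spec.negative_fraction), target,
                     InteractionClass.GENERIC)
        # guarantee the chain terminates at the phenotype
        add_edge(members[-1], _sign(rng, spec.negative_fraction), phe,
                 InteractionClass.GENERIC)

    def element(eid: str, bio_type: BioType, name: str | None = None) -> Element:
        return Element(
            id=eid,
            name=name or eid,
            bio_type=bio_type,
            submaps=frozenset(submaps[eid]),
        )

    elements = (
        [element(e, BioType.PROTEIN) for e in tfs]
        + [element(e, BioType.GENE) for e in genes]
        + [element(e, BioType.PROTEIN) for e in enzymes]
        + [element(e, BioType.METABOLITE) for e in metabolites]
        + [element(e, BioType.PHENOTYPE) for e in phenotypes]
        + [element(e, BioType.GENE) for e in signal]
    )
    graph = MIMGraph(elements, interactions)
    for phe in phenotypes:
        if not graph.submap_neighbours(phe):
            raise GenerationError(f"phenotype {phe} generated without regulators")
    return graph


def make_null_dces(
    graph: MIMGraph,
    n_dce: int,
    fc_sigma: float = 2.0,
    seed: int = 0,
    bio_type: BioType = BioType.GENE,
    p_threshold: float = 0.05,
    sample: str = "s1",
) -> pd.DataFrame:
    """Topology-independent random differential-change table.

    Identities are drawn uniformly (without replacement) among map elements
    of ``bio_type``; FC ~ Normal(0, ``fc_sigma``) on the log2 scale; adjusted
    p-values sit below ``p_threshold`` by construction so every row passes
    the default filter.
    """
    rng = np.random.default_rng(seed)
    pool = graph.elements_of_type(bio_type)
    if n_dce > len(pool):
        raise GenerationError(
            f"requested {n_dce} DCEs but the map has only {len(pool)} "
            f"elements of type {bio_type.value!r}"
        )
    chosen = [pool[i] for i in rng.choice(len(pool), size=n_dce, replace=False)]
    return pd.DataFrame(
        {
            "symbol": chosen,
            f"FC_{sample}": rng.normal(0.0, fc_sigma, size=n_dce),
            f"padj_{sample}": rng.uniform(0.0, p_threshold, size=n_dce),
        }
    )


@dataclasses.dataclass
class SignalSpec:
    """A planted regulatory signal.

    ``target`` is the element whose downstream influence drives the
    responders; responders receive ``FC = effect * sign(I) + noise`` and a
    significant adjusted p, non-responders pure noise and a non-significant
    p.  Defaults (effect 2 log2 units, half of the influenced elements
    responding, noise sigma 0.5) describe a strong but noisy perturbation.
    """

    target: str
    effect: float = 2.0
    responder_fraction: float = 0.5
    noise_sigma: float = 0.5
    p_threshold: float = 0.05
    seed: int = 0
    sample: str = "s1"


def make_planted_dces(
    graph: MIMGraph,
    influence,
    signal: SignalSpec,
) -> pd.DataFrame:
    """Differential-change table with a planted upstream regulator.

    ``influence`` is an upstream-context table (e.g. transcriptional);
    responders are sampled among elements the planted target influences,
    with fold changes aligned to the influence sign.  All remaining
    elements of the same type appear as non-responders with noise-only FC
    and adjusted p above the threshold (they are removed by the default
    filter, as in a real experiment's non-significant genes).
    """
    if signal.target not in graph:
        raise GenerationError(f"planted target {signal.target!r} not in map")
    rng = np.random.default_rng(signal.seed)
    row = influence.row(signal.target)
    influenced = sorted(u for u, s in row.items() if s != 0.0)
    if len(influenced) < 5:
        raise GenerationError(
            f"planted target {signal.target!r} influences only "
            f"{len(influenced)} elements (need >= 5)"
        )
    n_resp = max(1, int(round(signal.responder_fraction * len(influenced))))
    # strongly influenced elements respond preferentially, mirroring how a
    # real perturbation hits direct targets hardest
    weights = np.array([abs(row[u]) for u in influenced])
    weights = weights / weights.sum()
    responders = [
        influenced[i]
        for i in rng.choice(len(influenced), size=n_resp, replace=False, p=weights)
    ]
    resp_set = set(responders)

    types = {graph.element(u).bio_type for u in influenced}
    universe = sorted({e for t in types for e in graph.elements_of_type(t)})

    symbols: list = []
    fc: list = []
    padj: list = []
    for eid in universe:
        symbols.append(eid)
        if eid in resp_set:
            fc.append(
                signal.effect * np.sign(row[eid])
                + rng.normal(0.0, signal.noise_sigma)
            )
            padj.append(rng.uniform(0.0, signal.p_threshold))
        else:
            fc.append(rng.normal(0.0, signal.noise_sigma))
            padj.append(rng.uniform(signal.p_threshold, 1.0))
    return pd.DataFrame(
        {
            "symbol": symbols,
            f"FC_{signal.sample}": fc,
            f"padj_{signal.sample}": padj,
        }
    )
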