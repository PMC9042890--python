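import numpy as np
import pytest

from twodea.mim import BioType, Element, Interaction, InteractionClass, MIMGraph

TR = InteractionClass.TRANSCRIPTIONAL
CAT = InteractionClass.CATALYTIC
GEN = InteractionClass.GENERIC


def el(eid, bio_type=BioType.PROTEIN, submaps=(), name=None):
    return Element(
        id=eid, name=name or eid, bio_type=bio_type, submaps=frozenset(submaps)
    )


def edge(source, relation, target, iclass=GEN):
    return Interaction(source, relation, target, iclass)


def random_fixture(seed: int, n_nodes: int = 18, edge_factor: float = 2.2) -> MIMGraph:
    """Random signed, typed map with one phenotype + submap, genes with
    transcriptional in-edges and metabolites with catalytic in-edges.
    Structure-free by design: used to exercise every code path against the
    literal-formula oracles."""
    rng = np.random.default_rng(seed)
    ids = [f"N{i:02d}" for i in range(n_nodes)]
    types = {}
    types[ids[0]] = BioType.PHENOTYPE
    for eid in ids[1:]:
        r = rng.random()
        if r < 0.35:
            types[eid] = BioType.GENE
        elif r < 0.50:
            types[eid] = BioType.METABOLITE
        else:
            types[eid] = BioType.PROTEIN

    submap_size = int(rng.integers(3, 7))
    members = [ids[0]] + [
        ids[1 + i] for i in rng.choice(n_nodes - 1, size=submap_size, replace=False)
    ]
    submaps = {eid: ("S0",) if eid in members else () for eid in ids}

    elements = [el(eid, types[eid], submaps[eid]) for eid in ids]
    interactions = []
    p = edge_factor / n_nodes
    for s in ids:
        for t in ids:
            if s == t or rng.random() >= p:
                continue
            sign = -1 if rng.random() < 0.4 else 1
            if types[t] is BioType.GENE and rng.random() < 0.6:
                iclass = TR
            elif types[t] is BioType.METABOLITE and rng.random() < 0.6:
                iclass = CAT
            else:
                iclass = GEN
            interactions.append(edge(s, sign, t, iclass))
    return MIMGraph(elements, interactions)


@pytest.fixture
def toy_gene_map():
    """A -> G (+, transcriptional), B -| G (-, transcriptional), plus an
    upstream activator U -> A."""
    return MIMGraph(
        [
            el("A"), el("B"), el("U"),
            el("G", BioType.GENE),
        ],
        [
            edge("A", 1, "G", TR),
            edge("B", -1, "G", TR),
            edge("U", 1, "A", GEN),
        ],
    )


@pytest.fixture
def toy_metabolite_map():
    """Synthesis/consumption enzymes for metabolite M and an inhibitor of
    the consuming enzyme."""
    return MIMGraph(
        [
            el("SYN"), el("CON"), el("INH"),
            el("M", BioType.METABOLITE),
        ],
        [
            edge("SYN", 1, "M", CAT),
            edge("CON", -1, "M", CAT),
            edge("INH", -1, "CON", GEN),
        ],
    )


@pytest.fixture
def linear_submap():
    """a -> b -> v inside submap S with an outside element x -> a."""
    return MIMGraph(
        [
            el("a", submaps=("S",)),
            el("b", submaps=("S",)),
            el("v", BioType.PHENOTYPE, submaps=("S",)),
            el("x"),
        ],
        [
            edge("a", 1, "b"),
            edge("b", 1, "v"),
            edge("x", 1, "a"),
        ],
    )
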