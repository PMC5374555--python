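"""Synthetic inputs with planted disease modules.

Emulates the structure the method exploits: a scale-free background
interactome (preferential attachment, so degrees are heavy-tailed and the
hub penalty is exercised) with planted disease modules — small gene sets
wired densely among themselves and sparsely to the background. Each
module shares at least one specific GO term annotating only its genes, a
subset of each module is emitted as a protein complex, and the module's
genes form one synthetic disease. Background genes draw annotations from
a pool of large, uninformative terms. A co-occurrence table mixes
above- and below-threshold literature pairs for enrichment tests.

Everything is fully determined by the spec's RNG seed; the reference
benchmark configuration (500 background genes, 20 modules of size 6,
seed 42) is the default.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from .bio import ComplexCatalog, GOAnnotationSet
from .network import CooccurrenceTable, Network
from .prioritize import DiseaseGeneMap

__all__ = ["FixtureSpec", "FixtureBundle", "generate", "degenerate_cases", "write_fixture_files"]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic benchmark generator."""

    n_background: int = 500
    attach_edges: int = 3          # preferential-attachment edges per new node
    n_modules: int = 20
    module_size: int = 6
    p_within: float = 0.8          # within-module edge probability
    p_out: float = 0.01            # module-gene to background-gene edge probability
    terms_per_module: int = 1      # specific GO terms annotating only module genes
    n_background_terms: int = 30
    background_term_size: tuple[int, int] = (40, 120)
    background_terms_per_gene: int = 3
    complex_fraction: float = 0.8  # fraction of each module wrapped as a complex
    n_cooccurrence_pairs: int = 200
    seed: int = 42

    def validate(self) -> None:
        problems = []
        if self.module_size < 3:
            problems.append(f"module_size must be >= 3, got {self.module_size}")
        for name in ("p_within", "p_out", "complex_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                problems.append(f"{name} must be in [0, 1], got {value}")
        # within-module wiring must exceed the expected background density
        n = self.n_background
        background_density = 2.0 * self.attach_edges / max(n - 1, 1)
        if self.p_within <= background_density:
            problems.append(
                f"p_within={self.p_within} must exceed the background density "
                f"~{background_density:.4f}"
            )
        if self.n_background < 10:
            problems.append(f"n_background must be >= 10, got {self.n_background}")
        if self.attach_edges < 1:
            problems.append("attach_edges must be >= 1")
        if problems:
            raise ValueError("invalid fixture spec: " + "; ".join(problems))


@dataclass
class FixtureBundle:
    """The five synthetic inputs produced by :func:`generate`."""

    network: Network
    annotations: GOAnnotationSet
    catalog: ComplexCatalog
    diseases: DiseaseGeneMap
    cooccurrence: CooccurrenceTable
    spec: FixtureSpec


def _module_gene(module: int, j: int) -> str:
    return f"D{module:02d}G{j}"


def generate(spec: FixtureSpec = FixtureSpec()) -> FixtureBundle:
    """Generate the five synthetic inputs from the spec's seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    background = nx.barabasi_albert_graph(spec.n_background, spec.attach_edges, seed=spec.seed)
    graph = nx.relabel_nodes(background, {i: f"BG{i:04d}" for i in background.nodes})
    bg_genes = sorted(graph.nodes)
    nx.set_edge_attributes(graph, 1.0, "weight")

    modules: list[list[str]] = []
    for m in range(spec.n_modules):
        genes = [_module_gene(m, j) for j in range(spec.module_size)]
        modules.append(genes)
        for a in range(spec.module_size):
            for b in range(a + 1, spec.module_size):
                if rng.random() < spec.p_within:
                    graph.add_edge(genes[a], genes[b], weight=1.0)
        # sparse wiring to the background
        mask = rng.random((spec.module_size, spec.n_background)) < spec.p_out
        for a in range(spec.module_size):
            for b in np.flatnonzero(mask[a]):
                graph.add_edge(genes[a], bg_genes[b], weight=1.0)
        # random-walk rows require degree > 0: tether stray genes to a peer
        for a, g in enumerate(genes):
            if g not in graph or graph.degree(g) == 0:
                peer = genes[(a + 1) % spec.module_size]
                graph.add_edge(g, peer, weight=1.0)
    net = Network(graph)

    all_genes = sorted(graph.nodes)
    gene_to_terms: dict[str, set[str]] = {g: set() for g in all_genes}
    for m, genes in enumerate(modules):
        for k in range(spec.terms_per_module):
            term = f"GO:M{m:02d}T{k}"
            for g in genes:
                gene_to_terms[g].add(term)
    lo, hi = spec.background_term_size
    for i in range(spec.n_background_terms):
        term = f"GO:B{i:04d}"
        size = int(rng.integers(lo, hi + 1))
        for g in rng.choice(all_genes, size=min(size, len(all_genes)), replace=False):
            gene_to_terms[g].add(term)
    # make sure every gene carries some annotation signal
    bg_terms = [f"GO:B{i:04d}" for i in range(spec.n_background_terms)]
    if bg_terms:
        for g in all_genes:
            extra = rng.choice(bg_terms, size=min(spec.background_terms_per_gene, len(bg_terms)),
                               replace=False)
            gene_to_terms[g].update(extra)
    annot = GOAnnotationSet(gene_to_terms)

    complexes: dict[str, set[str]] = {}
    for m, genes in enumerate(modules):
        size = max(2, int(round(spec.complex_fraction * len(genes))))
        members = rng.choice(genes, size=min(size, len(genes)), replace=False)
        complexes[f"CPX{m:02d}"] = set(members)
    catalog = ComplexCatalog.from_mapping(complexes)

    diseases = DiseaseGeneMap.from_mapping(
        {f"DIS{m:02d}": set(genes) for m, genes in enumerate(modules)}
    )

    cooc_records = []
    seen = set()
    while len(cooc_records) < spec.n_cooccurrence_pairs:
        a, b = rng.choice(all_genes, size=2, replace=False)
        key = frozenset((a, b))
        if key in seen:
            continue
        seen.add(key)
        count = int(rng.integers(1, 60))
        cooc_records.append((a, b, count))
    cooccurrence = CooccurrenceTable.from_records(cooc_records)

    return FixtureBundle(net, annot, catalog, diseases, cooccurrence, spec)


def degenerate_cases() -> list[tuple[Network, str]]:
    """Small pathological graphs reused across the unit tests."""
    def from_edges(edges):
        g = nx.Graph()
        g.add_edges_from(((u, v, {"weight": 1.0}) for u, v in edges))
        return Network(g)

    dyad = from_edges([("A", "B")])
    path3 = from_edges([("A", "B"), ("B", "C")])
    triangle = from_edges([("A", "B"), ("B", "C"), ("C", "A")])
    star = from_edges([("HUB", leaf) for leaf in "ABCDE"])
    two_cliques = from_edges(
        [("A", "B"), ("B", "C"), ("C", "A"), ("X", "Y"), ("Y", "Z"), ("Z", "X")]
    )
    hub_graph = from_edges(
        [("HUB", n) for n in ("A", "B", "C", "D", "E", "F")] + [("A", "B"), ("C", "D")]
    )
    return [
        (dyad, "isolated dyad"),
        (path3, "three-node path"),
        (triangle, "triangle"),
        (star, "five-leaf star"),
        (two_cliques, "two disconnected triangles"),
        (hub_graph, "hub with six leaves and two chords"),
    ]


def write_fixture_files(bundle: FixtureBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write the bundle in the same text formats the readers consume."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "network": out / "ppi.tsv",
        "annotations": out / "annot.tsv",
        "complexes": out / "complexes.tsv",
        "diseases": out / "diseases.tsv",
        "cooccurrence": out / "cooccurrence.tsv",
    }
    with open(paths["network"], "w") as fh:
        for u, v, w in sorted(bundle.network.edges()):
            fh.write(f"{u}\t{v}\t{w!r}\n")
    with open(paths["annotations"], "w") as fh:
        for gene in sorted(bundle.annotations.gene_to_terms):
            for term in sorted(bundle.annotations.gene_to_terms[gene]):
                fh.write(f"{gene}\t{term}\n")
    with open(paths["complexes"], "w") as fh:
        for c in sorted(bundle.catalog.complexes, key=lambda c: c.complex_id):
            fh.write(f"{c.complex_id}\t{';'.join(sorted(c.members))}\n")
    with open(paths["diseases"], "w") as fh:
        for disease in sorted(bundle.diseases):
            fh.write(f"{disease}\t{';'.join(sorted(bundle.diseases[disease]))}\n")
    with open(paths["cooccurrence"], "w") as fh:
        for a, b, count in bundle.cooccurrence.records:
            fh.write(f"{a}\t{b}\t{count}\n")
    return paths
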