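"""Biological similarity from GO annotations and protein complexes.

Two genes are functionally similar if they share a specific GO term: the
score is the information content -log(min_k |S_k| / S_max) of their most
specific shared term, where |S_k| is the number of genes annotated with
term g_k and S_max the largest annotation size over all terms. All three
GO aspects (biological process, molecular function, cellular component)
are pooled.

Complex similarity sums, over every catalogued complex containing both
genes, a network reliability score: the induced-subgraph density times the
internal-weight ratio w_in / (w_in + w_bound).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .network import Network

logger = logging.getLogger(__name__)

__all__ = [
    "GOAnnotationSet",
    "ComplexCatalog",
    "go_similarity",
    "complex_score",
    "complex_similarity",
    "read_gaf",
    "read_annotation_tsv",
    "read_complexes",
]

# GAF 2.x column offsets (0-based)
_GAF_SYMBOL, _GAF_QUALIFIER, _GAF_GOID, _GAF_EVIDENCE, _GAF_ASPECT = 2, 3, 4, 6, 8


class GOAnnotationSet:
    """Gene -> GO-term mapping with derived per-term annotation sizes.

    ``ancestors`` optionally maps each term to its ancestor terms; when
    supplied, annotations are propagated up before sizes are computed
    (off by default — the similarity operates on directly assigned terms).
    """

    def __init__(
        self,
        gene_to_terms: Mapping[str, Iterable[str]],
        ancestors: Mapping[str, Iterable[str]] | None = None,
    ):
        g2t: dict[str, frozenset[str]] = {}
        for gene, terms in gene_to_terms.items():
            terms = set(terms)
            if ancestors is not None:
                for term in list(terms):
                    terms.update(ancestors.get(term, ()))
            if terms:
                g2t[gene] = frozenset(terms)
        t2g: dict[str, set[str]] = {}
        for gene, terms in g2t.items():
            for term in terms:
                t2g.setdefault(term, set()).add(gene)
        self.gene_to_terms = g2t
        self.term_to_genes = {t: frozenset(g) for t, g in t2g.items()}
        self.term_sizes = {t: len(g) for t, g in self.term_to_genes.items()}
        self.s_max = max(self.term_sizes.values(), default=0)

    def terms(self, gene: str) -> frozenset[str]:
        return self.gene_to_terms.get(gene, frozenset())

    def __contains__(self, gene: str) -> bool:
        return gene in self.gene_to_terms

    def __len__(self) -> int:
        return len(self.gene_to_terms)


def go_similarity(
    annot: GOAnnotationSet, v_i: str, v_j: str, log_base: float | None = None
) -> float:
    """Information content of the most specific shared GO term.

    Returns -log(min_k |S_k| / S_max) over shared terms g_k (natural log
    by default; ``log_base`` rescales). Genes without annotations, or
    pairs sharing no term, score 0.
    """
    if v_i not in annot or v_j not in annot:
        logger.warning("gene %s or %s has no GO annotations; similarity 0",
                       v_i, v_j)
        return 0.0
    shared = annot.terms(v_i) & annot.terms(v_j)
    if not shared:
        return 0.0
    min_size = min(annot.term_sizes[t] for t in shared)
    value = -math.log(min_size / annot.s_max)
    if log_base is not None:
        value /= math.log(log_base)
    return value


@dataclass(frozen=True)
class ProteinComplex:
    complex_id: str
    members: frozenset[str]


@dataclass
class ComplexCatalog:
    """Named gene sets with network-derived reliability scores."""

    complexes: tuple[ProteinComplex, ...]
    _score_cache: dict = field(default_factory=dict, repr=False)
    _membership_cache: dict = field(default_factory=dict, repr=False)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Iterable[str]]) -> "ComplexCatalog":
        return cls(tuple(
            ProteinComplex(cid, frozenset(members)) for cid, members in mapping.items()
        ))

    def scores(self, net: Network) -> dict[str, float]:
        """Reliability score of every complex against ``net`` (cached)."""
        key = id(net)
        if key not in self._score_cache:
            self._score_cache[key] = {
                c.complex_id: complex_score(net, c.members) for c in self.complexes
            }
        return self._score_cache[key]

    def complexes_of(self, gene: str) -> tuple[str, ...]:
        if not self._membership_cache:
            member_of: dict[str, list[str]] = {}
            for c in self.complexes:
                for g in c.members:
                    member_of.setdefault(g, []).append(c.complex_id)
            self._membership_cache.update(member_of)
            self._membership_cache.setdefault("", [])
        return tuple(self._membership_cache.get(gene, ()))

    def __len__(self) -> int:
        return len(self.complexes)


def complex_score(net: Network, members: Iterable[str]) -> float:
    """Network reliability score of one complex: density × w_in/(w_in+w_bound).

    Density is 2|E_C| / (|V_C|(|V_C|-1)) on the subgraph induced by the
    members present in the network; w_in is the total internal edge
    weight, w_bound the total weight of edges leaving the complex.
    Complexes with fewer than two present members, or with no internal
    interaction, score 0.
    """
    present = [g for g in set(members) if g in net]
    n = len(present)
    if n < 2:
        return 0.0
    present_set = set(present)
    w_in = 0.0
    n_internal = 0
    w_bound = 0.0
    for g in present:
        for nb in net.neighbors(g):
            w = net.weight(g, nb)
            if nb in present_set:
                w_in += w
                n_internal += 1
            else:
                w_bound += w
    w_in /= 2.0  # each internal edge visited from both endpoints
    n_internal //= 2
    if w_in == 0.0:
        return 0.0
    density = 2.0 * n_internal / (n * (n - 1))
    return density * w_in / (w_in + w_bound)


def complex_similarity(
    catalog: ComplexCatalog, net: Network, v_i: str, v_j: str
) -> float:
    """Sum of reliability scores of the complexes containing both genes."""
    shared = set(catalog.complexes_of(v_i)) & set(catalog.complexes_of(v_j))
    if not shared:
        return 0.0
    scores = catalog.scores(net)
    return sum(scores[cid] for cid in shared)


def read_gaf(path: str | Path, exclude_iea: bool = False) -> GOAnnotationSet:
    """Read GO annotations from a GAF 2.x file.

    Uses the DB-object-symbol (col 3), GO id (col 5), evidence (col 7)
    and aspect (col 9) columns; NOT-qualified rows are skipped, and all
    three aspects are pooled. ``exclude_iea`` drops electronically
    inferred annotations.
    """
    gene_to_terms: dict[str, set[str]] = {}
    with open(path) as fh:
        for raw in fh:
            if not raw.strip() or raw.startswith("!"):
                continue
            cols = raw.rstrip("\n").split("\t")
            if len(cols) <= _GAF_ASPECT:
                continue
            if "NOT" in cols[_GAF_QUALIFIER].split("|"):
                continue
            if exclude_iea and cols[_GAF_EVIDENCE] == "IEA":
                continue
            gene_to_terms.setdefault(cols[_GAF_SYMBOL], set()).add(cols[_GAF_GOID])
    return GOAnnotationSet(gene_to_terms)


def read_annotation_tsv(path: str | Path) -> GOAnnotationSet:
    """Read a simplified 2-column ``gene<TAB>GO:id`` annotation table."""
    gene_to_terms: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected gene<TAB>term, got {line!r}")
            gene_to_terms.setdefault(parts[0], set()).add(parts[1])
    return GOAnnotationSet(gene_to_terms)


def read_complexes(path: str | Path) -> ComplexCatalog:
    """Read a ``complex_id<TAB>gene1;gene2;...`` catalog (CORUM-export-like)."""
    mapping: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(
                    f"{path}:{lineno}: expected complex_id<TAB>members, got {line!r}"
                )
            members = {g for g in parts[1].split(";") if g}
            mapping.setdefault(parts[0], set()).update(members)
    return ComplexCatalog.from_mapping(mapping)
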