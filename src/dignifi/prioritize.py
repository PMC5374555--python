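"""Candidate-gene scoring and ranking.

A candidate's score against a disease is the sum, over the disease's
known (seed) genes, of its pairwise similarity to each seed. The pairwise
similarity blends three components with convex weights:

    Sim = (1 - alpha - beta) * topo + alpha * SimGO + beta * SimCOM

Because the three components live on incommensurate scales, each is by
default rescaled by its maximum over all (seed, candidate) pairs of the
current ranking task before blending; ``normalize=False`` gives the raw
blend.

Ranks are pessimistic by default: a candidate's rank is the number of
candidates scoring at least as high, so the target of interest is ranked
last among ties. Candidates with score exactly 0 are ranked at the bottom
(rank = candidate-set size), mirroring the evaluation protocol's rule
that a zero-similarity gene carries no evidence at all.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from . import topo
from .bio import ComplexCatalog, GOAnnotationSet, complex_similarity, go_similarity
from .network import Network

logger = logging.getLogger(__name__)

__all__ = [
    "DiseaseGeneMap",
    "RankingResult",
    "combined_similarity",
    "rank_candidates",
    "rank_genome",
    "read_disease_genes",
]


@dataclass(frozen=True)
class DiseaseGeneMap:
    """Disease id -> set of known causal genes."""

    diseases: dict[str, frozenset[str]]

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Iterable[str]]) -> "DiseaseGeneMap":
        return cls({d: frozenset(genes) for d, genes in mapping.items()})

    def known_in_network(self, disease: str, net: Network) -> frozenset[str]:
        """Known genes restricted to the network; dropped genes are logged."""
        known = self.diseases[disease]
        present = frozenset(g for g in known if g in net)
        dropped = known - present
        if dropped:
            logger.warning("disease %s: %d known gene(s) absent from the network: %s",
                           disease, len(dropped), ", ".join(sorted(dropped)))
        return present

    def __iter__(self):
        return iter(self.diseases)

    def __getitem__(self, disease: str) -> frozenset[str]:
        return self.diseases[disease]

    def __len__(self) -> int:
        return len(self.diseases)


@dataclass
class RankingResult:
    """Ordered candidate list for one disease with per-candidate ranks."""

    disease: str
    ranking: list[tuple[str, float]]  # (gene, combined score), descending
    ranks: dict[str, int]
    params: dict = field(default_factory=dict)

    def rank_of(self, gene: str) -> int:
        return self.ranks[gene]

    def top(self, n: int) -> list[tuple[str, float]]:
        return self.ranking[:n]


def _component_matrices(
    net: Network,
    annot: GOAnnotationSet | None,
    catalog: ComplexCatalog | None,
    seeds: Sequence[str],
    candidates: Sequence[str],
    t: int,
    log_base: float | None,
    topo_mode: str,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(seed x candidate) score matrices for topo, SimGO, SimCOM."""
    n_s, n_c = len(seeds), len(candidates)
    topo_m = np.zeros((n_s, n_c))
    go_m = np.zeros((n_s, n_c))
    com_m = np.zeros((n_s, n_c))
    cand_idx = [net.index(c) if c in net else -1 for c in candidates]
    for si, s in enumerate(seeds):
        if topo_mode == "lrw":
            vec = topo.lrw_scores_from(net, s, t)
        else:
            vec = topo.topo_scores_from(net, s, t)
        for ci, (c, idx) in enumerate(zip(candidates, cand_idx)):
            if idx >= 0 and c != s:
                topo_m[si, ci] = vec[idx]
            if annot is not None:
                go_m[si, ci] = go_similarity(annot, s, c, log_base=log_base)
            if catalog is not None:
                com_m[si, ci] = complex_similarity(catalog, net, s, c)
    return topo_m, go_m, com_m


def _normalize(matrix: np.ndarray) -> np.ndarray:
    peak = matrix.max()
    return matrix / peak if peak > 0 else matrix


def combined_similarity(
    net: Network,
    annot: GOAnnotationSet | None,
    catalog: ComplexCatalog | None,
    v_i: str,
    v_j: str,
    alpha: float = 0.1,
    beta: float = 0.1,
    t: int = topo.DEFAULT_STEPS,
    log_base: float | None = None,
) -> float:
    """Raw blended similarity of one pair (no ranking-context rescaling)."""
    if alpha + beta > 1:
        raise ValueError(f"alpha + beta must be <= 1, got {alpha} + {beta}")
    score = 0.0
    topo_w = 1.0 - alpha - beta
    if topo_w > 0:
        score += topo_w * topo.topo_similarity(net, v_i, v_j, t)
    if alpha > 0 and annot is not None:
        score += alpha * go_similarity(annot, v_i, v_j, log_base=log_base)
    if beta > 0 and catalog is not None:
        score += beta * complex_similarity(catalog, net, v_i, v_j)
    return score


def _assign_ranks(scores: np.ndarray, tie_rule: str) -> np.ndarray:
    if tie_rule == "pessimistic":
        ranks = rankdata(-scores, method="max")
    elif tie_rule == "average":
        ranks = rankdata(-scores, method="average")
    else:
        raise ValueError(f"unknown tie rule {tie_rule!r}")
    ranks = ranks.astype(float)
    ranks[scores == 0.0] = len(scores)  # zero evidence ranks at the bottom
    return ranks


def rank_candidates(
    net: Network,
    annot: GOAnnotationSet | None,
    catalog: ComplexCatalog | None,
    known: Iterable[str],
    candidates: Iterable[str],
    alpha: float = 0.1,
    beta: float = 0.1,
    t: int = topo.DEFAULT_STEPS,
    normalize: bool = True,
    log_base: float | None = None,
    tie_rule: str = "pessimistic",
    topo_mode: str = "dignifi",
    disease: str = "",
    allow_offnet: bool = False,
) -> RankingResult:
    """Score and rank a candidate set against a disease's known genes.

    ``topo_mode`` selects the topological component: ``"dignifi"`` routes
    adjacent pairs to the direct-neighbor score and the rest to the local
    random walk; ``"lrw"`` uses the walk for every pair. Candidates absent
    from the network score 0 unless ``allow_offnet`` lets their GO/complex
    components through.
    """
    if alpha + beta > 1:
        raise ValueError(f"alpha + beta must be <= 1, got {alpha} + {beta}")
    known = sorted(set(known))
    candidates = sorted(set(candidates))
    if not known:
        raise ValueError("known gene set is empty")
    overlap = set(known) & set(candidates)
    if overlap:
        raise ValueError(f"known and candidate sets overlap: {sorted(overlap)}")
    seeds = [g for g in known if g in net]
    if not seeds:
        raise ValueError("no known gene is present in the network")
    if len(seeds) < len(known):
        logger.warning("%d known gene(s) absent from the network were dropped",
                       len(known) - len(seeds))

    topo_m, go_m, com_m = _component_matrices(
        net, annot, catalog, seeds, candidates, t, log_base, topo_mode
    )
    if not allow_offnet:
        offnet = np.array([c not in net for c in candidates])
        go_m[:, offnet] = 0.0
        com_m[:, offnet] = 0.0
    if normalize:
        topo_m, go_m, com_m = map(_normalize, (topo_m, go_m, com_m))
    combined = (1.0 - alpha - beta) * topo_m + alpha * go_m + beta * com_m
    scores = combined.sum(axis=0)

    ranks = _assign_ranks(scores, tie_rule)
    order = np.lexsort((np.array(candidates), -scores))
    ranking = [(candidates[i], float(scores[i])) for i in order]
    rank_map = {c: int(r) if float(r).is_integer() else float(r)
                for c, r in zip(candidates, ranks)}
    params = dict(alpha=alpha, beta=beta, t=t, normalize=normalize,
                  log_base=log_base, tie_rule=tie_rule, topo_mode=topo_mode)
    return RankingResult(disease=disease, ranking=ranking, ranks=rank_map, params=params)


def rank_genome(
    net: Network,
    annot: GOAnnotationSet | None,
    catalog: ComplexCatalog | None,
    known: Iterable[str],
    alpha: float = 0.1,
    beta: float = 0.1,
    t: int = topo.DEFAULT_STEPS,
    top_n: int = 10,
    **kwargs,
) -> RankingResult:
    """Rank every network gene outside the known set (novel-gene mode).

    Returns the full ranking truncated to the ``top_n`` best candidates;
    ranks are computed over the whole genome-wide candidate set.
    """
    known = set(known)
    candidates = [g for g in net.nodes if g not in known]
    if not candidates:
        raise ValueError("candidate set is empty: known genes cover the whole network")
    result = rank_candidates(
        net, annot, catalog, known, candidates, alpha=alpha, beta=beta, t=t, **kwargs
    )
    result.ranking = result.ranking[: max(top_n, 0)]
    return result


def read_disease_genes(path: str | Path) -> DiseaseGeneMap:
    """Read a ``disease_id<TAB>gene1;gene2;...`` association table."""
    mapping: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected disease<TAB>genes, got {line!r}")
            genes = {g for g in parts[1].split(";") if g}
            mapping.setdefault(parts[0], set()).update(genes)
    return DiseaseGeneMap.from_mapping(mapping)
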