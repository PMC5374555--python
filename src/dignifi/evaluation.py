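"""Leave-one-out decoy evaluation and the random-walk-with-restart baseline.

Each trial removes one known causal gene of a disease (the target), seeds
the ranker with the remaining known genes, and ranks the target inside a
candidate set of the target plus 99 decoy genes drawn uniformly at random
from the network (excluding every known gene of that disease, so fellow
seeds never appear as decoys). A trial succeeds at level k if the target
ranks within the top k; a target with similarity score exactly zero is
ranked at the candidate-set size. success@k is the fraction of successful
trials.

Decoys are redrawn per trial from an RNG seeded by (config seed + trial
index), so a report is reproducible from its seed alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from . import topo
from .bio import ComplexCatalog, GOAnnotationSet
from .network import Network
from .prioritize import DiseaseGeneMap, rank_candidates, _assign_ranks

logger = logging.getLogger(__name__)

__all__ = [
    "EvalConfig",
    "EvalReport",
    "TrialRecord",
    "loocv",
    "success_at_k",
    "rwr_scores",
    "rank_ttest",
    "METHODS",
]

METHODS = ("dignifi", "simgo", "simcom", "simbio", "lrw", "rwr")


@dataclass(frozen=True)
class EvalConfig:
    """Protocol parameters for the leave-one-out decoy benchmark."""

    method: str = "dignifi"
    ks: tuple[int, ...] = tuple(range(1, 11))
    decoys: int = 99
    seed: int = 0
    alpha: float = 0.1
    beta: float = 0.1
    t: int = topo.DEFAULT_STEPS
    restart: float = 0.8
    min_genes: int = 5
    normalize: bool = True
    tie_rule: str = "pessimistic"

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; choose from {METHODS}")
        if self.decoys < 1:
            raise ValueError("decoys must be >= 1")
        if any(k < 1 or k > self.decoys + 1 for k in self.ks):
            raise ValueError("each k must satisfy 1 <= k <= decoys + 1")


@dataclass(frozen=True)
class TrialRecord:
    disease: str
    target: str
    rank: int


@dataclass
class EvalReport:
    """Per-trial target ranks plus aggregated success rates."""

    config: EvalConfig
    records: list[TrialRecord] = field(default_factory=list)

    @property
    def n_trials(self) -> int:
        return len(self.records)

    @property
    def ranks(self) -> list[int]:
        return [r.rank for r in self.records]

    def success_rate(self, k: int) -> float:
        return success_at_k(self.ranks, k)

    def successes(self, k: int) -> int:
        return sum(r <= k for r in self.ranks)

    def summary_rows(self) -> list[tuple[int, int, int, float]]:
        """(k, successes, trials, rate) per configured k."""
        return [(k, self.successes(k), self.n_trials, self.success_rate(k))
                for k in self.config.ks]

    def write_tsv(self, path, detail_path=None) -> None:
        with open(path, "w") as fh:
            fh.write("k\tsuccesses\ttrials\trate\n")
            for k, s, n, rate in self.summary_rows():
                fh.write(f"{k}\t{s}\t{n}\t{rate:.6f}\n")
        if detail_path is not None:
            with open(detail_path, "w") as fh:
                fh.write("disease\ttarget\trank\n")
                for rec in self.records:
                    fh.write(f"{rec.disease}\t{rec.target}\t{rec.rank}\n")


def success_at_k(ranks: Sequence[int], k: int) -> float:
    """Fraction of trials whose target ranked within the top k."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    ranks = list(ranks)
    if not ranks:
        raise ValueError("no trials recorded")
    return sum(r <= k for r in ranks) / len(ranks)


def _method_params(cfg: EvalConfig) -> dict:
    alpha, beta, mode = {
        "dignifi": (0.0, 0.0, "dignifi"),
        "simgo": (cfg.alpha, 0.0, "dignifi"),
        "simcom": (0.0, cfg.beta, "dignifi"),
        "simbio": (cfg.alpha, cfg.beta, "dignifi"),
        "lrw": (0.0, 0.0, "lrw"),
    }[cfg.method]
    return dict(alpha=alpha, beta=beta, topo_mode=mode)


def _rank_trial(
    net: Network,
    annot: GOAnnotationSet | None,
    catalog: ComplexCatalog | None,
    seeds: list[str],
    candidates: list[str],
    target: str,
    cfg: EvalConfig,
) -> int:
    if cfg.method == "rwr":
        p = rwr_scores(net, seeds, restart=cfg.restart)
        scores = np.array(
            [p[net.index(c)] if c in net else 0.0 for c in candidates]
        )
        ranks = _assign_ranks(scores, cfg.tie_rule)
        return int(ranks[candidates.index(target)])
    params = _method_params(cfg)
    result = rank_candidates(
        net, annot, catalog, seeds, candidates,
        t=cfg.t, normalize=cfg.normalize, tie_rule=cfg.tie_rule, **params,
    )
    return int(result.rank_of(target))


def loocv(
    net: Network,
    annot: GOAnnotationSet | None,
    catalog: ComplexCatalog | None,
    diseases: DiseaseGeneMap,
    cfg: EvalConfig,
) -> EvalReport:
    """Run the leave-one-out decoy benchmark over every eligible disease.

    Diseases with fewer than ``cfg.min_genes`` known genes in the network
    are skipped (with a log entry). For each trial the decoy pool is the
    network minus the disease's entire known-gene set; decoys are drawn
    without replacement.
    """
    report = EvalReport(config=cfg)
    all_nodes = np.array(net.nodes)
    trial_index = 0
    for disease in sorted(diseases):
        known = sorted(diseases.known_in_network(disease, net))
        if len(known) < cfg.min_genes:
            logger.info("skipping %s: %d known network gene(s) < min_genes=%d",
                        disease, len(known), cfg.min_genes)
            continue
        known_set = set(known)
        pool = all_nodes[[g not in known_set for g in net.nodes]]
        if len(pool) < cfg.decoys:
            logger.warning("skipping %s: decoy pool smaller than %d", disease, cfg.decoys)
            continue
        for target in known:
            seeds = [g for g in known if g != target]
            rng = np.random.default_rng(cfg.seed + trial_index)
            decoys = rng.choice(pool, size=cfg.decoys, replace=False)
            candidates = sorted([target, *decoys])
            rank = _rank_trial(net, annot, catalog, seeds, candidates, target, cfg)
            report.records.append(TrialRecord(disease, target, rank))
            trial_index += 1
    if not report.records:
        raise ValueError("no disease passed the min_genes filter; nothing evaluated")
    return report


def rwr_scores(
    net: Network,
    seeds: Iterable[str],
    restart: float = 0.8,
    tol: float = 1e-10,
    max_iter: int = 10000,
) -> np.ndarray:
    """Random walk with restart: stationary p of p <- (1-r) P^T p + r p0.

    p0 is uniform over the seed genes; iteration stops when the L1 change
    drops below ``tol``. Returns the stationary probability over all
    network nodes in canonical order.
    """
    seeds = sorted(set(seeds))
    if not seeds:
        raise ValueError("seed set is empty")
    idx = [net.index(s) for s in seeds]
    if not 0 < restart <= 1:
        raise ValueError(f"restart probability must be in (0, 1], got {restart}")
    p0 = np.zeros(net.n_nodes)
    p0[idx] = 1.0 / len(idx)
    if restart == 1.0:
        return p0
    pt = net.transition_matrix().T.tocsr()
    p = p0.copy()
    for _ in range(max_iter):
        p_next = (1.0 - restart) * (pt @ p) + restart * p0
        delta = float(np.abs(p_next - p).sum())
        p = p_next
        if delta < tol:
            return p
    raise RuntimeError(
        f"random walk with restart did not converge within {max_iter} iterations "
        f"(last L1 change {delta:.3e}, tol {tol:.1e})"
    )


def rank_ttest(ranks_a: Sequence[float], ranks_b: Sequence[float]) -> tuple[float, float]:
    """Two-tailed paired t-test on two methods' per-trial rank lists.

    Thin reporting utility for method comparison tables; returns
    (t statistic, p value).
    """
    res = stats.ttest_rel(list(ranks_a), list(ranks_b))
    return float(res.statistic), float(res.pvalue)
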