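"""MAP-Elites search over gene feature sets, baselines, and consensus ranking.

A solution ("individual") is a gene feature set. Its *quality* is the
validation ROC-AUC of the univariate logistic classifier built on its
aggregated score; its *behavior descriptor* is the pair of mean Euclidean
and mean Canberra distances of its member genes' embeddings from the
known-disease-gene anchor centroid — i.e. how mechanistically far from the
known biology the set sits. The archive is a 4x4 grid over descriptor
quartiles holding at most one elite per cell; quartile edges are frozen from
a reference descriptor distribution before the search so cell identity does
not drift.

Baselines: single-generation random search at equal evaluation budget,
NSGA-II (non-dominated sorting + crowding distance with the same variation
operators), and a global gradient-boosted learner over all gene scores.
Consensus ranking counts, across independently seeded runs, how often a
drug's target-gene set overlaps an elite feature set.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .feature_engineering import FeatureSet, canberra, euclidean
from .graph_embeddings import EmbeddingTable
from .kg import KnowledgeGraph
from .scoring_eval import MetricsRecord

log = logging.getLogger(__name__)

GRID = 4  # 4x4 archive over descriptor quartiles


# ---------------------------------------------------------------------------
# descriptors and binning
# ---------------------------------------------------------------------------

def descriptor(feature_set, gene_embeddings: EmbeddingTable, anchor_genes) -> tuple[float, float]:
    """(mean Euclidean, mean Canberra) distance of member genes from the
    anchor-gene centroid."""
    genes = sorted(getattr(feature_set, "genes", feature_set))
    if not genes:
        raise ValueError("feature set is empty")
    for g in genes:
        if g not in gene_embeddings:
            raise KeyError(f"gene lacks an embedding: {g!r}")
    centroid = gene_embeddings.subset(anchor_genes).mean(axis=0)
    de = float(np.mean([euclidean(gene_embeddings.vector(g), centroid) for g in genes]))
    dc = float(np.mean([canberra(gene_embeddings.vector(g), centroid) for g in genes]))
    return de, dc


def bin_descriptor(d: tuple[float, float], edges) -> tuple[int, int]:
    """Right-open quartile binning of a descriptor into the 4x4 grid.

    ``edges`` holds three cut points per axis; values below the minimum map
    to bin 0, values at/above the last cut to bin 3, and a value exactly at a
    cut point falls in the upper bin (right-open convention).
    """
    if edges is None:
        raise ValueError("bin edges are not frozen yet")
    out = []
    for k in range(2):
        e = np.asarray(edges[k], dtype=float)
        if e.size != GRID - 1:
            raise ValueError("each axis needs exactly 3 cut points")
        out.append(int(min(np.searchsorted(e, d[k], side="right"), GRID - 1)))
    return out[0], out[1]


def freeze_edges(descriptors) -> tuple[np.ndarray, np.ndarray]:
    """Quartile cut points (25/50/75th percentiles) per descriptor axis."""
    arr = np.asarray(list(descriptors), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 4:
        raise ValueError("need >= 4 reference descriptors of dimension 2")
    return (
        np.percentile(arr[:, 0], [25, 50, 75]),
        np.percentile(arr[:, 1], [25, 50, 75]),
    )


class DescriptorSpace:
    """Caches per-gene anchor distances and the frozen grid edges."""

    def __init__(self, gene_embeddings: EmbeddingTable, anchor_genes):
        self._emb = gene_embeddings
        self._centroid = gene_embeddings.subset(anchor_genes).mean(axis=0)
        self._cache: dict[str, tuple[float, float]] = {}
        self.edges: tuple[np.ndarray, np.ndarray] | None = None

    def _gene(self, g: str) -> tuple[float, float]:
        if g not in self._cache:
            v = self._emb.vector(g)
            self._cache[g] = (euclidean(v, self._centroid), canberra(v, self._centroid))
        return self._cache[g]

    def descriptor(self, genes) -> tuple[float, float]:
        gs = sorted(getattr(genes, "genes", genes))
        if not gs:
            raise ValueError("feature set is empty")
        vals = np.array([self._gene(g) for g in gs])
        return float(vals[:, 0].mean()), float(vals[:, 1].mean())

    def freeze(self, reference_sets) -> None:
        self.edges = freeze_edges([self.descriptor(fs) for fs in reference_sets])

    def bin(self, d: tuple[float, float]) -> tuple[int, int]:
        return bin_descriptor(d, self.edges)


# ---------------------------------------------------------------------------
# individuals and archive
# ---------------------------------------------------------------------------

@dataclass
class Individual:
    genes: frozenset[str]
    quality: float | None = None
    descriptor: tuple[float, float] | None = None
    bin: tuple[int, int] | None = None
    metrics: MetricsRecord | None = None


class Archive:
    """4x4 grid keeping the single best individual per descriptor cell."""

    def __init__(self, edges):
        if edges is None:
            raise ValueError("archive needs frozen bin edges")
        self.edges = edges
        self.cells: dict[tuple[int, int], Individual] = {}
        self.generation = 0

    def update(self, ind: Individual) -> bool:
        """Insert if the cell is empty; replace only on strictly higher
        quality (ties keep the incumbent, for determinism)."""
        if ind.quality is None or ind.descriptor is None:
            raise ValueError("individual must be evaluated before archiving")
        b = bin_descriptor(ind.descriptor, self.edges)
        ind.bin = b
        incumbent = self.cells.get(b)
        if incumbent is None or ind.quality > incumbent.quality:
            self.cells[b] = ind
            return True
        return False

    @property
    def coverage(self) -> int:
        return len(self.cells)

    @property
    def qd_score(self) -> float:
        return float(sum(e.quality for e in self.cells.values()))

    def elites(self) -> list[Individual]:
        return [self.cells[k] for k in sorted(self.cells)]

    def check_invariants(self) -> None:
        assert len(self.cells) <= GRID * GRID
        for key, e in self.cells.items():
            assert e.bin == key
            assert bin_descriptor(e.descriptor, self.edges) == key
            assert 0.0 <= e.quality <= 1.0

    def to_json(self) -> str:
        payload = {
            "generation": self.generation,
            "edges": [list(map(float, e)) for e in self.edges],
            "cells": {
                f"{k[0]},{k[1]}": {
                    "genes": sorted(e.genes),
                    "quality": e.quality,
                    "descriptor": list(e.descriptor),
                }
                for k, e in sorted(self.cells.items())
            },
        }
        return json.dumps(payload, sort_keys=True, indent=1)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


def archive_update(archive: Archive, ind: Individual) -> bool:
    return archive.update(ind)


# ---------------------------------------------------------------------------
# variation operators
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SearchConfig:
    generations: int = 100
    batch_per_gen: int = 100
    seed: int = 0
    min_size: int = 2
    max_size: int = 200
    p_crossover: float = 0.3
    p_cluster: float = 0.7  # cluster-biased gene addition probability
    n_reference_random: int = 200  # random sets added to the edge-freezing reference


def _gene_pool_index(gene_pools: dict[int, tuple[str, ...]]) -> dict[str, list[int]]:
    idx: dict[str, list[int]] = {}
    for label, pool in gene_pools.items():
        for g in pool:
            idx.setdefault(g, []).append(label)
    return idx


def mutate(
    genes: frozenset[str],
    rng: np.random.Generator,
    universe: list[str],
    gene_pools: dict[int, tuple[str, ...]] | None,
    cfg: SearchConfig,
) -> frozenset[str]:
    """One mutation: add a gene (cluster-biased), remove one, or swap."""
    s = set(genes)
    pool_index = _gene_pool_index(gene_pools) if gene_pools else {}

    def add_gene():
        candidates: list[str] = []
        if s and gene_pools and rng.random() < cfg.p_cluster:
            member = sorted(s)[rng.integers(len(s))]
            labels = pool_index.get(member)
            if labels:
                label = labels[rng.integers(len(labels))]
                candidates = [g for g in gene_pools[label] if g not in s]
        if not candidates:
            candidates = [g for g in universe if g not in s]
        if candidates:
            s.add(candidates[rng.integers(len(candidates))])

    def remove_gene():
        if len(s) > cfg.min_size:
            s.remove(sorted(s)[rng.integers(len(s))])

    op = rng.integers(3)
    if op == 0:
        add_gene()
    elif op == 1:
        remove_gene()
    else:
        remove_gene()
        add_gene()
    while len(s) > cfg.max_size:
        s.remove(sorted(s)[rng.integers(len(s))])
    if not s:  # never emit an empty set
        s.add(universe[rng.integers(len(universe))])
    return frozenset(s)


def crossover(a: frozenset[str], b: frozenset[str], rng: np.random.Generator) -> frozenset[str]:
    """Uniform set crossover: intersection kept, symmetric difference coin-flipped."""
    child = set(a & b)
    for g in sorted(a ^ b):
        if rng.random() < 0.5:
            child.add(g)
    if not child:
        child = set(a)
    return frozenset(child)


def _offspring(parents, rng, universe, gene_pools, cfg) -> frozenset[str]:
    if len(parents) > 1 and rng.random() < cfg.p_crossover:
        genes = crossover(parents[0], parents[1], rng)
    else:
        genes = parents[0]
    return mutate(genes, rng, universe, gene_pools, cfg)


# ---------------------------------------------------------------------------
# searches
# ---------------------------------------------------------------------------

def _evaluate(genes: frozenset[str], evaluate_fn, dspace: DescriptorSpace) -> Individual | None:
    try:
        metrics = evaluate_fn(genes)
    except Exception as exc:
        log.warning("offspring evaluation failed (%s); discarded", exc)
        return None
    return Individual(
        genes=genes,
        quality=float(metrics.roc_auc),
        descriptor=dspace.descriptor(genes),
        metrics=metrics,
    )


def run_map_elites(
    initial_sets: list[FeatureSet],
    evaluate_fn,
    dspace: DescriptorSpace,
    universe: list[str],
    gene_pools: dict[int, tuple[str, ...]] | None = None,
    config: SearchConfig | None = None,
) -> tuple[Archive, pd.DataFrame]:
    """MAP-Elites over gene feature sets.

    ``evaluate_fn(frozenset) -> MetricsRecord`` supplies quality (ROC-AUC).
    If the descriptor-space edges are not frozen yet they are frozen here
    from the initial sets plus ``n_reference_random`` random variants.
    History logs per-generation coverage and QD-score.
    """
    config = config or SearchConfig()
    if not initial_sets:
        raise ValueError("need at least one initial feature set")
    rng = np.random.default_rng(config.seed)
    init_genes = [frozenset(fs.genes) for fs in initial_sets]

    if dspace.edges is None:
        reference = list(init_genes)
        for _ in range(config.n_reference_random):
            base = init_genes[rng.integers(len(init_genes))]
            reference.append(mutate(base, rng, universe, gene_pools, config))
        dspace.freeze(reference)

    archive = Archive(dspace.edges)
    for genes in init_genes:
        ind = _evaluate(genes, evaluate_fn, dspace)
        if ind is not None:
            archive.update(ind)
    history = [(0, archive.coverage, archive.qd_score)]

    for gen in range(1, config.generations + 1):
        elites = archive.elites()
        for _ in range(config.batch_per_gen):
            if not elites:
                break
            i = rng.integers(len(elites))
            j = rng.integers(len(elites))
            parents = (elites[i].genes, elites[j].genes)
            child = _offspring(parents, rng, universe, gene_pools, config)
            ind = _evaluate(child, evaluate_fn, dspace)
            if ind is not None:
                archive.update(ind)
        archive.generation = gen
        archive.check_invariants()
        history.append((gen, archive.coverage, archive.qd_score))

    hist = pd.DataFrame(history, columns=["generation", "coverage", "qd_score"])
    return archive, hist


def run_random_search(
    initial_sets: list[FeatureSet],
    evaluate_fn,
    dspace: DescriptorSpace,
    universe: list[str],
    gene_pools: dict[int, tuple[str, ...]] | None = None,
    budget: int = 10000,
    seed: int = 0,
    config: SearchConfig | None = None,
) -> list[Individual]:
    """Single-generation random baseline: ``budget`` random feature sets
    drawn with the same mutation kernel from the initialization, each
    evaluated once, no archive."""
    if budget < 1:
        raise ValueError("budget must be >= 1")
    config = config or SearchConfig()
    rng = np.random.default_rng(seed)
    init_genes = [frozenset(fs.genes) for fs in initial_sets]
    out = []
    for _ in range(budget):
        genes = init_genes[rng.integers(len(init_genes))]
        for _ in range(int(rng.integers(1, 6))):
            genes = mutate(genes, rng, universe, gene_pools, config)
        ind = _evaluate(genes, evaluate_fn, dspace)
        if ind is not None:
            out.append(ind)
    return out


def top_by_quality(individuals: list[Individual], k: int) -> list[Individual]:
    return sorted(individuals, key=lambda i: (-i.quality, sorted(i.genes)))[:k]


# ---------------------------------------------------------------------------
# NSGA-II baseline
# ---------------------------------------------------------------------------

def _dominates(a: np.ndarray, b: np.ndarray) -> bool:
    return bool((a >= b).all() and (a > b).any())


def fast_non_dominated_sort(objectives: np.ndarray) -> list[list[int]]:
    """Fronts of indices, best first; both objectives are maximized."""
    objs = np.asarray(objectives, dtype=float)
    n = len(objs)
    dominated_by: list[list[int]] = [[] for _ in range(n)]
    counts = np.zeros(n, dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            if _dominates(objs[i], objs[j]):
                dominated_by[i].append(j)
                counts[j] += 1
            elif _dominates(objs[j], objs[i]):
                dominated_by[j].append(i)
                counts[i] += 1
    fronts = [sorted(np.flatnonzero(counts == 0).tolist())]
    while True:
        nxt = []
        for i in fronts[-1]:
            for j in dominated_by[i]:
                counts[j] -= 1
                if counts[j] == 0:
                    nxt.append(j)
        if not nxt:
            return fronts
        fronts.append(sorted(nxt))


def crowding_distance(objectives: np.ndarray, front: list[int]) -> np.ndarray:
    """NSGA-II crowding distance; boundary points get infinity."""
    objs = np.asarray(objectives, dtype=float)[front]
    m = len(front)
    dist = np.zeros(m)
    for k in range(objs.shape[1]):
        order = np.argsort(objs[:, k], kind="stable")
        dist[order[0]] = dist[order[-1]] = np.inf
        span = objs[order[-1], k] - objs[order[0], k]
        if span > 0:
            for r in range(1, m - 1):
                dist[order[r]] += (objs[order[r + 1], k] - objs[order[r - 1], k]) / span
    return dist


def run_nsga2(
    initial_sets: list[FeatureSet],
    evaluate_fn,
    dspace: DescriptorSpace,
    universe: list[str],
    gene_pools: dict[int, tuple[str, ...]] | None = None,
    config: SearchConfig | None = None,
    pop_size: int = 40,
) -> tuple[list[Individual], list[Individual]]:
    """NSGA-II with objectives (quality, mean descriptor novelty), the same
    variation operators as MAP-Elites. Returns (final population, front)."""
    config = config or SearchConfig()
    if pop_size < 4:
        raise ValueError("population must be >= 4")
    rng = np.random.default_rng(config.seed)
    init_genes = [frozenset(fs.genes) for fs in initial_sets]

    if dspace.edges is None:
        dspace.freeze(init_genes + [
            mutate(init_genes[rng.integers(len(init_genes))], rng, universe, gene_pools, config)
            for _ in range(max(4, config.n_reference_random))
        ])

    def novelty(ind: Individual) -> float:
        return float(np.mean(ind.descriptor))

    pop: list[Individual] = []
    k = 0
    while len(pop) < pop_size and k < 10 * pop_size:
        genes = init_genes[k % len(init_genes)]
        if k >= len(init_genes):
            genes = mutate(genes, rng, universe, gene_pools, config)
        ind = _evaluate(genes, evaluate_fn, dspace)
        if ind is not None:
            pop.append(ind)
        k += 1

    def select(population: list[Individual]) -> list[Individual]:
        objs = np.array([[p.quality, novelty(p)] for p in population])
        fronts = fast_non_dominated_sort(objs)
        chosen: list[Individual] = []
        for front in fronts:
            if len(chosen) + len(front) <= pop_size:
                chosen.extend(population[i] for i in front)
            else:
                cd = crowding_distance(objs, front)
                order = np.argsort(-cd, kind="stable")
                need = pop_size - len(chosen)
                chosen.extend(population[front[i]] for i in order[:need])
                break
        return chosen

    for _ in range(config.generations):
        objs = np.array([[p.quality, novelty(p)] for p in pop])
        fronts = fast_non_dominated_sort(objs)
        rank = np.empty(len(pop), dtype=int)
        for r, front in enumerate(fronts):
            rank[front] = r
        offspring = []
        while len(offspring) < pop_size:
            i, j = rng.integers(len(pop), size=2)
            p1 = i if rank[i] < rank[j] else j
            i, j = rng.integers(len(pop), size=2)
            p2 = i if rank[i] < rank[j] else j
            child = _offspring((pop[p1].genes, pop[p2].genes), rng, universe, gene_pools, config)
            ind = _evaluate(child, evaluate_fn, dspace)
            if ind is not None:
                offspring.append(ind)
        pop = select(pop + offspring)

    objs = np.array([[p.quality, novelty(p)] for p in pop])
    front = [pop[i] for i in fast_non_dominated_sort(objs)[0]]
    return pop, front


# ---------------------------------------------------------------------------
# global learner baseline and consensus ranking
# ---------------------------------------------------------------------------

def run_global_baseline(
    gene_scores: pd.DataFrame,
    phenotype: np.ndarray,
    splits: dict[str, np.ndarray],
    seed: int = 0,
    learner_factory=None,
    eval_subset: str = "val",
    threshold: float = 0.5,
) -> MetricsRecord:
    """Pure-exploitation baseline: a strong tabular learner on all gene scores.

    The learner is pluggable via ``learner_factory(seed)``; the default is a
    deep gradient-boosted tree ensemble (XGBoost) with aggressive row/column
    subsampling — the exploitation-heavy regime this framework is contrasted
    against, where independent seeds genuinely differ.
    """
    from .scoring_eval import roc_auc
    from sklearn.metrics import average_precision_score

    if learner_factory is None:
        def learner_factory(s):
            from xgboost import XGBClassifier

            return XGBClassifier(
                n_estimators=60,
                max_depth=6,
                learning_rate=0.1,
                subsample=0.5,
                colsample_bytree=0.5,
                random_state=s,
                n_jobs=1,
                verbosity=0,
            )

    x = gene_scores.to_numpy(float)
    y = np.asarray(phenotype, dtype=int)

    def pick(name):
        m = np.asarray(splits[name])
        idx = np.flatnonzero(m) if m.dtype == bool else m.astype(int)
        return x[idx], y[idx]

    x_tr, y_tr = pick("train")
    x_ev, y_ev = pick(eval_subset)
    if len(np.unique(y_tr)) < 2 or len(np.unique(y_ev)) < 2:
        raise ValueError("train and eval subsets must contain both classes")
    model = learner_factory(seed)
    model.fit(x_tr, y_tr)
    prob = model.predict_proba(x_ev)[:, 1]
    pred = (prob >= threshold).astype(int)
    ad_total = int(y_ev.sum())
    ad_detected = int(((pred == 1) & (y_ev == 1)).sum())
    hc_flagged = int(((pred == 1) & (y_ev == 0)).sum())
    recall = ad_detected / ad_total
    precision = ad_detected / (ad_detected + hc_flagged) if (ad_detected + hc_flagged) else 0.0
    undefined = (precision + recall) == 0
    return MetricsRecord(
        recall=recall,
        precision=precision,
        f1=0.0 if undefined else 2 * precision * recall / (precision + recall),
        roc_auc=roc_auc(prob, y_ev),
        pr_auc=float(average_precision_score(y_ev, prob)),
        ad_total=ad_total,
        hc_total=int((1 - y_ev).sum()),
        ad_detected=ad_detected,
        hc_flagged=hc_flagged,
        f1_undefined=bool(undefined),
    )


def jaccard(a: frozenset, b: frozenset) -> float:
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


def rank_drugs(
    archives: list[Archive],
    kg: KnowledgeGraph,
    tau: float = 0.3,
    q: float | None = None,
    universe=None,
) -> pd.DataFrame:
    """Consensus drug ranking across independently seeded archives.

    Within each run a drug is *retrieved* when its target-gene set has
    Jaccard overlap >= ``tau`` with any elite feature set whose quality is at
    least ``q`` (default: that archive's median elite quality). When a
    ``universe`` of scoreable genes is given, targets are restricted to it
    first — genes without GWAS-mappable variants can never appear in a
    feature set, so counting them against the overlap would only penalize
    well-annotated drugs. Drugs are ranked by retrieval count, ties broken by
    the mean overlap-weighted elite quality.
    """
    if not archives:
        raise ValueError("need at least one archive")
    uni = frozenset(universe) if universe is not None else None
    drugs = kg.drugs()
    counts = {d: 0 for d in drugs}
    weighted = {d: [] for d in drugs}
    for archive in archives:
        elites = archive.elites()
        if not elites:
            continue
        cut = q if q is not None else float(np.median([e.quality for e in elites]))
        elig = [e for e in elites if e.quality >= cut]
        for d in drugs:
            targets = kg.drug_targets(d)
            if uni is not None:
                targets = targets & uni
            overlaps = np.array([jaccard(targets, e.genes) for e in elig])
            if overlaps.size and overlaps.max() >= tau:
                counts[d] += 1
            if overlaps.sum() > 0:
                quals = np.array([e.quality for e in elig])
                weighted[d].append(float((overlaps * quals).sum() / overlaps.sum()))
    rows = [
        (d, counts[d], float(np.mean(weighted[d])) if weighted[d] else 0.0)
        for d in drugs
    ]
    df = pd.DataFrame(rows, columns=["drug_id", "retrieval_count", "mean_weighted_quality"])
    return df.sort_values(
        ["retrieval_count", "mean_weighted_quality", "drug_id"],
        ascending=[False, False, True],
    ).reset_index(drop=True)
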