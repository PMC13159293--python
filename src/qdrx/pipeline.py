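"""End-to-end study orchestration on synthetic data.

`build_study` assembles the full stack the framework expects: a knowledge
graph with an anchored disease module, trained gene and drug encoders, a
planted two-niche phenotype landscape (one predictive gene module inside the
anchor neighborhood, one in the most distant embedding module, plus a
planted drug targeting the distant module), a matched case-control cohort
with optimized 1:1:1 splits, gene scores, and cluster-derived feature sets.

The searches (`run_search`, baselines) then operate on the study artifacts,
so independently seeded runs share data exactly as independent validation
seeds share the cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import Cohort
from .cohort_qc import QCConfig, pca_top8, qc_filter
from .feature_engineering import (
    FeatureConfig,
    FeatureSet,
    build_drug_features,
    canberra,
    cosine_distance,
    derive_feature_sets,
    euclidean,
)
from .graph_embeddings import EmbeddingTable, EncoderConfig, train_drug_encoder, train_gene_encoder
from .kg import DRUG, REL_TARGETS, AnchorSets, KnowledgeGraph
from .matching_split import (
    SplitResult,
    fit_propensity,
    match_pairs,
    matched_cohort,
    optimize_split,
    select_reference_snps,
    split_masks,
)
from .qd_search import (
    Archive,
    DescriptorSpace,
    Individual,
    SearchConfig,
    run_global_baseline,
    run_map_elites,
    run_nsga2,
    run_random_search,
)
from .scoring_eval import MetricsRecord, build_gene_scores, evaluate_feature_set, feature_set_score
from .synthetic_data import SyntheticCohortConfig, SyntheticKGConfig, simulate_cohort, simulate_kg

PLANTED_DRUG = "D_PLANTED"


@dataclass(frozen=True)
class StudyConfig:
    kg: SyntheticKGConfig = field(default_factory=lambda: SyntheticKGConfig(
        n_genes=260, n_drugs=120, n_diseases=4, n_anchor_genes=12, n_anchor_drugs=6
    ))
    module_genes: int = 12  # size of each planted predictive module (~median drug degree)
    embedding_dim: int = 16
    encoder_epochs: int = 150
    n_pairs: int = 300
    n_variants: int = 800
    # the well-characterized (anchor-proximal) module is the better powered
    # signal, as known disease biology is in real cohorts; the distant module
    # is predictive but weaker
    effect_near: float = 0.9
    effect_far: float = 0.75
    confounding: float = 1.0
    fst: float = 0.1
    n_populations: int = 2
    n_reference_snps: int = 30
    n_split_trials: int = 120
    k_clusters: int = 6
    hub_threshold: int = 20


@dataclass
class Study:
    """Everything a search run needs, built once per study seed."""

    config: StudyConfig
    kg: KnowledgeGraph
    anchors: AnchorSets
    gene_embeddings: EmbeddingTable
    drug_embeddings: EmbeddingTable
    near_module: tuple[str, ...]
    far_module: tuple[str, ...]
    cohort: Cohort  # matched analytic cohort
    pcs: np.ndarray
    split: SplitResult
    masks: dict[str, np.ndarray]
    gene_scores: pd.DataFrame
    full_gene_scores: pd.DataFrame  # unfiltered table for the global baseline
    drug_features: pd.DataFrame
    feature_sets: list[FeatureSet]
    gene_pools: dict[int, tuple[str, ...]]
    universe: list[str]
    descriptor_edges: tuple[np.ndarray, np.ndarray] | None = None

    def descriptor_space(self) -> DescriptorSpace:
        """Descriptor space with the study's shared frozen quartile edges, so
        every seeded run maps descriptors onto the same 4x4 grid."""
        ds = DescriptorSpace(self.gene_embeddings, list(self.anchors.genes))
        ds.edges = self.descriptor_edges
        return ds

    def evaluator(self, eval_subset: str = "val"):
        """Memoized feature-set evaluator (univariate logistic, ROC-AUC)."""
        cache: dict[frozenset, MetricsRecord] = {}
        phenotype = self.cohort.phenotype()

        def evaluate(genes: frozenset) -> MetricsRecord:
            if genes not in cache:
                s = feature_set_score(self.gene_scores, genes)
                cache[genes] = evaluate_feature_set(s, phenotype, self.masks, eval_subset)
            return cache[genes]

        return evaluate


def _module_chunks(kg_cfg: SyntheticKGConfig) -> list[list[str]]:
    genes = [f"G{i:04d}" for i in range(kg_cfg.n_genes)]
    rest = genes[kg_cfg.n_anchor_genes :]
    return [rest[i : i + kg_cfg.module_size] for i in range(0, len(rest), kg_cfg.module_size)]


def _farthest_module(chunks, gene_embeddings: EmbeddingTable, anchor_genes) -> list[str]:
    centroid = gene_embeddings.subset(anchor_genes).mean(axis=0)
    best, best_d = None, -np.inf
    for chunk in chunks:
        d = float(np.mean([euclidean(gene_embeddings.vector(g), centroid) for g in chunk]))
        if d > best_d:
            best, best_d = chunk, d
    return best


def build_study(seed: int, config: StudyConfig | None = None) -> Study:
    config = config or StudyConfig()
    seeds = np.random.default_rng(seed).integers(2**31 - 1, size=8)

    kg_cfg = replace(config.kg, seed=int(seeds[0]))
    kg, anchors = simulate_kg(kg_cfg)

    enc = EncoderConfig(
        embedding_dim=config.embedding_dim,
        epochs=config.encoder_epochs,
        seed=int(seeds[1]),
    )
    gene_emb = train_gene_encoder(kg, anchors.genes, enc)

    near = tuple(anchors.genes[: config.module_genes])
    far_chunk = _farthest_module(_module_chunks(kg_cfg), gene_emb, list(anchors.genes))
    far = tuple(far_chunk[: config.module_genes])

    # plant a drug (plus two partial-overlap mates) targeting the far module,
    # so one drug cluster carries the distant predictive mechanism
    kg.add_entity(PLANTED_DRUG, DRUG)
    for g in far:
        kg.add_relation(PLANTED_DRUG, REL_TARGETS, g)
    for k, extra in enumerate(far_chunk[config.module_genes : config.module_genes + 2]):
        mate = f"D_MATE{k}"
        kg.add_entity(mate, DRUG)
        for g in far[: len(far) // 2 + 2]:
            kg.add_relation(mate, REL_TARGETS, g)
        kg.add_relation(mate, REL_TARGETS, extra)

    drug_emb = train_drug_encoder(kg, anchors.drugs, replace(enc, seed=int(seeds[2])))

    # simulate a surplus pool: matching then keeps only the closest pairs, so
    # poorly matched (typically cross-population) pairs are discarded
    cohort_cfg = SyntheticCohortConfig(
        n_pairs=int(round(1.35 * config.n_pairs)),
        n_variants=config.n_variants,
        n_populations=config.n_populations,
        fst_like_divergence=config.fst,
        planted_effect_genes=near + far,
        effect_size=config.effect_near,
        effect_size_by_gene=tuple((g, config.effect_far) for g in far),
        confounding=config.confounding,
        seed=int(seeds[3]),
    )
    raw_cohort = simulate_cohort(cohort_cfg, kg)

    retained, _report = qc_filter(raw_cohort, QCConfig())
    pcs = pca_top8(raw_cohort, retained)
    prop = fit_propensity(pcs, raw_cohort.phenotype())
    pairs = match_pairs(prop.scores, raw_cohort.phenotype())
    pairs = pairs.nsmallest(config.n_pairs, "distance", keep="first")
    cohort = matched_cohort(raw_cohort, pairs)

    refs = select_reference_snps(cohort, n=config.n_reference_snps)
    split = optimize_split(cohort, refs, n_trials=config.n_split_trials, seed=int(seeds[4]))
    masks = split_masks(cohort, split.assignment)

    gene_scores = build_gene_scores(cohort)
    full_gene_scores = build_gene_scores(cohort, p_threshold=1.01)
    feat_cfg = FeatureConfig(
        k_clusters=config.k_clusters, hub_threshold=config.hub_threshold, seed=int(seeds[5])
    )
    drug_features = build_drug_features(drug_emb, kg, anchors, feat_cfg)
    mappable = list(gene_scores.columns)
    feature_sets = derive_feature_sets(drug_features, kg, mappable_genes=mappable)
    gene_pools = {fs.label: tuple(sorted(fs.genes)) for fs in feature_sets}

    # freeze the 4x4 grid once per study: quartiles of the descriptor
    # distribution of the cluster-derived sets plus 200 random variants
    from .qd_search import SearchConfig, mutate

    ds = DescriptorSpace(gene_emb, list(anchors.genes))
    ref_rng = np.random.default_rng(int(seeds[6]))
    ref_cfg = SearchConfig(seed=int(seeds[6]))
    init_genes = [frozenset(fs.genes) for fs in feature_sets]
    reference = list(init_genes)
    for _ in range(ref_cfg.n_reference_random):
        base = init_genes[ref_rng.integers(len(init_genes))]
        reference.append(mutate(base, ref_rng, mappable, gene_pools, ref_cfg))
    ds.freeze(reference)

    return Study(
        config=config,
        kg=kg,
        anchors=anchors,
        gene_embeddings=gene_emb,
        drug_embeddings=drug_emb,
        near_module=near,
        far_module=far,
        cohort=cohort,
        pcs=pca_top8(cohort, [v for v in retained if v in set(cohort.variants["variant_id"])]),
        split=split,
        masks=masks,
        gene_scores=gene_scores,
        full_gene_scores=full_gene_scores,
        drug_features=drug_features,
        feature_sets=feature_sets,
        gene_pools=gene_pools,
        universe=mappable,
        descriptor_edges=ds.edges,
    )


# ---------------------------------------------------------------------------
# seeded runs over one study
# ---------------------------------------------------------------------------

@dataclass
class SearchRun:
    archive: Archive
    history: pd.DataFrame
    best: MetricsRecord  # metrics of the highest-quality elite


def run_search(study: Study, seed: int, generations: int = 40,
               batch_per_gen: int = 25) -> SearchRun:
    cfg = SearchConfig(generations=generations, batch_per_gen=batch_per_gen, seed=seed)
    evaluate = study.evaluator()
    dspace = study.descriptor_space()
    archive, history = run_map_elites(
        study.feature_sets, evaluate, dspace, study.universe, study.gene_pools, cfg
    )
    best = max(archive.elites(), key=lambda e: e.quality)
    return SearchRun(archive=archive, history=history, best=best.metrics)


def run_random(study: Study, seed: int, budget: int = 1000) -> list[Individual]:
    evaluate = study.evaluator()
    dspace = study.descriptor_space()
    cfg = SearchConfig(seed=seed)
    return run_random_search(
        study.feature_sets, evaluate, dspace, study.universe, study.gene_pools,
        budget=budget, seed=seed, config=cfg,
    )


def run_nsga2_baseline(study: Study, seed: int, generations: int = 25,
                       pop_size: int = 40):
    cfg = SearchConfig(generations=generations, seed=seed)
    return run_nsga2(
        study.feature_sets, study.evaluator(), study.descriptor_space(),
        study.universe, study.gene_pools, cfg, pop_size=pop_size,
    )


def run_global(study: Study, seed: int, eval_subset: str = "test") -> MetricsRecord:
    """Pure-exploitation baseline on the same gene-score feature space the
    search operates on, so the comparison isolates the search strategy."""
    return run_global_baseline(
        study.gene_scores, study.cohort.phenotype(), study.masks,
        seed=seed, eval_subset=eval_subset,
    )


def archive_test_metrics(study: Study, archive: Archive) -> list[MetricsRecord]:
    """Held-out (test subset) metrics of every elite in an archive."""
    pheno = study.cohort.phenotype()
    return [
        evaluate_feature_set(
            feature_set_score(study.gene_scores, e.genes), pheno, study.masks,
            eval_subset="test",
        )
        for e in archive.elites()
    ]


def archive_mean_recall(study: Study, archive: Archive) -> float:
    """A run's retrieval performance: mean test recall over its elites.

    The archive is the method's output — a panel of mechanistically distinct
    solutions — so run-level retrieval is summarized across the panel rather
    than by a single member."""
    return float(np.mean([m.recall for m in archive_test_metrics(study, archive)]))


def mean_set_distances(gene_sets, gene_embeddings: EmbeddingTable, anchor_genes) -> dict[str, float]:
    """Mean per-set (Euclidean, Canberra, Cosine) distance from the anchor
    centroid — the coverage summary used to compare search strategies."""
    centroid = gene_embeddings.subset(anchor_genes).mean(axis=0)
    per_set = {"euclidean": [], "canberra": [], "cosine": []}
    for gs in gene_sets:
        genes = sorted(getattr(gs, "genes", gs))
        vecs = [gene_embeddings.vector(g) for g in genes]
        per_set["euclidean"].append(np.mean([euclidean(v, centroid) for v in vecs]))
        per_set["canberra"].append(np.mean([canberra(v, centroid) for v in vecs]))
        per_set["cosine"].append(np.mean([cosine_distance(v, centroid) for v in vecs]))
    return {k: float(np.mean(v)) for k, v in per_set.items()}
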