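"""Synthetic knowledge graphs, case-control cohorts and GWAS summary tables.

The generator reproduces the statistical structure the rest of the package
assumes, so every downstream stage is testable without controlled-access
data:

* a drug->gene degree distribution that is heavy-tailed (log-normal, solved
  from target median and mean), with a planted connected module of anchor
  disease genes preferentially targeted by anchor drugs;
* admixed case-control genotypes whose populations diverge enough for PCA to
  recover them, with case status driven by a planted-gene dosage burden plus
  a population-membership confounder (so unmatched analyses are biased and
  matching is demonstrably useful);
* a GWAS summary table whose beta column is the true per-variant log odds
  plus noise and whose p column comes from per-variant score tests on the
  simulated genotypes.

All randomness flows from a single integer seed through one root generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .cohort import Cohort
from .cohort_qc import association_pvalues
from .kg import (
    DISEASE,
    DRUG,
    GENE,
    REL_DRUG_DISEASE,
    REL_GENE_DISEASE,
    REL_INTERACTS,
    REL_TARGETS,
    AnchorSets,
    KnowledgeGraph,
)


@dataclass(frozen=True)
class SyntheticKGConfig:
    n_genes: int = 300
    n_drugs: int = 150
    n_diseases: int = 5
    n_anchor_genes: int = 12
    n_anchor_drugs: int = 8
    degree_median_target: int = 10
    degree_mean_target: float = 36.33
    modularity: float = 0.7
    seed: int = 0
    module_size: int = 20
    anchor_target_bias: float = 0.7  # fraction of anchor-drug targets drawn from anchor genes

    def validate(self) -> None:
        if min(self.n_genes, self.n_drugs, self.n_diseases) <= 0:
            raise ValueError("node counts must be positive")
        if not 0 <= self.n_anchor_genes <= self.n_genes:
            raise ValueError("n_anchor_genes must be in [0, n_genes]")
        if not 0 <= self.n_anchor_drugs <= self.n_drugs:
            raise ValueError("n_anchor_drugs must be in [0, n_drugs]")
        if self.degree_median_target < 1 or self.degree_median_target > self.n_genes:
            raise ValueError("degree_median_target must be in [1, n_genes]")
        if self.degree_mean_target < self.degree_median_target:
            raise ValueError("heavy tail requires degree_mean_target >= degree_median_target")
        if not 0 <= self.modularity <= 1:
            raise ValueError("modularity must be in [0, 1]")


def _lognormal_degree_params(median: float, mean: float) -> tuple[float, float]:
    """(mu, sigma) of the log-normal whose median and mean hit the targets."""
    mu = math.log(median)
    sigma = math.sqrt(max(0.0, 2.0 * math.log(mean / median)))
    return mu, sigma


def simulate_kg(config: SyntheticKGConfig) -> tuple[KnowledgeGraph, AnchorSets]:
    """Generate a typed drug/gene/disease graph with planted anchor structure."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    kg = KnowledgeGraph()

    genes = [f"G{i:04d}" for i in range(config.n_genes)]
    drugs = [f"D{i:04d}" for i in range(config.n_drugs)]
    diseases = [f"DZ{i:02d}" for i in range(config.n_diseases)]
    for g in genes:
        kg.add_entity(g, GENE)
    for d in drugs:
        kg.add_entity(d, DRUG)
    for z in diseases:
        kg.add_entity(z, DISEASE)

    anchor_genes = tuple(genes[: config.n_anchor_genes])
    anchor_drugs = tuple(drugs[: config.n_anchor_drugs])

    # gene modules: module 0 is the planted anchor module, the rest chunk the
    # remaining genes
    modules: list[list[str]] = []
    if anchor_genes:
        modules.append(list(anchor_genes))
    rest = genes[config.n_anchor_genes :]
    for i in range(0, len(rest), config.module_size):
        modules.append(rest[i : i + config.module_size])

    p_in = 0.05 + 0.25 * config.modularity
    p_out = 0.002 + 0.008 * (1.0 - config.modularity)
    for mod in modules:
        # random spanning path keeps each planted module connected
        order = list(rng.permutation(mod))
        for a, b in zip(order, order[1:]):
            kg.add_relation(a, REL_INTERACTS, b)
        for i, a in enumerate(mod):
            for b in mod[i + 1 :]:
                if rng.random() < p_in:
                    kg.add_relation(a, REL_INTERACTS, b)
    gene_arr = np.array(genes)
    n_bg = rng.binomial(config.n_genes * (config.n_genes - 1) // 2, p_out)
    for _ in range(int(n_bg)):
        a, b = rng.choice(gene_arr, size=2, replace=False)
        kg.add_relation(a, REL_INTERACTS, b)

    # heavy-tailed drug out-degrees
    mu, sigma = _lognormal_degree_params(config.degree_median_target, config.degree_mean_target)
    degrees = np.maximum(1, np.rint(rng.lognormal(mu, sigma, config.n_drugs))).astype(int)
    degrees = np.minimum(degrees, config.n_genes)
    anchor_gene_arr = np.array(anchor_genes) if anchor_genes else None
    for d, deg in zip(drugs, degrees):
        targets: set[str] = set()
        if d in anchor_drugs and anchor_gene_arr is not None:
            n_anchor = min(len(anchor_gene_arr), int(round(config.anchor_target_bias * deg)))
            targets.update(rng.choice(anchor_gene_arr, size=n_anchor, replace=False))
        remaining = deg - len(targets)
        if remaining > 0:
            pool = rng.choice(gene_arr, size=min(remaining * 2 + 4, config.n_genes), replace=False)
            for g in pool:
                if len(targets) >= deg:
                    break
                targets.add(str(g))
        for g in targets:
            kg.add_relation(d, REL_TARGETS, g)

    focal = diseases[0]
    for g in anchor_genes:
        kg.add_relation(g, REL_GENE_DISEASE, focal)
    for d in anchor_drugs:
        kg.add_relation(d, REL_DRUG_DISEASE, focal)
    for g in genes:
        if rng.random() < 0.02:
            kg.add_relation(g, REL_GENE_DISEASE, str(rng.choice(diseases)))
    for d in drugs:
        if rng.random() < 0.05:
            kg.add_relation(d, REL_DRUG_DISEASE, str(rng.choice(diseases)))

    return kg, AnchorSets(genes=anchor_genes, drugs=anchor_drugs)


def simulate_drug_community_graph(
    n_drugs: int = 200,
    n_communities: int = 2,
    p_in: float = 0.15,
    p_out: float = 0.01,
    degree_sigma: float = 0.8,
    seed: int = 0,
):
    """Degree-corrected community graph over drug nodes.

    A planted-partition model with log-normal degree propensities — the same
    heavy-tailed degree structure the drug projection graph exhibits. Used as
    a controlled substrate for evaluating the drug encoder's held-out edge
    reconstruction.
    """
    import networkx as nx

    rng = np.random.default_rng(seed)
    theta = rng.lognormal(0.0, degree_sigma, n_drugs)
    theta /= theta.mean()
    block = n_drugs // n_communities
    nodes = [f"D{i:04d}" for i in range(n_drugs)]
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for i in range(n_drugs):
        for j in range(i + 1, n_drugs):
            same = (i // block) == (j // block)
            base = p_in if same else p_out
            if rng.random() < min(1.0, base * theta[i] * theta[j]):
                g.add_edge(nodes[i], nodes[j])
    return g


@dataclass(frozen=True)
class SyntheticCohortConfig:
    n_pairs: int = 150
    n_variants: int = 500
    n_populations: int = 2
    fst_like_divergence: float = 0.1
    planted_effect_genes: tuple[str, ...] = ()
    effect_size: float = 0.5
    seed: int = 0
    confounding: float = 1.0  # log-odds shift tied to population membership
    ld_rho: float = 0.2  # adjacent-variant gaussian-copula correlation
    variants_per_planted_gene: int = 3
    beta_noise_sd: float = 0.05
    n_gwas_samples: int = 1500  # independent discovery sample for summary stats
    # optional per-gene log odds overriding effect_size, as (gene, beta) pairs
    effect_size_by_gene: tuple[tuple[str, float], ...] | None = None

    def validate(self, kg: KnowledgeGraph) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if self.n_populations < 1:
            raise ValueError("n_populations must be >= 1")
        if not math.isfinite(self.effect_size):
            raise ValueError("effect_size must be finite")
        missing = set(self.planted_effect_genes) - set(kg.genes())
        if missing:
            raise ValueError(f"planted effect genes absent from graph: {sorted(missing)[:5]}")
        n_causal = len(self.planted_effect_genes) * self.variants_per_planted_gene
        if n_causal > self.n_variants:
            raise ValueError("not enough variants to cover planted genes")


def _variant_gene_map(config: SyntheticCohortConfig, kg: KnowledgeGraph) -> list[str]:
    planted = list(config.planted_effect_genes)
    others = [g for g in kg.genes() if g not in set(planted)]
    genes: list[str] = []
    for g in planted:
        genes.extend([g] * config.variants_per_planted_gene)
    i = 0
    while len(genes) < config.n_variants:
        genes.append(others[i % len(others)] if others else planted[i % len(planted)])
        i += 1
    return genes


def _estimate_beta(dosages: np.ndarray, y: np.ndarray, strata: np.ndarray) -> np.ndarray:
    """Per-variant log-odds-ratio estimate from a discovery sample.

    Within-stratum residualized linear slope divided by ybar*(1-ybar) — the
    one-step approximation to the logistic MLE, vectorized over variants.
    """
    d = np.asarray(dosages, dtype=float).copy()
    yc = np.asarray(y, dtype=float).copy()
    for g in np.unique(strata):
        m = strata == g
        yc[m] -= yc[m].mean()
        d[m] -= d[m].mean(axis=0)
    var = (d**2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        slope = (d * yc[:, None]).sum(axis=0) / var
    ybar = float(np.mean(y))
    return np.where(np.isfinite(slope), slope, 0.0) / max(ybar * (1 - ybar), 1e-12)


def _draw_genotypes(rng: np.random.Generator, pop: np.ndarray, pop_freq: np.ndarray,
                    ld_rho: float) -> np.ndarray:
    """Dosages for one batch: two haplotypes per sample, each an AR(1)
    gaussian-copula thresholded at the sample's population allele frequency,
    which induces the adjacent-variant correlation."""
    n, v = pop.size, pop_freq.shape[1]
    z = rng.standard_normal((2 * n, v))
    rho = float(np.clip(ld_rho, 0.0, 0.99))
    if rho > 0:
        for j in range(1, v):
            z[:, j] = rho * z[:, j - 1] + math.sqrt(1 - rho**2) * z[:, j]
    u = norm.cdf(z)
    p = pop_freq[np.repeat(pop, 2)]
    hap = (u < p).astype(float)
    return hap[0::2] + hap[1::2]


def simulate_cohort(config: SyntheticCohortConfig, kg: KnowledgeGraph) -> Cohort:
    """Simulate a matched case-control cohort plus GWAS summary statistics.

    Case status follows a logistic model over the planted-gene dosage burden
    plus a centered population confounder; exactly one case and one control
    share each pair id, paired within population where possible.

    The GWAS summary table plays the role of an external discovery study: its
    p-values come from score tests on an *independent* simulated sample of
    ``n_gwas_samples`` individuals drawn from the same population model, so
    genes that pass the significance filter by chance carry no in-sample
    association with the returned cohort.
    """
    config.validate(kg)
    rng = np.random.default_rng(config.seed)

    variant_genes = _variant_gene_map(config, kg)
    v = config.n_variants
    p0 = rng.uniform(0.1, 0.9, v)
    f = config.fst_like_divergence
    if f > 0:
        a, b = p0 * (1 - f) / f, (1 - p0) * (1 - f) / f
        pop_freq = np.clip(rng.beta(a, b, size=(config.n_populations, v)), 0.01, 0.99)
    else:
        pop_freq = np.tile(p0, (config.n_populations, 1))

    gene_effect = {g: config.effect_size for g in config.planted_effect_genes}
    if config.effect_size_by_gene:
        gene_effect.update(dict(config.effect_size_by_gene))
    beta_true = np.array([gene_effect.get(g, 0.0) for g in variant_genes])
    causal = beta_true != 0.0
    expected_burden = float(2.0 * (pop_freq.mean(axis=0) * beta_true).sum())
    pop_effect = np.linspace(-1.0, 1.0, config.n_populations) if config.n_populations > 1 else np.zeros(1)

    def draw_labeled(n_draw):
        p_ = rng.integers(config.n_populations, size=n_draw)
        d_ = _draw_genotypes(rng, p_, pop_freq, config.ld_rho)
        lin = d_ @ beta_true - expected_burden
        lin = lin + config.confounding * pop_effect[p_]
        y_ = (rng.random(n_draw) < expit(lin)).astype(int)
        return p_, d_, y_

    # independent discovery sample -> GWAS summary columns; stratified by
    # population (an uncorrected test would be inflated genome-wide by the
    # confounder). The beta column is the discovery *estimate* of the log
    # odds ratio — i.e. the true simulation log odds plus sampling noise —
    # so that variants significant by chance carry realistically sized
    # effect estimates, exactly as in real summary statistics.
    disc_pop, disc_d, disc_y = draw_labeled(config.n_gwas_samples)
    disc_p = association_pvalues(disc_d, disc_y, strata=disc_pop)
    disc_beta = _estimate_beta(disc_d, disc_y, disc_pop)

    dosage_chunks, pop_chunks, y_chunks = [], [], []
    n_cases = n_controls = 0
    while n_cases < config.n_pairs or n_controls < config.n_pairs:
        if len(dosage_chunks) >= 40:
            raise ValueError("could not draw enough cases and controls; check effect sizes")
        batch = max(64, int(2.6 * config.n_pairs))
        pop, dos, y = draw_labeled(batch)
        dosage_chunks.append(dos)
        pop_chunks.append(pop)
        y_chunks.append(y)
        n_cases += int(y.sum())
        n_controls += int((1 - y).sum())

    dos = np.vstack(dosage_chunks)
    pop = np.concatenate(pop_chunks)
    y = np.concatenate(y_chunks)

    case_idx = np.flatnonzero(y == 1)[: config.n_pairs]
    ctrl_idx = np.flatnonzero(y == 0)[: config.n_pairs]
    # pair within population where possible: stable sort both sides by population
    case_idx = case_idx[np.argsort(pop[case_idx], kind="stable")]
    ctrl_idx = ctrl_idx[np.argsort(pop[ctrl_idx], kind="stable")]

    rows, order = [], []
    for k in range(config.n_pairs):
        pair = f"P{k:05d}"
        order.extend([case_idx[k], ctrl_idx[k]])
        rows.append((f"S{2 * k:05d}", 1, pair, int(pop[case_idx[k]])))
        rows.append((f"S{2 * k + 1:05d}", 0, pair, int(pop[ctrl_idx[k]])))
    samples = pd.DataFrame(rows, columns=["sample_id", "phenotype", "pair_id", "population"])
    dosages = dos[np.array(order)]

    beta = disc_beta + rng.normal(0.0, config.beta_noise_sd, v)
    variants = pd.DataFrame(
        {
            "variant_id": [f"V{j:05d}" for j in range(v)],
            "chrom": "1",
            "pos": np.arange(1, v + 1) * 1000,
            "gene": variant_genes,
            "beta": beta,
            "p": disc_p,
        }
    )
    return Cohort(samples=samples, dosages=dosages, variants=variants)
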