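# Methods

This note records the models implemented in `qdrx`, the assumptions behind
them, the defaults and why they were chosen, and what the synthetic data can
and cannot establish.

## Node encoders and the anchor clustering loss

Both encoders operate on graphs without node attributes, so inputs are
fixed random Gaussian features (seeded, dimension = hidden width). The gene
encoder is a two-layer mean-neighborhood aggregator: each layer applies a
linear map to `[h_self ‖ mean(h_neighbors)]` followed by ReLU, and the
output layer is row-L2-normalized. It is trained on a binary cross-entropy
link objective over the gene-incident subgraph (direct gene–gene edges plus
genes co-incident to a shared drug or disease, skipping non-gene nodes with
more than 30 gene neighbors so hubs do not create quadratic cliques), with
1:1 uniformly sampled negatives redrawn each epoch. Isolated nodes
aggregate a zero neighbor vector, so every node is embeddable.

The drug encoder is a variational graph autoencoder on the drug one-mode
projection (drugs connected when they share at least one target gene): the
encoder produces per-node means and log-variances, latents are drawn by
reparameterization, and an inner-product decoder with a sigmoid
reconstructs adjacency against sampled non-edges, with a KL penalty to the
standard normal. The returned embeddings are the posterior means. One
numerical point matters: the reconstruction term is accounted *per node*
(sum over sampled pairs divided by n). If it is instead averaged over
pairs, the per-node KL gradient dominates and the posterior means collapse
to a point (held-out edge AUC pins at 0.5); the per-node scaling matches
the relative weighting of the canonical full-adjacency VGAE objective, and
on a 200-node degree-corrected two-community graph the held-out
reconstruction AUC (0.75–0.84 across seeds) then approaches the rank-2
spectral ceiling (~0.85).

Both objectives add `λ_cluster · L_cluster` where `L_cluster` is the
maximum pairwise Euclidean distance among the anchor (known disease
entity) embeddings, plus an L2 penalty on the weights. Defaults follow the
framework's stated settings: `λ_cluster = 1`, L2 weight `1e-2`, embedding
dimension 16 (32 supported), two layers, hidden width 2× the embedding
dimension, Adam at 1e-2, full batch. During gradient steps the hard
maximum is replaced by a temperature-0.1 log-sum-exp (the subgradient of
the hard max destabilizes training); all *reported* values use the exact
maximum. Training is deterministic given the config seed; initialization,
negative sampling and reparameterization noise use independent child
generators of that seed, so ablations with different loss weights see
identical sampling streams.

## Drug feature table and feature sets

Each drug's feature row holds three distances (Canberra, Euclidean,
Cosine) from its embedding to the centroid of the anchor-drug embeddings
(a per-anchor-minimum mode is available via `FeatureConfig.reference`),
its raw gene-interaction count (number of gene targets in the graph, not
global degree), and a K-means label. Drugs with more than `hub_threshold`
(default 20) targets are labeled −1 and excluded from clustering so
promiscuous compounds cannot drag the centroids, but they stay in the
table and contribute a feature set. The three distances are z-standardized
before K-means (they live on different scales); K-means uses 10 seeded
restarts, and `elbow_k` picks k by the maximal discrete second difference
of the within-cluster sum of squares, ties toward smaller k. The default
k = 24 matches the framework's reference setting; the synthetic studies
use k = 6 because their graphs are ~20× smaller. One gene feature set per
cluster label (including −1) is the union of the cluster's drugs' targets,
restricted to genes with GWAS-mappable variants.

## Cohort construction

QC follows standard practice: retain variants with MAF strictly > 0.02;
exclude Hardy-Weinberg exact-test p ≤ 1e-7 (Levene–Haldane two-sided,
summing configurations no more probable than the observed one); LD-prune
in sliding windows of 100 variants advancing by 10, greedily removing the
lower-MAF member (tie: later position) of any pair with r² ≥ 0.1. Window
units are variant counts. Missing dosages are mean-imputed for PCA and r²
only, excluded pairwise for MAF/HWE. PCA takes the top 8 components of the
column-standardized dosage matrix, with the largest-magnitude loading of
each component made positive for a reproducible sign.

The propensity model is a maximum-likelihood logistic regression of case
status on PC1..PC8 (a 1e-6 ridge fallback handles perfect separation, with
a warning). Matching is greedy 1:1 nearest neighbor on the score, cases in
descending score order. In the synthetic pipeline the generator produces a
35% surplus pool and only the closest `n_pairs` matches are kept, which
discards the poorly matched (typically cross-population) pairs — without a
surplus, equal case/control counts force every case to match and residual
confounding leaks into downstream scores.

## Optimized data partitioning

Whole matched pairs are assigned 1:1:1 to train/validation/test by a
seeded shuffle; subset sizes differ by at most one pair and pair integrity
is asserted on every trial. Each trial's quality is measured on reference
SNPs (default 30; most-associated variants passing MAF > 0.1, HWE p >
1e-7, pairwise r² < 0.8): `M_k` is the median −log p (natural log; any
fixed base gives the same ranking) of their score-test p-values within
subset k, `f1 = median(M_train, M_val, M_test)` and `f2` the sum of
absolute pairwise differences. The two objectives are scalarized as
`J = f1 − w·f2` with `w = 1` — both live on the −log p scale, and a single
number is needed to select a split.

The seed is optimized with a Tree-structured Parzen Estimator. Raw integer
seeds carry no learnable topology, so the good/bad densities l(x) and g(x)
are estimated over structural *fingerprints* of the induced split:
decile-binned per-subset means of the per-sample reference-SNP dosage mean
plus the case-count imbalance, with Laplace +1 smoothing, γ = 0.25, and 10
random startup trials. Candidate seeds are proposed by maximizing l/g over
their fingerprints; degenerate histories fall back to uniform draws.

## Scoring and evaluation

Gene scores average β × dosage over a gene's qualifying variants (GWAS
p < 0.05, strictly); feature-set scores are row sums over member genes.
The evaluator fits a univariate logistic model (two-parameter
Newton–Raphson with a 1e-8 ridge and step clipping; coefficient cap at
±30 guards complete separation) on the training subset and reports
validation ROC-AUC (rank statistic with ties counted ½), PR-AUC (average
precision), and threshold-0.5 confusion metrics. F1 is reported as 0 with
a flag when precision + recall = 0. The classification threshold is
configurable; 0.5 is the default.

## MAP-Elites and baselines

Descriptors are the mean Euclidean and mean Canberra distances of a set's
gene embeddings from the anchor-gene centroid. Quartile edges are frozen
*once per study* from the descriptor distribution of the cluster-derived
feature sets plus 200 random variants, and shared by every seeded run —
refreezing per run makes cell identity drift and inflates cross-run
variance. Binning is right-open; values at or beyond the extreme cuts
clamp to bins 0 and 3.

Variation: with probability 0.3 uniform set crossover (intersection kept,
symmetric difference coin-flipped), then one mutation — add a gene
(sampled from a cluster pool containing a random member gene with
probability 0.7, else uniformly), remove a gene, or swap, each with
probability ⅓; set sizes are clamped to [2, 200]. Archive updates insert
into empty cells and replace only on strictly higher quality (ties keep
the incumbent, for determinism). The reference budget is 100 generations ×
100 offspring = 10,000 evaluations, matching the single-generation random
search baseline; the synthetic studies run 40 × 25 so a five-run protocol
completes in seconds. NSGA-II uses the same variation operators with
objectives (quality, mean of the two descriptor components), standard fast
non-dominated sorting and crowding distance. The global baseline is a
deliberately exploitation-heavy gradient-boosted ensemble (XGBoost, depth
6, 60 trees, 0.5 row and column subsampling — pluggable via
`learner_factory`) on the same significance-filtered gene-score table the
search uses, so the comparison isolates the search strategy.

Consensus ranking: within each run a drug is retrieved when its target set
(restricted to scoreable genes — genes without GWAS-mappable variants can
never appear in a feature set) has Jaccard overlap ≥ τ = 0.3 with an elite
of quality ≥ q (default: the archive's median elite quality). Drugs are
ranked by retrieval count across runs, ties by overlap-weighted elite
quality.

For cross-run stability a run's retrieval performance is summarized as the
mean test-subset recall over its archive elites: the archive is the
method's output — a panel of mechanistically distinct solutions — so
run-level retrieval is a property of the panel, not of a single member.
Cross-run comparisons use the sample SD of recall, a two-sided
variance-ratio F-test (larger variance in the numerator, p = 2·min(cdf,
sf) capped at 1) and Welch's t with Satterthwaite degrees of freedom;
significance markers at 0.05 (*) and 0.01 (**).

## The synthetic data generator

`simulate_kg` draws drug out-degrees from a log-normal solved in closed
form from the target median (10) and mean (36.33) — the two-parameter
family that matches both — clamped to [1, n_genes], so the drug–gene graph
is heavy-tailed like real polypharmacology data. Gene–gene edges follow a
planted-module layout (a random spanning path keeps each module connected)
whose density interpolates with a modularity parameter; anchor genes form
module 0 and anchor drugs draw 70% of their targets from it.

`simulate_cohort` draws two haplotypes per individual from
population-specific allele frequencies (Balding–Nichols beta model around
a shared ancestral frequency, divergence parameter F). Adjacent-variant
correlation comes from an AR(1) Gaussian copula on the haplotype uniforms
(ρ = 0.2); realistic LD *block* structure and haplotype-level processes
are deliberately out of scope. Case status is logistic in the planted-gene
dosage burden plus a centered population confounder (coefficient 1.0), so
unmatched analyses are genuinely biased and matching demonstrably helps.
All randomness flows from one root generator per seed.

The GWAS summary table emulates an *external* discovery study: an
independent simulated sample (n = 1500) from the same population model
supplies the p column via a population-stratified score test (an
uncorrected test would be inflated genome-wide by the confounder) and the
β column via the one-step logistic estimate — i.e., the true simulation
log odds plus genuine sampling noise. Two properties of real summary
statistics matter downstream and are preserved: β̂ and p come from the
same estimate, so variants significant by chance carry |β̂| ≈ 2·SE rather
than near-zero effects; and no column is computed on the analytic cohort
itself, so aggregating chance-significant genes dilutes rather than
inflates the classifier (a null-only feature set scores AUC ≈ 0.5).

## The planted two-niche study

`pipeline.build_study` assembles the benchmark landscape: after training
the gene encoder, one predictive module is placed inside the anchor set
("near", 12 genes, per-variant log odds 0.9) and one in the embedding
module most distant from the anchor centroid ("far", 12 genes, log odds
0.75), three variants per planted gene. A planted drug targets the far
module exactly (plus two partial-overlap companions so a drug cluster
carries the distant mechanism). The asymmetry in effect sizes mirrors real
cohorts, where the well-characterized biology is the better-powered
signal; it also means a pure quality ranking concentrates near the
anchors, which is precisely the failure mode quality-diversity search is
meant to avoid. Study conditions: 300 matched pairs from a 35% surplus
pool, 800 variants, two populations at F = 0.1, 30 reference SNPs, 120
TPE trials, k = 6 drug clusters; searches run 40 generations × 25
offspring with five independent seeds. These sizes keep a full study
under ten seconds and the complete protocol suite under a minute on one
core while leaving every qualitative contrast (niche structure, dilution
penalty, baseline instability) intact.

What passing on this landscape shows: the archive fills distinct
descriptor niches including cells the quality-only baselines neglect, the
planted distant-mechanism drug is recovered by consensus across seeds, and
the elite panel's retrieval is at least as stable as the global learner's.
What it does not show: performance on real knowledge graphs (ascertainment
bias, richer relation inventories), real LD structure, rare-variant
signal, or calibration of absolute AUC values — the synthetic effect sizes
are chosen for clear signal at small n, not to match any disease.

## Known limitations

* The encoders are full-batch NumPy implementations; they are sized for
  graphs of 10²–10⁴ nodes, not for minibatched neighbor sampling at scale.
* The drug projection for the VGAE discards which gene mediates each
  drug–drug connection; a heterogeneous-graph decoder is future work.
* TPE over split fingerprints gives modest gains over random search at
  these cohort sizes; its value is the protocol (pair integrity +
  reference-SNP balance), not large f1 improvements.
* Recall at small validation/test subsets is quantized (steps of 1/n),
  which limits the resolution of the cross-run SD comparisons.
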