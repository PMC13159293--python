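"""Drug feature table construction and candidate gene feature sets.

Each drug is described by three complementary distances (Canberra,
Euclidean, Cosine) from its embedding to the centroid of the known-drug
anchor embeddings, its raw gene-interaction count (number of gene targets in
the knowledge graph), and a K-means cluster label over the standardized
distance features. Promiscuous "hub" drugs — more gene targets than the hub
threshold — are labeled −1 and excluded from clustering so they cannot drag
the centroids, but stay in the feature table. Candidate gene feature sets
are the per-cluster unions of target genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .graph_embeddings import EmbeddingTable
from .kg import AnchorSets, KnowledgeGraph

log = logging.getLogger(__name__)

HUB_LABEL = -1


@dataclass(frozen=True)
class FeatureConfig:
    k_clusters: int = 24
    hub_threshold: int = 20
    elbow_k_min: int = 2
    elbow_k_max: int = 30
    reference: str = "centroid"  # or "min": distance to the nearest anchor
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_clusters < 2:
            raise ValueError("k_clusters must be >= 2")
        if self.hub_threshold < 1:
            raise ValueError("hub_threshold must be >= 1")
        if self.reference not in ("centroid", "min"):
            raise ValueError("reference must be 'centroid' or 'min'")


@dataclass(frozen=True)
class FeatureSet:
    """A candidate gene set derived from one drug cluster."""

    label: int
    genes: frozenset[str]

    def __len__(self) -> int:
        return len(self.genes)


# ---------------------------------------------------------------------------
# distance metrics
# ---------------------------------------------------------------------------

def _check_dims(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {y.shape}")
    return x, y


def canberra(x, y) -> float:
    """Canberra distance: sum of |x_i - y_i| / (|x_i| + |y_i|).

    Terms with a zero denominator (both coordinates zero) contribute 0,
    matching the usual convention for this metric.
    """
    x, y = _check_dims(x, y)
    num = np.abs(x - y)
    den = np.abs(x) + np.abs(y)
    terms = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    return float(terms.sum())


def euclidean(x, y) -> float:
    x, y = _check_dims(x, y)
    return float(np.sqrt(((x - y) ** 2).sum()))


def cosine_distance(x, y) -> float:
    """1 - cos(x, y); a zero vector is maximally dissimilar (distance 1)."""
    x, y = _check_dims(x, y)
    nx_, ny_ = np.linalg.norm(x), np.linalg.norm(y)
    if nx_ == 0 or ny_ == 0:
        log.warning("cosine distance with a zero vector; returning 1.0")
        return 1.0
    return float(1.0 - np.dot(x, y) / (nx_ * ny_))


_METRICS = {"canberra": canberra, "euclidean": euclidean, "cosine": cosine_distance}


def anchor_distances(vector: np.ndarray, anchor_matrix: np.ndarray,
                     reference: str = "centroid") -> dict[str, float]:
    """Three distances from one embedding to the anchor reference.

    ``centroid`` measures against the mean anchor embedding (fixed-length
    feature row); ``min`` takes, per metric, the minimum over the anchors.
    """
    if reference == "centroid":
        ref = anchor_matrix.mean(axis=0)
        return {name: fn(vector, ref) for name, fn in _METRICS.items()}
    return {
        name: min(fn(vector, a) for a in anchor_matrix)
        for name, fn in _METRICS.items()
    }


# ---------------------------------------------------------------------------
# feature table
# ---------------------------------------------------------------------------

def build_drug_features(
    drug_embeddings: EmbeddingTable,
    kg: KnowledgeGraph,
    anchors: AnchorSets,
    config: FeatureConfig | None = None,
) -> pd.DataFrame:
    """One row per drug: three anchor distances, hub/cluster label, target count.

    Drugs whose gene-interaction count exceeds ``hub_threshold`` get label −1
    and are excluded from K-means; the remaining drugs are clustered on the
    z-standardized 3-distance feature space (10 restarts, seeded).
    """
    config = config or FeatureConfig()
    drugs = kg.drugs()
    missing = [d for d in drugs if d not in drug_embeddings]
    if missing:
        raise ValueError(f"drugs without embeddings: {missing[:5]}")
    if not anchors.drugs:
        raise ValueError("anchor drug set is empty")
    anchor_matrix = drug_embeddings.subset(anchors.drugs)
    counts = kg.target_counts()

    rows = []
    for d in drugs:
        dist = anchor_distances(drug_embeddings.vector(d), anchor_matrix, config.reference)
        rows.append(
            (d, dist["canberra"], dist["euclidean"], dist["cosine"], counts[d])
        )
    df = pd.DataFrame(
        rows,
        columns=["drug_id", "d_canberra", "d_euclidean", "d_cosine", "gene_interaction_count"],
    )
    is_hub = df["gene_interaction_count"] > config.hub_threshold
    n_free = int((~is_hub).sum())
    if n_free == 0:
        raise ValueError("all drugs exceed the hub threshold; nothing to cluster")
    if n_free < config.k_clusters:
        raise ValueError(
            f"k_clusters={config.k_clusters} exceeds the {n_free} non-hub drugs"
        )

    feats = df.loc[~is_hub, ["d_canberra", "d_euclidean", "d_cosine"]].to_numpy()
    mu, sd = feats.mean(axis=0), feats.std(axis=0)
    sd[sd == 0] = 1.0
    z = (feats - mu) / sd
    km = KMeans(n_clusters=config.k_clusters, n_init=10, random_state=config.seed)
    labels = km.fit_predict(z)

    df["cluster_label"] = HUB_LABEL
    df.loc[~is_hub, "cluster_label"] = labels
    df["cluster_label"] = df["cluster_label"].astype(int)
    return df


def kmeans_wcss(drug_features: pd.DataFrame, k_range, seed: int = 0) -> dict[int, float]:
    """Within-cluster sum of squares over a k grid (non-hub drugs only)."""
    free = drug_features[drug_features["cluster_label"] != HUB_LABEL] \
        if "cluster_label" in drug_features else drug_features
    feats = free[["d_canberra", "d_euclidean", "d_cosine"]].to_numpy()
    mu, sd = feats.mean(axis=0), feats.std(axis=0)
    sd[sd == 0] = 1.0
    z = (feats - mu) / sd
    out = {}
    for k in k_range:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(z)
        out[int(k)] = float(km.inertia_)
    return out


def elbow_k(wcss_by_k: dict[int, float]) -> int:
    """Elbow of a WCSS curve: the k maximizing the discrete second difference
    wcss(k-1) - 2*wcss(k) + wcss(k+1); ties break toward smaller k."""
    ks = sorted(wcss_by_k)
    if len(ks) < 3:
        raise ValueError("need at least 3 consecutive k values")
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("k grid must be consecutive integers")
    best_k, best_curv = None, -np.inf
    for k in ks[1:-1]:
        curv = wcss_by_k[k - 1] - 2 * wcss_by_k[k] + wcss_by_k[k + 1]
        if curv > best_curv + 1e-12:
            best_k, best_curv = k, curv
    return int(best_k)


def derive_feature_sets(
    drug_features: pd.DataFrame,
    kg: KnowledgeGraph,
    mappable_genes=None,
) -> list[FeatureSet]:
    """One gene feature set per cluster label (hub group −1 included).

    The set is the union of the cluster's drugs' target genes, restricted to
    genes with GWAS-mappable variants when ``mappable_genes`` is given; empty
    sets are dropped with a warning.
    """
    if "cluster_label" not in drug_features:
        raise ValueError("drug features lack cluster labels; run build_drug_features")
    mappable = set(mappable_genes) if mappable_genes is not None else None
    out = []
    for label, grp in drug_features.groupby("cluster_label", sort=True):
        genes: set[str] = set()
        for d in grp["drug_id"]:
            genes |= kg.drug_targets(d)
        if mappable is not None:
            genes &= mappable
        if not genes:
            log.warning("cluster %s has no mappable target genes; dropped", label)
            continue
        out.append(FeatureSet(label=int(label), genes=frozenset(genes)))
    return out
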