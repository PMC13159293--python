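"""Aggregated polygenic gene scores, feature-set scores, and retrieval metrics.

Per individual i and gene g, the gene score averages GWAS-weighted dosages
over the gene's qualifying variants (association p < 0.05):

    GeneScore[i, g] = sum_j(beta_j * dosage_ij) / n_variants(g)

A feature-set score sums gene scores over the member genes, reducing the
gene space to one interpretable predictor per set. That single score feeds a
univariate logistic classifier; ROC-AUC is the rank statistic
P(score_case > score_control) with ties counted 1/2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import rankdata
from sklearn.metrics import average_precision_score

from .cohort import Cohort

log = logging.getLogger(__name__)


@dataclass
class MetricsRecord:
    recall: float
    precision: float
    f1: float
    roc_auc: float
    pr_auc: float
    ad_total: int = 0
    hc_total: int = 0
    ad_detected: int = 0
    hc_flagged: int = 0
    f1_undefined: bool = False

    def as_dict(self) -> dict:
        return {
            "recall": self.recall,
            "precision": self.precision,
            "f1": self.f1,
            "roc_auc": self.roc_auc,
            "pr_auc": self.pr_auc,
        }


def gene_score(betas, genotypes) -> float:
    """Mean of beta * dosage over a gene's qualifying variants."""
    b = np.asarray(betas, dtype=float)
    g = np.asarray(genotypes, dtype=float)
    if b.size == 0 or g.size == 0:
        raise ValueError("gene_score needs at least one variant")
    if b.shape != g.shape:
        raise ValueError("beta and genotype vectors must have equal length")
    if not np.isin(g, (0.0, 1.0, 2.0)).all():
        raise ValueError("genotypes must be allele dosages 0, 1 or 2")
    return float((b * g).sum() / b.size)


def build_gene_scores(cohort: Cohort, p_threshold: float = 0.05) -> pd.DataFrame:
    """Samples x genes score matrix over variants with GWAS p < threshold.

    Genes without any qualifying variant are absent from the result. Missing
    dosages are imputed with the variant mean.
    """
    qual = cohort.variants["p"].to_numpy() < p_threshold
    if not qual.any():
        raise ValueError("no variants pass the GWAS p threshold")
    variants = cohort.variants[qual]
    d = cohort.dosages[:, qual]
    if np.isnan(d).any():
        means = np.nanmean(d, axis=0)
        idx = np.where(np.isnan(d))
        d = d.copy()
        d[idx] = means[idx[1]]
    betas = variants["beta"].to_numpy()
    cols, names = [], []
    for gene, grp in variants.groupby("gene", sort=True):
        j = variants.index.get_indexer(grp.index)
        cols.append(d[:, j] @ betas[j] / len(j))
        names.append(gene)
    return pd.DataFrame(
        np.column_stack(cols), index=cohort.samples["sample_id"], columns=names
    )


def feature_set_score(gene_scores: pd.DataFrame, feature_set) -> pd.Series:
    """Per-sample sum of gene scores over the member genes of a feature set."""
    genes = sorted(getattr(feature_set, "genes", feature_set))
    present = [g for g in genes if g in gene_scores.columns]
    dropped = len(genes) - len(present)
    if dropped:
        log.warning("%d feature-set genes lack scores and were dropped", dropped)
    if not present:
        raise ValueError("feature set empty after restriction to scored genes")
    return gene_scores[present].sum(axis=1)


def roc_auc(scores, labels) -> float:
    """Rank-statistic AUC: P(score_case > score_control), ties counted 1/2."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n1, n0 = int(y.sum()), int((1 - y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both classes")
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _fit_logistic_1d(x: np.ndarray, y: np.ndarray, max_iter: int = 60) -> tuple[float, float]:
    """Newton-Raphson fit of logit(p) = b0 + b1*x (tiny ridge for stability)."""
    xs = x.std()
    xm = x.mean()
    z = (x - xm) / xs if xs > 0 else np.zeros_like(x)
    b = np.zeros(2)
    X = np.column_stack([np.ones_like(z), z])
    ridge = 1e-8
    for _ in range(max_iter):
        p = expit(X @ b)
        w = np.maximum(p * (1 - p), 1e-10)
        g = X.T @ (y - p) - ridge * b
        h = (X * w[:, None]).T @ X + ridge * np.eye(2)
        step = np.linalg.solve(h, g)
        step = np.clip(step, -10, 10)
        b = b + step
        if np.abs(step).max() < 1e-10:
            break
    b = np.clip(b, -30, 30)  # complete-separation guard
    if xs > 0:
        return float(b[0] - b[1] * xm / xs), float(b[1] / xs)
    return float(b[0]), 0.0


def evaluate_feature_set(
    scores: pd.Series | np.ndarray,
    phenotype: np.ndarray,
    splits: dict[str, np.ndarray],
    eval_subset: str = "val",
    threshold: float = 0.5,
) -> MetricsRecord:
    """Fit a univariate logistic model on the train subset, score another.

    ``splits`` maps subset names to boolean masks or index arrays over the
    samples. The decision threshold on predicted probability defaults to 0.5.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(phenotype, dtype=int)

    def pick(name):
        m = np.asarray(splits[name])
        idx = np.flatnonzero(m) if m.dtype == bool else m.astype(int)
        return s[idx], y[idx]

    x_tr, y_tr = pick("train")
    x_ev, y_ev = pick(eval_subset)
    for name, yy in (("train", y_tr), (eval_subset, y_ev)):
        if len(yy) == 0 or len(np.unique(yy)) < 2:
            raise ValueError(f"subset {name!r} must be nonempty with both classes")

    b0, b1 = _fit_logistic_1d(x_tr, y_tr)
    prob = expit(b0 + b1 * x_ev)
    pred = (prob >= threshold).astype(int)

    ad_total = int(y_ev.sum())
    hc_total = int((1 - y_ev).sum())
    ad_detected = int(((pred == 1) & (y_ev == 1)).sum())
    hc_flagged = int(((pred == 1) & (y_ev == 0)).sum())
    recall = ad_detected / ad_total
    precision = ad_detected / (ad_detected + hc_flagged) if (ad_detected + hc_flagged) else 0.0
    undefined = (precision + recall) == 0
    f1 = 0.0 if undefined else 2 * precision * recall / (precision + recall)
    return MetricsRecord(
        recall=recall,
        precision=precision,
        f1=f1,
        roc_auc=roc_auc(prob, y_ev),
        pr_auc=float(average_precision_score(y_ev, prob)),
        ad_total=ad_total,
        hc_total=hc_total,
        ad_detected=ad_detected,
        hc_flagged=hc_flagged,
        f1_undefined=bool(undefined),
    )


def recall_sd(recalls) -> float:
    """Sample standard deviation (N-1 denominator) of per-run recalls."""
    r = np.asarray(list(recalls), dtype=float)
    if r.size < 2:
        raise ValueError("recall_sd needs at least two runs")
    return float(r.std(ddof=1))


def aggregate_metrics(records: list[MetricsRecord]) -> pd.DataFrame:
    """Cross-run mean and SD for each retrieval metric."""
    df = pd.DataFrame([r.as_dict() for r in records])
    return pd.DataFrame({"mean": df.mean(), "sd": df.std(ddof=1)})
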