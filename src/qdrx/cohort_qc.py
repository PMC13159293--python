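"""Genotype quality control: MAF, Hardy-Weinberg exact test, LD pruning, PCA.

These are the standard pre-PCA filters for ancestry analysis: rare variants
(MAF below threshold) destabilize the covariance structure, variants out of
Hardy-Weinberg equilibrium flag technical artifacts, and LD pruning keeps one
representative variant per correlated block so local linkage does not
dominate the principal components.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2 as chi2_dist

from .cohort import Cohort

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class QCConfig:
    maf_min: float = 0.02
    hwe_p_min: float = 1e-7
    ld_window: int = 100
    ld_step: int = 10
    ld_r2_max: float = 0.1

    def __post_init__(self) -> None:
        if not 0 < self.maf_min < 0.5:
            raise ValueError("maf_min must be in (0, 0.5)")
        if not 0 < self.ld_r2_max < 1:
            raise ValueError("ld_r2_max must be in (0, 1)")
        if self.ld_window < 2 or self.ld_step < 1:
            raise ValueError("ld_window must be >= 2 and ld_step >= 1")


def maf(dosages: np.ndarray) -> float:
    """Minor allele frequency of one variant from allele dosages.

    ``f = sum(dosage) / (2 * n_nonmissing)``; returns ``min(f, 1 - f)``.
    """
    d = np.asarray(dosages, dtype=float)
    d = d[~np.isnan(d)]
    if d.size == 0:
        raise ValueError("MAF undefined: all dosages missing")
    f = d.sum() / (2.0 * d.size)
    return float(min(f, 1.0 - f))


def _hwe_log_probs(n_het_obs: int, n_a: int, n_total: int) -> tuple[np.ndarray, np.ndarray]:
    """Log Levene-Haldane probabilities over all het counts compatible with
    the allele count ``n_a`` (count of the rarer allele) in ``n_total``."""
    hets = np.arange(n_a % 2, n_a + 1, 2)
    hets = hets[(n_a - hets) % 2 == 0]
    hets = hets[(n_a - hets) // 2 + hets <= n_total * 2]
    hom_rare = (n_a - hets) // 2
    hom_common = n_total - hets - hom_rare
    keep = hom_common >= 0
    hets, hom_rare, hom_common = hets[keep], hom_rare[keep], hom_common[keep]
    logp = (
        gammaln(n_total + 1)
        - gammaln(hom_rare + 1)
        - gammaln(hets + 1)
        - gammaln(hom_common + 1)
        + hets * np.log(2.0)
    )
    logp -= np.logaddexp.reduce(logp)  # normalize the conditional distribution
    return hets, logp


def hwe_exact_p(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided Hardy-Weinberg exact p-value (Levene-Haldane distribution).

    Sums, over every heterozygote count compatible with the observed allele
    counts, the conditional probabilities that do not exceed that of the
    observed genotype configuration.
    """
    counts = (n_hom_ref, n_het, n_hom_alt)
    if any(c < 0 or int(c) != c for c in counts):
        raise ValueError(f"genotype counts must be non-negative integers: {counts}")
    n = int(sum(counts))
    if n == 0:
        raise ValueError("empty genotype table")
    n_rare = min(2 * n_hom_ref + n_het, 2 * n_hom_alt + n_het)
    hets, logp = _hwe_log_probs(int(n_het), int(n_rare), n)
    obs = logp[hets == n_het]
    if obs.size != 1:  # pragma: no cover - guarded by count validation
        raise RuntimeError("observed configuration not in support")
    p = np.exp(logp[logp <= obs[0] + 1e-12]).sum()
    return float(min(p, 1.0))


def genotype_counts(dosages: np.ndarray) -> tuple[int, int, int]:
    d = np.asarray(dosages, dtype=float)
    d = d[~np.isnan(d)]
    return int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum())


def _imputed(dosages: np.ndarray) -> np.ndarray:
    """Column-mean imputation of missing dosages (float copy)."""
    d = np.array(dosages, dtype=float)
    if np.isnan(d).any():
        means = np.nanmean(d, axis=0)
        means = np.where(np.isnan(means), 0.0, means)
        idx = np.where(np.isnan(d))
        d[idx] = means[idx[1]]
    return d


def association_pvalues(dosages: np.ndarray, phenotype: np.ndarray,
                        strata: np.ndarray | None = None) -> np.ndarray:
    """Per-variant score (Cochran-Armitage trend) test of dosage vs phenotype.

    chi2 = n * r^2 where r is the Pearson correlation between dosage and
    case status; one degree of freedom. Zero-variance columns get p = 1.
    With ``strata`` (e.g. population labels), phenotype and dosages are
    centered within stratum first — a stratified score test that removes
    mean confounding by group membership.
    """
    d = _imputed(np.atleast_2d(np.asarray(dosages, dtype=float)))
    y = np.asarray(phenotype, dtype=float)
    n = d.shape[0]
    if strata is not None:
        s = np.asarray(strata)
        yc = y.copy()
        dc = d.copy()
        for g in np.unique(s):
            m = s == g
            yc[m] -= yc[m].mean()
            dc[m] -= dc[m].mean(axis=0)
    else:
        yc = y - y.mean()
        dc = d - d.mean(axis=0)
    denom = np.sqrt((dc**2).sum(axis=0) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (dc * yc[:, None]).sum(axis=0) / denom
    chi2 = n * np.square(np.where(np.isfinite(r), r, 0.0))
    return chi2_dist.sf(chi2, df=1)


def _r2_matrix(d: np.ndarray) -> np.ndarray:
    dc = d - d.mean(axis=0)
    sd = dc.std(axis=0)
    sd[sd == 0] = np.nan
    c = (dc.T @ dc) / d.shape[0]
    with np.errstate(invalid="ignore"):
        r = c / np.outer(sd, sd)
    r2 = np.square(r)
    np.fill_diagonal(r2, 0.0)
    return np.nan_to_num(r2)


def _prune_block(r2: np.ndarray, mafs: np.ndarray, pos: np.ndarray,
                 active: np.ndarray, r2_max: float) -> None:
    """Greedy in-place removal on one window until no pair has r2 >= r2_max.

    The pair with the highest r2 is resolved first; the member with the
    lower MAF is removed (tie: later position).
    """
    while True:
        sub = r2 * np.outer(active, active)
        i, j = np.unravel_index(int(np.argmax(sub)), sub.shape)
        if sub[i, j] < r2_max:
            return
        if (mafs[i], -pos[i]) < (mafs[j], -pos[j]):
            drop = i
        else:
            drop = j
        active[drop] = False


def ld_prune(cohort: Cohort, config: QCConfig, candidate_ids=None) -> list[str]:
    """Sliding-window LD pruning; returns retained variant ids in input order.

    Windows of ``ld_window`` variants advance by ``ld_step`` within each
    chromosome; within a window, one member of any pair with squared Pearson
    dosage correlation >= ``ld_r2_max`` is removed greedily.
    """
    variants = cohort.variants
    if candidate_ids is not None:
        keep = variants["variant_id"].isin(set(candidate_ids))
        variants = variants[keep]
    order = variants.sort_values(["chrom", "pos"]).index.to_numpy()
    col = {v: i for i, v in enumerate(cohort.variants["variant_id"])}
    removed: set[str] = set()
    for _, chrom_df in variants.loc[order].groupby("chrom", sort=True):
        vids = chrom_df["variant_id"].to_list()
        pos = chrom_df["pos"].to_numpy(float)
        cols = [col[v] for v in vids]
        d = _imputed(cohort.dosages[:, cols])
        mafs = np.array([maf(cohort.dosages[:, c]) for c in cols])
        n = len(vids)
        active = np.ones(n, dtype=bool)
        start = 0
        while True:
            stop = min(start + config.ld_window, n)
            sl = slice(start, stop)
            r2 = _r2_matrix(d[:, sl])
            act = active[sl].copy()
            _prune_block(r2, mafs[sl], pos[sl], act, config.ld_r2_max)
            active[sl] = act
            if stop >= n:
                break
            start += config.ld_step
        removed.update(v for v, a in zip(vids, active) if not a)
    return [v for v in variants["variant_id"] if v not in removed]


def qc_filter(cohort: Cohort, config: QCConfig | None = None) -> tuple[list[str], pd.DataFrame]:
    """MAF -> HWE -> LD filter pipeline. Returns retained ids and a report.

    Retention rules: MAF strictly greater than ``maf_min``; HWE exclusion iff
    exact p <= ``hwe_p_min``; then LD pruning on the survivors.
    """
    config = config or QCConfig()
    rows = []
    survivors = []
    for j, vid in enumerate(cohort.variants["variant_id"]):
        d = cohort.dosages[:, j]
        m = maf(d)
        hp = hwe_exact_p(*genotype_counts(d))
        if m <= config.maf_min:
            rows.append((vid, m, hp, "dropped", "maf"))
        elif hp <= config.hwe_p_min:
            rows.append((vid, m, hp, "dropped", "hwe"))
        else:
            rows.append((vid, m, hp, "kept", ""))
            survivors.append(vid)
    retained = set(ld_prune(cohort, config, candidate_ids=survivors))
    report = pd.DataFrame(rows, columns=["variant_id", "maf", "hwe_p", "status", "reason"])
    ld_dropped = report["variant_id"].isin(
        {v for v in survivors if v not in retained}
    )
    report.loc[ld_dropped, ["status", "reason"]] = ["dropped", "ld"]
    return [v for v in survivors if v in retained], report


def pca_top8(cohort: Cohort, variant_ids=None, n_components: int = 8) -> np.ndarray:
    """Top principal-component scores of the standardized dosage matrix.

    Missing dosages are column-mean imputed; zero-variance variants are
    dropped with a warning. Sign convention: the largest-magnitude loading
    of each component is made positive.
    """
    if variant_ids is None:
        variant_ids = list(cohort.variants["variant_id"])
    idx = cohort.variant_index(variant_ids)
    if cohort.n_samples < n_components + 1:
        raise ValueError(f"need at least {n_components + 1} samples")
    d = _imputed(cohort.dosages[:, idx])
    sd = d.std(axis=0)
    if (sd == 0).any():
        warnings.warn(f"dropping {(sd == 0).sum()} zero-variance variants from PCA")
        d = d[:, sd > 0]
        sd = sd[sd > 0]
    if d.shape[1] < n_components:
        raise ValueError(f"need at least {n_components} informative variants")
    z = (d - d.mean(axis=0)) / sd
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    scores = u[:, :n_components] * s[:n_components]
    for k in range(n_components):
        lead = np.argmax(np.abs(vt[k]))
        if vt[k, lead] < 0:
            scores[:, k] = -scores[:, k]
    return scores
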