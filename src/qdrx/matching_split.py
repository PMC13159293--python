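"""Propensity matching on ancestry PCs and TPE-optimized 1:1:1 partitioning.

Ancestry is summarized by a propensity score: a logistic regression of case
status on the top eight principal components, ``logit(pi) = b0 + b1*PC1 +
... + b8*PC8``. One-to-one nearest-neighbor matching on the score builds the
analytic case-control pairs. The matched pairs are then split 1:1:1 into
train/validation/test subsets by a seeded shuffle, and the splitting seed is
itself optimized with a Tree-structured Parzen Estimator so the chosen split
maximizes reference-SNP signal strength (f1, the median of the per-subset
median -log p) while minimizing cross-subset divergence (f2, the sum of
absolute pairwise differences of those medians).

Raw integer seeds carry no topology for TPE to learn, so the good/bad
densities l(x) and g(x) are estimated over structural split fingerprints
(decile-binned per-subset reference-SNP dosage means and case-count
imbalance) and candidate seeds are mapped through their fingerprints.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort
from .cohort_qc import association_pvalues, genotype_counts, hwe_exact_p, maf

log = logging.getLogger(__name__)

SUBSETS = ("train", "val", "test")


# ---------------------------------------------------------------------------
# propensity model and matching
# ---------------------------------------------------------------------------

@dataclass
class PropensityModel:
    intercept: float
    coefficients: np.ndarray  # one per PC
    scores: np.ndarray  # per-sample predicted case probability pi_i
    ridged: bool = False  # True when a tiny L2 fallback was needed


def fit_propensity(pcs: np.ndarray, phenotype: np.ndarray) -> PropensityModel:
    """Maximum-likelihood logistic fit of case status on the PC matrix.

    Perfect separation falls back to an L2 ridge of 1e-6 with a warning.
    """
    import statsmodels.api as sm

    x = np.asarray(pcs, dtype=float)
    y = np.asarray(phenotype, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    design = sm.add_constant(x, has_constant="add")
    ridged = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, design).fit(disp=0, maxiter=200)
        params = np.asarray(res.params, dtype=float)
        if not np.isfinite(params).all() or np.abs(params).max() > 1e3:
            raise np.linalg.LinAlgError("separation suspected")
    except Exception:  # perfect separation or singular design
        warnings.warn("propensity fit fell back to a 1e-6 L2 ridge")
        from sklearn.linear_model import LogisticRegression

        lr = LogisticRegression(C=1e6, max_iter=2000)
        lr.fit(x, y)
        params = np.concatenate([lr.intercept_, lr.coef_.ravel()])
        ridged = True
    from scipy.special import expit

    scores = expit(design @ params)
    return PropensityModel(
        intercept=float(params[0]),
        coefficients=params[1:].copy(),
        scores=scores,
        ridged=ridged,
    )


def match_pairs(scores: np.ndarray, phenotype: np.ndarray) -> pd.DataFrame:
    """Greedy 1:1 nearest-neighbor matching on propensity scores.

    Cases are processed in descending score order; each takes the unmatched
    control with the smallest |pi_case - pi_control| (ties: lower index).
    Surplus on either side is left unmatched. Returns a frame with columns
    pair_id, case_index, control_index, distance.
    """
    pi = np.asarray(scores, dtype=float)
    y = np.asarray(phenotype, dtype=int)
    cases = np.flatnonzero(y == 1)
    controls = np.flatnonzero(y == 0)
    if cases.size == 0 or controls.size == 0:
        raise ValueError("need at least one case and one control")
    order = cases[np.argsort(-pi[cases], kind="stable")]
    free = list(controls)
    rows = []
    for k, c in enumerate(order):
        if not free:
            break
        d = np.abs(pi[np.array(free)] - pi[c])
        j = int(np.argmin(d))
        rows.append((f"M{k:05d}", int(c), int(free[j]), float(d[j])))
        free.pop(j)
    return pd.DataFrame(rows, columns=["pair_id", "case_index", "control_index", "distance"])


def matched_cohort(cohort: Cohort, pairs: pd.DataFrame) -> Cohort:
    """Subset a cohort to the matched samples, rewriting pair ids."""
    idx, pair_ids = [], []
    for _, row in pairs.iterrows():
        idx += [row["case_index"], row["control_index"]]
        pair_ids += [row["pair_id"], row["pair_id"]]
    idx = np.array(idx, dtype=int)
    samples = cohort.samples.iloc[idx].reset_index(drop=True).assign(pair_id=pair_ids)
    return Cohort(
        samples=samples,
        dosages=cohort.dosages[idx].copy(),
        variants=cohort.variants.copy(),
    )


# ---------------------------------------------------------------------------
# reference SNPs and split objectives
# ---------------------------------------------------------------------------

def select_reference_snps(
    cohort: Cohort,
    n: int = 30,
    maf_min: float = 0.1,
    hwe_p_min: float = 1e-7,
    r2_max: float = 0.8,
) -> list[str]:
    """Top-n most associated variants passing strict QC, mutually in low LD.

    Candidates need MAF > 0.1 and HWE p > 1e-7; variants are then taken in
    ascending association-p order, skipping any with squared correlation
    >= ``r2_max`` to an already selected variant.
    """
    pvals = association_pvalues(cohort.dosages, cohort.phenotype())
    order = np.argsort(pvals, kind="stable")
    chosen: list[int] = []
    d = cohort.dosages
    for j in order:
        col = d[:, j]
        if maf(col) <= maf_min:
            continue
        if hwe_exact_p(*genotype_counts(col)) <= hwe_p_min:
            continue
        ok = True
        for k in chosen:
            a, b = col, d[:, k]
            r = np.corrcoef(a, b)[0, 1]
            if np.isfinite(r) and r * r >= r2_max:
                ok = False
                break
        if ok:
            chosen.append(int(j))
        if len(chosen) >= n:
            break
    return [cohort.variants["variant_id"].iloc[j] for j in chosen]


@dataclass(frozen=True)
class TrialRecord:
    seed: int
    m_train: float
    m_val: float
    m_test: float
    f1: float
    f2: float

    @property
    def objective(self) -> float:
        return self.f1 - self.f2


def _pair_groups(cohort: Cohort) -> tuple[list[str], dict[str, np.ndarray]]:
    if cohort.samples["pair_id"].isna().any():
        raise ValueError("split optimization requires a fully paired cohort")
    groups = cohort.samples.groupby("pair_id", sort=True).indices
    return sorted(groups), {k: np.asarray(v) for k, v in groups.items()}


def assign_pairs(pair_ids: list[str], seed: int) -> dict[str, str]:
    """Seeded 1:1:1 assignment of pairs to train/val/test (sizes within 1)."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pair_ids))
    out = {}
    for pos, k in enumerate(order):
        out[pair_ids[k]] = SUBSETS[pos % 3]
    return out


def split_masks(cohort: Cohort, assignment: dict[str, str]) -> dict[str, np.ndarray]:
    """Sample-level boolean masks for one pair-level assignment."""
    subset = cohort.samples["pair_id"].map(assignment)
    if subset.isna().any():
        raise ValueError("assignment does not cover all pairs")
    return {name: (subset == name).to_numpy() for name in SUBSETS}


def check_pair_integrity(cohort: Cohort, assignment: dict[str, str]) -> bool:
    """Both members of every pair must land in the same subset."""
    subset = cohort.samples["pair_id"].map(assignment)
    return bool(subset.groupby(cohort.samples["pair_id"]).nunique().eq(1).all())


def f_objectives(m_train: float, m_val: float, m_test: float) -> tuple[float, float]:
    """Signal strength f1 = median of the three subset medians; divergence
    f2 = sum of absolute pairwise differences. Both are label-symmetric."""
    ms = (m_train, m_val, m_test)
    f1 = float(np.median(ms))
    f2 = float(abs(ms[0] - ms[1]) + abs(ms[0] - ms[2]) + abs(ms[1] - ms[2]))
    return f1, f2


def split_objectives(
    cohort: Cohort,
    assignment: dict[str, str],
    reference_snps: list[str],
    seed: int = -1,
) -> TrialRecord:
    """Recompute the per-subset reference-SNP medians and fill a trial record.

    M_k is the median -log(p) (natural log) of the reference SNPs' score-test
    p-values within subset k; f1 = median(M_train, M_val, M_test) and f2 is
    the sum of absolute pairwise differences of the three medians.
    """
    masks = split_masks(cohort, assignment)
    cols = cohort.variant_index(reference_snps)
    y = cohort.phenotype()
    ms = {}
    for name in SUBSETS:
        m = masks[name]
        if m.sum() == 0:
            raise ValueError(f"subset {name!r} is empty")
        p = association_pvalues(cohort.dosages[np.ix_(m, cols)], y[m])
        ms[name] = float(np.median(-np.log(np.maximum(p, 1e-300))))
    f1, f2 = f_objectives(ms["train"], ms["val"], ms["test"])
    return TrialRecord(seed=seed, m_train=ms["train"], m_val=ms["val"],
                       m_test=ms["test"], f1=f1, f2=f2)


# ---------------------------------------------------------------------------
# TPE over split fingerprints
# ---------------------------------------------------------------------------

@dataclass
class TPEState:
    gamma: float = 0.25
    n_startup: int = 10
    history: list[tuple[int, float]] = field(default_factory=list)  # (seed, objective)

    def __post_init__(self) -> None:
        if not 0 < self.gamma < 1:
            raise ValueError("gamma must be in (0, 1)")


def _fingerprint(features: np.ndarray, edges: list[np.ndarray]) -> tuple[int, ...]:
    return tuple(
        int(np.searchsorted(edges[k], features[k], side="right"))
        for k in range(len(features))
    )


class SeedFingerprinter:
    """Maps candidate seeds to decile-binned structural split fingerprints.

    The raw features of a seed's split are the per-subset means of the
    per-sample reference-SNP dosage mean, plus the case-count imbalance
    across subsets; decile edges come from the candidate pool distribution.
    """

    def __init__(self, cohort: Cohort, reference_snps: list[str], pool: list[int]):
        self.pair_ids, groups = _pair_groups(cohort)
        cols = cohort.variant_index(reference_snps)
        snp_mean = np.nanmean(cohort.dosages[:, cols], axis=1)
        y = cohort.phenotype()
        self._pair_mean = np.array(
            [snp_mean[groups[p]].mean() for p in self.pair_ids]
        )
        self._pair_cases = np.array([y[groups[p]].sum() for p in self.pair_ids])
        raw = np.array([self._raw(s) for s in pool])
        qs = np.linspace(10, 90, 9)
        self._edges = [np.percentile(raw[:, k], qs) for k in range(raw.shape[1])]
        self._cache = {s: _fingerprint(raw[i], self._edges) for i, s in enumerate(pool)}

    def _raw(self, seed: int) -> np.ndarray:
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(self.pair_ids))
        feats = []
        for k in range(3):
            idx = order[k::3]  # same cyclic rule as assign_pairs
            feats.append(self._pair_mean[idx].mean())
        imbalance = float(np.ptp([self._pair_cases[order[k::3]].sum() for k in range(3)]))
        return np.array(feats + [imbalance])

    def fingerprint(self, seed: int) -> tuple[int, ...]:
        return self._cache[seed]


def propose_seed(
    state: TPEState,
    pool: list[int],
    fingerprinter: SeedFingerprinter,
    rng: np.random.Generator,
) -> int:
    """Next candidate seed by the density ratio l(x)/g(x) over fingerprints.

    Cold start (fewer than ``n_startup`` trials) and degenerate histories
    (all objectives equal, so l = g) fall back to a uniform seeded draw from
    the unexplored pool.
    """
    tried = {s for s, _ in state.history}
    unexplored = [s for s in pool if s not in tried]
    if not unexplored:
        raise ValueError("candidate seed pool exhausted")
    if len(state.history) < state.n_startup:
        return int(unexplored[rng.integers(len(unexplored))])

    objs = np.array([o for _, o in state.history])
    cut = np.quantile(objs, 1.0 - state.gamma)  # objective is maximized
    good = [s for s, o in state.history if o >= cut]
    bad = [s for s, o in state.history if o < cut]
    if not bad or np.ptp(objs) == 0:
        return int(unexplored[rng.integers(len(unexplored))])

    def density(seeds):
        counts: dict[tuple, int] = {}
        for s in seeds:
            fp = fingerprinter.fingerprint(s)
            counts[fp] = counts.get(fp, 0) + 1
        support = {fingerprinter.fingerprint(s) for s in pool}
        total = len(seeds) + len(support)  # Laplace +1 smoothing
        return {fp: (counts.get(fp, 0) + 1) / total for fp in support}

    l_d, g_d = density(good), density(bad)
    ratios = np.array(
        [l_d[fingerprinter.fingerprint(s)] / g_d[fingerprinter.fingerprint(s)]
         for s in unexplored]
    )
    best = np.flatnonzero(ratios == ratios.max())
    return int(unexplored[best[rng.integers(len(best))]])


@dataclass
class SplitResult:
    assignment: dict[str, str]  # pair_id -> subset
    best_trial: TrialRecord
    trials: pd.DataFrame


def optimize_split(
    cohort: Cohort,
    reference_snps: list[str],
    n_trials: int = 1000,
    seed: int = 0,
    f2_weight: float = 1.0,
    gamma: float = 0.25,
) -> SplitResult:
    """TPE search over partition seeds; returns the best pair-level split.

    Each trial assigns whole pairs 1:1:1 by its seed, scores f1 and f2 on the
    reference SNPs, and the scalarized objective J = f1 - f2_weight * f2 is
    maximized over the trial log. Pair integrity holds in every trial by
    construction and is asserted.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    pair_ids, _ = _pair_groups(cohort)
    if len(pair_ids) < 3:
        raise ValueError("need at least 3 pairs for a 1:1:1 split")
    rng = np.random.default_rng(seed)
    pool = list(range(max(4 * n_trials, 64)))
    fingerprinter = SeedFingerprinter(cohort, reference_snps, pool)
    state = TPEState(gamma=gamma)

    rows = []
    best: tuple[float, TrialRecord, dict[str, str]] | None = None
    for _ in range(n_trials):
        s = propose_seed(state, pool, fingerprinter, rng)
        assignment = assign_pairs(pair_ids, s)
        assert check_pair_integrity(cohort, assignment)
        rec = split_objectives(cohort, assignment, reference_snps, seed=s)
        j = rec.f1 - f2_weight * rec.f2
        state.history.append((s, j))
        rows.append((s, rec.m_train, rec.m_val, rec.m_test, rec.f1, rec.f2, j))
        if best is None or j > best[0]:
            best = (j, rec, assignment)

    trials = pd.DataFrame(
        rows, columns=["seed", "m_train", "m_val", "m_test", "f1", "f2", "J"]
    )
    return SplitResult(assignment=best[2], best_trial=best[1], trials=trials)
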