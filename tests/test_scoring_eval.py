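"""Gene/feature-set scoring vs double-loop oracles; rank-AUC; retrieval metrics."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from qdrx.cohort import Cohort
from qdrx.scoring_eval import (
    build_gene_scores,
    evaluate_feature_set,
    feature_set_score,
    gene_score,
    recall_sd,
    roc_auc,
    _fit_logistic_1d,
)


class TestGeneScore:
    @pytest.mark.parametrize("betas,genos,expected", [
        ([0.5], [2], 1.0),
        ([0.3, -0.7], [0, 0], 0.0),
        ([0.2, -0.1], [1, 2], 0.0),
        ([1.0, 1.0, 1.0], [1, 1, 1], 1.0),
    ])
    def test_examples(self, betas, genos, expected):
        assert gene_score(betas, genos) == pytest.approx(expected)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            gene_score([], [])

    def test_invalid_dosage_raises(self):
        with pytest.raises(ValueError):
            gene_score([0.5], [3])


def random_cohort(rng, n_samples=20, n_variants=15, n_genes=5):
    genes = [f"g{j % n_genes}" for j in range(n_variants)]
    samples = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n_samples)],
        "phenotype": rng.integers(0, 2, n_samples),
        "pair_id": [None] * n_samples,
        "population": [0] * n_samples,
    })
    variants = pd.DataFrame({
        "variant_id": [f"v{j}" for j in range(n_variants)],
        "chrom": "1",
        "pos": np.arange(1, n_variants + 1),
        "gene": genes,
        "beta": rng.normal(0, 0.5, n_variants),
        "p": rng.uniform(0, 1, n_variants),
    })
    dosages = rng.integers(0, 3, (n_samples, n_variants)).astype(float)
    return Cohort(samples=samples, dosages=dosages, variants=variants)


def oracle_gene_scores(cohort, p_threshold=0.05):
    """Naive double loop over samples and genes."""
    out = {}
    qual = cohort.variants[cohort.variants["p"] < p_threshold]
    for gene, grp in qual.groupby("gene"):
        col = []
        for i in range(cohort.n_samples):
            total = 0.0
            for _, row in grp.iterrows():
                j = cohort.variants.index.get_loc(row.name)
                total += row["beta"] * cohort.dosages[i, j]
            col.append(total / len(grp))
        out[gene] = col
    return pd.DataFrame(out, index=cohort.samples["sample_id"])


class TestScoreMatrix:
    def test_matches_double_loop_oracle(self, rng):
        for _ in range(5):
            cohort = random_cohort(rng)
            mine = build_gene_scores(cohort, p_threshold=0.5)
            oracle = oracle_gene_scores(cohort, p_threshold=0.5)
            assert sorted(mine.columns) == sorted(oracle.columns)
            assert np.allclose(mine[sorted(mine.columns)], oracle[sorted(mine.columns)])

    def test_feature_set_score_is_row_sum(self, rng):
        cohort = random_cohort(rng)
        scores = build_gene_scores(cohort, p_threshold=0.9)
        genes = list(scores.columns[:3])
        s = feature_set_score(scores, frozenset(genes))
        assert np.allclose(s, scores[genes].sum(axis=1))

    def test_additivity_over_disjoint_sets(self, rng):
        cohort = random_cohort(rng)
        scores = build_gene_scores(cohort, p_threshold=0.9)
        cols = list(scores.columns)
        f1, f2 = frozenset(cols[:2]), frozenset(cols[2:4])
        assert np.allclose(
            feature_set_score(scores, f1 | f2),
            feature_set_score(scores, f1) + feature_set_score(scores, f2),
        )

    def test_empty_after_restriction_raises(self, rng):
        cohort = random_cohort(rng)
        scores = build_gene_scores(cohort, p_threshold=0.9)
        with pytest.raises(ValueError):
            feature_set_score(scores, frozenset(["nope"]))

    def test_no_qualifying_variants_raises(self, rng):
        cohort = random_cohort(rng)
        with pytest.raises(ValueError):
            build_gene_scores(cohort, p_threshold=1e-12)


class TestRocAuc:
    def test_all_ties_half(self):
        assert roc_auc([1.0] * 6, [0, 1, 0, 1, 0, 1]) == pytest.approx(0.5)

    def test_perfect_separation(self):
        assert roc_auc([0.1, 0.4, 0.6, 0.9], [0, 0, 1, 1]) == pytest.approx(1.0)

    def test_one_swap_gives_three_quarters(self):
        assert roc_auc([0.1, 0.4, 0.6, 0.9], [0, 1, 0, 1]) == pytest.approx(0.75)

    def test_matches_sklearn_on_random_data(self, rng):
        for _ in range(30):
            n = int(rng.integers(10, 200))
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                continue
            s = np.round(rng.normal(size=n), 1)  # induce ties
            assert roc_auc(s, y) == pytest.approx(roc_auc_score(y, s))

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])


class TestLogisticFit:
    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        x = rng.normal(size=120)
        y = (rng.random(120) < 1 / (1 + np.exp(-(0.3 + 0.8 * x)))).astype(int)
        b0, b1 = _fit_logistic_1d(x, y)
        ref = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        assert b0 == pytest.approx(ref.params[0], abs=1e-4)
        assert b1 == pytest.approx(ref.params[1], abs=1e-4)

    def test_constant_feature_gives_intercept_only(self):
        y = np.array([0, 1, 1, 0, 1])
        b0, b1 = _fit_logistic_1d(np.ones(5), y)
        assert b1 == 0.0
        assert 1 / (1 + np.exp(-b0)) == pytest.approx(y.mean(), abs=1e-6)


class TestEvaluate:
    def make_inputs(self, rng, n=90):
        y = rng.integers(0, 2, n)
        s = y * 1.0 + rng.normal(0, 0.8, n)
        idx = np.arange(n)
        splits = {"train": idx[: n // 3], "val": idx[n // 3: 2 * n // 3],
                  "test": idx[2 * n // 3:]}
        return s, y, splits

    def test_metrics_within_unit_interval(self, rng):
        s, y, splits = self.make_inputs(rng)
        m = evaluate_feature_set(s, y, splits)
        for v in (m.recall, m.precision, m.f1, m.roc_auc, m.pr_auc):
            assert 0.0 <= v <= 1.0
        assert m.ad_detected + (m.ad_total - m.ad_detected) == m.ad_total

    def test_perfectly_separating_score(self, rng):
        y = np.array([0, 1] * 30)
        s = y.astype(float)
        splits = {"train": np.arange(30), "val": np.arange(30, 60)}
        m = evaluate_feature_set(s, y, splits)
        assert m.roc_auc == pytest.approx(1.0)
        assert m.recall == pytest.approx(1.0)

    def test_single_class_subset_raises(self, rng):
        s = rng.normal(size=20)
        y = np.array([1] * 10 + [0] * 10)
        splits = {"train": np.arange(10), "val": np.arange(10, 20)}
        with pytest.raises(ValueError):
            evaluate_feature_set(s, y, splits)


class TestRecallSD:
    def test_identical_runs_zero(self):
        assert recall_sd([0.7, 0.7, 0.7]) == pytest.approx(0.0, abs=1e-12)

    def test_hand_example(self):
        assert recall_sd([0.6, 0.8]) == pytest.approx(np.sqrt(2 * 0.01), abs=1e-9)

    def test_permutation_invariant(self, rng):
        vals = list(rng.random(8))
        perm = list(rng.permutation(vals))
        assert recall_sd(vals) == pytest.approx(recall_sd(perm))

    def test_single_run_raises(self):
        with pytest.raises(ValueError):
            recall_sd([0.5])
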