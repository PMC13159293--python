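"""Propensity matching and the optimized pair-preserving data partition."""

import numpy as np
import pandas as pd
import pytest

from qdrx.cohort import Cohort
from qdrx.matching_split import (
    SeedFingerprinter,
    TPEState,
    assign_pairs,
    check_pair_integrity,
    f_objectives,
    fit_propensity,
    match_pairs,
    matched_cohort,
    optimize_split,
    propose_seed,
    select_reference_snps,
    split_masks,
    split_objectives,
)
from qdrx.synthetic_data import SyntheticCohortConfig, SyntheticKGConfig, simulate_cohort, simulate_kg


@pytest.fixture(scope="module")
def paired_cohort():
    kg, _ = simulate_kg(SyntheticKGConfig(n_genes=100, n_drugs=30, seed=2))
    cfg = SyntheticCohortConfig(
        n_pairs=60, n_variants=150, seed=3,
        planted_effect_genes=tuple(f"G{i:04d}" for i in range(5)), effect_size=0.6,
    )
    return simulate_cohort(cfg, kg)


class TestPropensity:
    def test_identical_pcs_give_case_fraction(self):
        pcs = np.ones((40, 8))
        y = np.array([1] * 15 + [0] * 25)
        model = fit_propensity(pcs, y)
        assert np.allclose(model.scores, y.mean(), atol=1e-3)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            fit_propensity(np.random.default_rng(0).normal(size=(10, 8)), np.ones(10))

    def test_confounded_population_has_higher_scores(self, paired_cohort):
        from qdrx.cohort_qc import pca_top8

        pcs = pca_top8(paired_cohort)
        model = fit_propensity(pcs, paired_cohort.phenotype())
        pop = paired_cohort.samples["population"].to_numpy()
        # generator shifts case probability up in the last population
        assert model.scores[pop == 1].mean() > model.scores[pop == 0].mean()


class TestMatchPairs:
    def test_hand_example_greedy_equals_optimal(self):
        scores = np.array([0.9, 0.1, 0.85, 0.2])
        pheno = np.array([1, 1, 0, 0])
        pairs = match_pairs(scores, pheno)
        got = {(r.case_index, r.control_index) for r in pairs.itertuples()}
        assert got == {(0, 2), (1, 3)}

    def test_surplus_cases_left_unmatched(self):
        pairs = match_pairs(np.array([0.5, 0.6, 0.7, 0.4]), np.array([1, 1, 1, 0]))
        assert len(pairs) == 1

    def test_equal_scores_all_matched(self):
        n = 10
        pairs = match_pairs(np.full(2 * n, 0.5), np.array([1] * n + [0] * n))
        assert len(pairs) == n

    def test_matched_cohort_pair_integrity(self, paired_cohort):
        from qdrx.cohort_qc import pca_top8

        model = fit_propensity(pca_top8(paired_cohort), paired_cohort.phenotype())
        pairs = match_pairs(model.scores, paired_cohort.phenotype())
        sub = matched_cohort(paired_cohort, pairs)
        grp = sub.samples.groupby("pair_id")["phenotype"]
        assert (grp.size() == 2).all() and (grp.sum() == 1).all()

    def test_matching_reduces_confounding(self, paired_cohort):
        from qdrx.cohort_qc import pca_top8

        model = fit_propensity(pca_top8(paired_cohort), paired_cohort.phenotype())
        pi, y = model.scores, paired_cohort.phenotype()
        pairs = match_pairs(pi, y)
        matched_gap = pairs["distance"].mean()
        rng = np.random.default_rng(0)
        gaps = []
        for _ in range(3):
            cases = rng.permutation(np.flatnonzero(y == 1))
            controls = rng.permutation(np.flatnonzero(y == 0))
            k = min(len(cases), len(controls))
            gaps.append(np.abs(pi[cases[:k]] - pi[controls[:k]]).mean())
        assert matched_gap < min(gaps)


class TestSplitObjectives:
    def test_formula_hand_example(self):
        f1, f2 = f_objectives(1.0, 2.0, 4.0)
        assert f1 == 2.0 and f2 == pytest.approx(1 + 3 + 2)

    def test_identical_medians_zero_divergence(self):
        f1, f2 = f_objectives(3.0, 3.0, 3.0)
        assert f1 == 3.0 and f2 == 0.0

    def test_label_permutation_invariance(self, rng):
        for _ in range(20):
            a, b, c = rng.normal(size=3)
            base = f_objectives(a, b, c)
            assert f_objectives(c, a, b) == pytest.approx(base)

    def test_split_objectives_on_cohort(self, paired_cohort):
        refs = select_reference_snps(paired_cohort, n=10)
        pair_ids = sorted(paired_cohort.samples["pair_id"].unique())
        assignment = assign_pairs(pair_ids, seed=0)
        rec = split_objectives(paired_cohort, assignment, refs)
        assert rec.f1 == pytest.approx(np.median([rec.m_train, rec.m_val, rec.m_test]))
        assert rec.f2 >= 0

    def test_empty_subset_raises(self, paired_cohort):
        refs = select_reference_snps(paired_cohort, n=5)
        pair_ids = sorted(paired_cohort.samples["pair_id"].unique())
        assignment = {p: "train" for p in pair_ids}
        with pytest.raises(ValueError):
            split_objectives(paired_cohort, assignment, refs)


class TestReferenceSNPs:
    def test_count_and_qc_filters(self, paired_cohort):
        refs = select_reference_snps(paired_cohort, n=10, maf_min=0.1)
        assert len(refs) == 10
        from qdrx.cohort_qc import maf

        idx = paired_cohort.variant_index(refs)
        for j in idx:
            assert maf(paired_cohort.dosages[:, j]) > 0.1


class _StubFingerprinter:
    def __init__(self, mapping):
        self.mapping = mapping

    def fingerprint(self, seed):
        return self.mapping[seed]


class TestTPE:
    def test_cold_start_uniform_and_seeded(self):
        state = TPEState()
        fp = _StubFingerprinter({s: (0,) for s in range(20)})
        rng1 = np.random.default_rng(5)
        rng2 = np.random.default_rng(5)
        pool = list(range(20))
        assert propose_seed(state, pool, fp, rng1) == propose_seed(state, pool, fp, rng2)

    def test_degenerate_equal_objectives_falls_back(self):
        state = TPEState()
        state.history = [(s, 1.0) for s in range(12)]
        fp = _StubFingerprinter({s: (s % 3,) for s in range(30)})
        seed = propose_seed(state, list(range(30)), fp, np.random.default_rng(0))
        assert seed not in {s for s, _ in state.history}

    def test_good_bin_dominates_proposal(self):
        # fingerprints: bin 0 is always good (high J), bin 1 always bad
        mapping = {s: ((0,) if s % 2 == 0 else (1,)) for s in range(40)}
        state = TPEState()
        state.history = [(s, 10.0 if s % 2 == 0 else -10.0) for s in range(12)]
        fp = _StubFingerprinter(mapping)
        for trial in range(5):
            seed = propose_seed(state, list(range(40)), fp, np.random.default_rng(trial))
            assert mapping[seed] == (0,)

    def test_exhausted_pool_raises(self):
        state = TPEState()
        state.history = [(0, 1.0)]
        fp = _StubFingerprinter({0: (0,)})
        with pytest.raises(ValueError):
            propose_seed(state, [0], fp, np.random.default_rng(0))


class TestOptimizeSplit:
    @pytest.fixture(scope="class")
    def result(self, paired_cohort):
        refs = select_reference_snps(paired_cohort, n=10)
        return optimize_split(paired_cohort, refs, n_trials=60, seed=7), refs

    def test_pair_integrity_and_balance(self, paired_cohort, result):
        res, _ = result
        assert check_pair_integrity(paired_cohort, res.assignment)
        masks = split_masks(paired_cohort, res.assignment)
        sizes = sorted(m.sum() // 2 for m in masks.values())
        assert sizes[-1] - sizes[0] <= 1

    def test_best_trial_dominates_log(self, result):
        res, _ = result
        assert (res.best_trial.f1 - res.best_trial.f2) >= res.trials["J"].max() - 1e-12

    def test_selected_f2_not_worse_than_median(self, result):
        res, _ = result
        assert res.best_trial.f2 <= res.trials["f2"].median()

    def test_invalid_trial_count(self, paired_cohort):
        with pytest.raises(ValueError):
            optimize_split(paired_cohort, [], n_trials=0)

    def test_fingerprinter_deterministic(self, paired_cohort):
        refs = select_reference_snps(paired_cohort, n=5)
        pool = list(range(50))
        f1 = SeedFingerprinter(paired_cohort, refs, pool)
        f2 = SeedFingerprinter(paired_cohort, refs, pool)
        assert all(f1.fingerprint(s) == f2.fingerprint(s) for s in pool)
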