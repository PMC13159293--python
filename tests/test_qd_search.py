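"""Archive mechanics, descriptors, variation, NSGA-II vs a Pareto oracle."""

import numpy as np
import pytest

from qdrx.feature_engineering import FeatureSet
from qdrx.graph_embeddings import EmbeddingTable
from qdrx.qd_search import (
    Archive,
    DescriptorSpace,
    Individual,
    SearchConfig,
    archive_update,
    bin_descriptor,
    crossover,
    crowding_distance,
    descriptor,
    fast_non_dominated_sort,
    freeze_edges,
    mutate,
    rank_drugs,
    run_map_elites,
    run_random_search,
)
from qdrx.scoring_eval import MetricsRecord


def toy_embeddings():
    """Ten genes on a line; anchors g0, g1 (centroid at x = 0.5)."""
    ids = [f"g{i}" for i in range(10)]
    vecs = np.zeros((10, 2))
    vecs[:, 0] = np.arange(10, dtype=float)
    vecs[1, 0] = 1.0
    return EmbeddingTable(ids=ids, vectors=vecs, kind="gene")


def toy_metrics(q):
    return MetricsRecord(recall=q, precision=q, f1=q, roc_auc=q, pr_auc=q)


def toy_evaluator(genes):
    """Deterministic quality: normalized digit sum, in [0, 1]."""
    q = (sum(int(g[1:]) for g in genes) % 17) / 16.0
    return toy_metrics(q)


@pytest.fixture()
def toy_space():
    emb = toy_embeddings()
    ds = DescriptorSpace(emb, ["g0", "g1"])
    sets = [frozenset({f"g{i}"}) for i in range(10)]
    ds.freeze(sets)
    return emb, ds


class TestDescriptor:
    def test_anchor_centroid_gene_is_origin(self):
        emb = toy_embeddings()
        emb.vectors[5] = emb.subset(["g0", "g1"]).mean(axis=0)
        d = descriptor(frozenset({"g5"}), emb, ["g0", "g1"])
        assert d == (pytest.approx(0.0), pytest.approx(0.0))

    def test_mean_linearity(self):
        emb = toy_embeddings()
        d2 = descriptor(frozenset({"g2"}), emb, ["g0", "g1"])
        d8 = descriptor(frozenset({"g8"}), emb, ["g0", "g1"])
        d28 = descriptor(frozenset({"g2", "g8"}), emb, ["g0", "g1"])
        assert d28[0] == pytest.approx((d2[0] + d8[0]) / 2)
        assert d28[1] == pytest.approx((d2[1] + d8[1]) / 2)

    def test_hand_computed_five_gene_toy(self):
        emb = toy_embeddings()
        genes = ["g2", "g3", "g4", "g6", "g9"]
        centroid = np.array([0.5, 0.0])
        expected_euclid = np.mean([abs(emb.vector(g)[0] - 0.5) for g in genes])
        d = descriptor(frozenset(genes), emb, ["g0", "g1"])
        assert d[0] == pytest.approx(expected_euclid)

    def test_missing_embedding_names_gene(self):
        emb = toy_embeddings()
        with pytest.raises(KeyError, match="gX"):
            descriptor(frozenset({"gX"}), emb, ["g0", "g1"])


class TestBinning:
    def test_boundary_rules(self):
        edges = (np.array([1.0, 2.0, 3.0]), np.array([10.0, 20.0, 30.0]))
        assert bin_descriptor((0.5, 5.0), edges) == (0, 0)
        assert bin_descriptor((99.0, 99.0), edges) == (3, 3)
        assert bin_descriptor((2.0, 20.0), edges) == (2, 2)  # right-open at the cut

    def test_unfrozen_edges_raise(self):
        with pytest.raises(ValueError):
            bin_descriptor((0.0, 0.0), None)

    def test_freeze_edges_are_quartiles(self, rng):
        pts = rng.normal(size=(200, 2))
        e0, e1 = freeze_edges(pts)
        assert np.allclose(e0, np.percentile(pts[:, 0], [25, 50, 75]))
        assert np.allclose(e1, np.percentile(pts[:, 1], [25, 50, 75]))


class TestArchiveUpdate:
    def make(self):
        edges = (np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0]))
        return Archive(edges)

    def ind(self, q, d=(0.5, 0.5)):
        return Individual(genes=frozenset({"g"}), quality=q, descriptor=d)

    def test_empty_cell_accepts(self):
        a = self.make()
        assert archive_update(a, self.ind(0.6)) is True

    def test_lower_quality_rejected(self):
        a = self.make()
        archive_update(a, self.ind(0.65))
        assert archive_update(a, self.ind(0.60)) is False
        assert a.cells[(0, 0)].quality == 0.65

    def test_tie_keeps_incumbent(self):
        a = self.make()
        first = self.ind(0.6)
        archive_update(a, first)
        challenger = self.ind(0.6)
        assert archive_update(a, challenger) is False
        assert a.cells[(0, 0)] is first

    def test_unevaluated_raises(self):
        a = self.make()
        with pytest.raises(ValueError):
            archive_update(a, Individual(genes=frozenset({"g"})))


class TestVariation:
    def test_mutation_respects_bounds_and_nonempty(self, rng):
        cfg = SearchConfig(min_size=2, max_size=5)
        universe = [f"g{i}" for i in range(10)]
        s = frozenset(universe[:4])
        for _ in range(200):
            s2 = mutate(s, rng, universe, None, cfg)
            assert 1 <= len(s2) <= 5
            assert s2 <= set(universe)

    def test_crossover_keeps_intersection(self, rng):
        a = frozenset({"g1", "g2", "g3"})
        b = frozenset({"g2", "g3", "g4"})
        for _ in range(50):
            child = crossover(a, b, rng)
            assert {"g2", "g3"} <= child <= (a | b)

    def test_cluster_biased_addition_draws_from_pools(self, rng):
        cfg = SearchConfig(p_cluster=1.0)
        universe = [f"g{i}" for i in range(10)]
        pools = {0: ("g0", "g1", "g2"), 1: ("g7", "g8", "g9")}
        hits = 0
        for _ in range(300):
            s2 = mutate(frozenset({"g0"}), rng, universe, pools, cfg)
            added = s2 - {"g0"}
            if added and added <= {"g1", "g2"}:
                hits += 1
        assert hits > 0


class TestMapElites:
    def test_zero_generations_is_initialization_only(self, toy_space):
        _, ds = toy_space
        sets = [FeatureSet(label=i, genes=frozenset({f"g{i}", f"g{i+1}"})) for i in range(4)]
        cfg = SearchConfig(generations=0, seed=0)
        archive, hist = run_map_elites(sets, toy_evaluator, ds, [f"g{i}" for i in range(10)], None, cfg)
        assert len(hist) == 1
        assert archive.coverage >= 1

    def test_qd_score_monotone_and_invariants(self, toy_space):
        _, ds = toy_space
        sets = [FeatureSet(label=i, genes=frozenset({f"g{i}", f"g{i+1}"})) for i in range(4)]
        cfg = SearchConfig(generations=25, batch_per_gen=10, seed=1, max_size=4)
        archive, hist = run_map_elites(sets, toy_evaluator, ds, [f"g{i}" for i in range(10)], None, cfg)
        qd = hist["qd_score"].to_numpy()
        assert (np.diff(qd) >= -1e-12).all()
        archive.check_invariants()

    def test_deterministic_given_seed(self, toy_space):
        _, ds = toy_space
        sets = [FeatureSet(label=0, genes=frozenset({"g0", "g3"}))]
        cfg = SearchConfig(generations=10, batch_per_gen=8, seed=9, max_size=5)
        runs = []
        for _ in range(2):
            emb = toy_embeddings()
            ds2 = DescriptorSpace(emb, ["g0", "g1"])
            ds2.edges = ds.edges
            a, _ = run_map_elites(sets, toy_evaluator, ds2, [f"g{i}" for i in range(10)], None, cfg)
            runs.append(a.to_json())
        assert runs[0] == runs[1]


class TestRandomSearch:
    def test_budget_one_single_evaluation(self, toy_space):
        _, ds = toy_space
        calls = []

        def counting(genes):
            calls.append(genes)
            return toy_evaluator(genes)

        sets = [FeatureSet(label=0, genes=frozenset({"g0", "g3"}))]
        out = run_random_search(sets, counting, ds, [f"g{i}" for i in range(10)], None,
                                budget=1, seed=0)
        assert len(calls) == 1 and len(out) == 1

    def test_budget_parity_with_map_elites(self, toy_space):
        """Total evaluations equal generations x batch (plus initialization)."""
        _, ds = toy_space
        calls = []

        def counting(genes):
            calls.append(genes)
            return toy_evaluator(genes)

        sets = [FeatureSet(label=0, genes=frozenset({"g0", "g3"}))]
        cfg = SearchConfig(generations=6, batch_per_gen=7, seed=2, max_size=5)
        run_map_elites(sets, counting, ds, [f"g{i}" for i in range(10)], None, cfg)
        assert len(calls) == len(sets) + 6 * 7


def pareto_oracle(objs):
    """O(n^2) dominance scan for the non-dominated subset (maximization)."""
    objs = np.asarray(objs, float)
    front = []
    for i in range(len(objs)):
        dominated = any(
            (objs[j] >= objs[i]).all() and (objs[j] > objs[i]).any()
            for j in range(len(objs)) if j != i
        )
        if not dominated:
            front.append(i)
    return sorted(front)


class TestNSGA2:
    def test_fronts_match_pareto_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 64))
            objs = rng.normal(size=(n, 2))
            fronts = fast_non_dominated_sort(objs)
            assert fronts[0] == pareto_oracle(objs)
            # successive fronts are the oracle of the remaining points
            remaining = list(range(n))
            for front in fronts:
                sub_oracle = [remaining[k] for k in pareto_oracle(objs[remaining])]
                assert front == sorted(sub_oracle)
                remaining = [i for i in remaining if i not in set(front)]
            assert not remaining

    def test_single_point_is_front_zero(self):
        assert fast_non_dominated_sort(np.array([[1.0, 2.0]])) == [[0]]

    def test_crowding_boundary_infinite(self, rng):
        objs = rng.normal(size=(12, 2))
        front = pareto_oracle(objs)
        cd = crowding_distance(objs, front)
        lo = int(np.argmin(objs[front, 0]))
        hi = int(np.argmax(objs[front, 0]))
        assert np.isinf(cd[lo]) and np.isinf(cd[hi])


class TestRankDrugs:
    def test_exact_target_match_retrieved(self, kg_small):
        kg, _ = kg_small
        drug = kg.drugs()[0]
        targets = kg.drug_targets(drug)
        edges = (np.array([1.0, 2.0, 3.0]),) * 2
        archive = Archive(edges)
        ind = Individual(genes=frozenset(targets), quality=0.9, descriptor=(0.5, 0.5))
        archive.update(ind)
        ranked = rank_drugs([archive], kg)
        assert int(ranked.loc[ranked.drug_id == drug, "retrieval_count"].iloc[0]) == 1

    def test_drug_without_overlap_count_zero(self, kg_small):
        kg, _ = kg_small
        edges = (np.array([1.0, 2.0, 3.0]),) * 2
        archive = Archive(edges)
        archive.update(Individual(genes=frozenset({"NOT_A_TARGET"}), quality=0.9,
                                  descriptor=(0.5, 0.5)))
        ranked = rank_drugs([archive], kg)
        assert (ranked["retrieval_count"] == 0).all()

    def test_empty_archive_list_raises(self, kg_small):
        kg, _ = kg_small
        with pytest.raises(ValueError):
            rank_drugs([], kg)
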