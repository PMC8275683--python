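import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from implinet.core_io import ExpressionMatrix, SampleAnnotation
from implinet.network_builder import ClusterEdge, ClusterNetwork, GeneCluster
from implinet.path_engine import (
    BooleanPath,
    enumerate_paths,
    evaluate_signature,
    fisher_exact_2x2,
    normalize_expression,
    roc_auc,
    score_samples,
    select_best_path,
)
from implinet.stepminer import binarize_matrix


def brute_force_auc(scores, labels):
    """Oracle: average over all positive-negative pairs, ties at 0.5."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def enumerate_fisher_two_sided(table):
    """Oracle: enumerate all tables with the observed margins."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return (math.comb(r1, x) * math.comb(r2, c1 - x)) / math.comb(n, c1)

    p_obs = prob(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


def linear_network():
    clusters = [
        GeneCluster("C1", frozenset({"a1", "a2", "a3"}), "healthy"),
        GeneCluster("C2", frozenset({"b1", "b2", "b3"}), "healthy"),
        GeneCluster("C3", frozenset({"c1", "c2", "c3"}), "disease"),
    ]
    edges = [
        ClusterEdge("C1", "C2", "EQUIVALENT", 1.0, 5.0),
        ClusterEdge("C2", "C3", "OPPOSITE", 1.0, 5.0),
    ]
    return ClusterNetwork(clusters, edges)


class TestEnumeratePaths:
    def test_linear_three_node(self):
        paths = enumerate_paths(linear_network(), max_len=5)
        assert [p.clusters for p in paths] == [("C1", "C2"), ("C1", "C2", "C3"), ("C2", "C3")]

    def test_weights_are_side_signed(self):
        paths = {p.clusters: p for p in enumerate_paths(linear_network())}
        assert paths[("C1", "C2", "C3")].weights == (1.0, 1.0, -1.0)

    def test_equivalent_edge_across_sides_inadmissible(self):
        net = linear_network()
        net.edges[1] = ClusterEdge("C2", "C3", "EQUIVALENT", 1.0, 5.0)
        paths = enumerate_paths(net)
        assert [p.clusters for p in paths] == [("C1", "C2")]

    def test_cycle_terminates(self):
        clusters = [GeneCluster(f"C{i}", frozenset({f"g{i}a", f"g{i}b", f"g{i}c"}), "healthy")
                    for i in (1, 2, 3)]
        edges = [ClusterEdge("C1", "C2", "OPPOSITE", 1.0, 5.0),
                 ClusterEdge("C2", "C3", "OPPOSITE", 1.0, 5.0),
                 ClusterEdge("C3", "C1", "OPPOSITE", 1.0, 5.0)]
        paths = enumerate_paths(ClusterNetwork(clusters, edges), max_len=5)
        chains = [p.clusters for p in paths]
        assert len(chains) == len(set(chains))
        assert all(len(set(c)) == len(c) for c in chains)

    def test_max_len_error(self):
        with pytest.raises(ValueError, match="max_len"):
            enumerate_paths(linear_network(), max_len=1)

    def test_random_dag_matches_dfs_oracle(self, rng):
        nodes = [f"C{i}" for i in range(1, 9)]
        clusters = [GeneCluster(n, frozenset({f"{n}x", f"{n}y", f"{n}z"}), "healthy")
                    for n in nodes]
        edges = []
        for i, j in itertools.combinations(range(8), 2):
            if rng.random() < 0.3:
                edges.append(ClusterEdge(nodes[i], nodes[j], "OPPOSITE", 1.0, 4.0))
        net = ClusterNetwork(clusters, edges)
        max_len = 5
        adjacency = {n: sorted(e.target for e in edges if e.source == n) for n in nodes}

        oracle = set()

        def dfs(chain):
            if 2 <= len(chain) <= max_len:
                oracle.add(tuple(chain))
            if len(chain) == max_len:
                return
            for nxt in adjacency[chain[-1]]:
                if nxt not in chain:
                    dfs(chain + [nxt])

        for start in nodes:
            dfs([start])
        got = {p.clusters for p in enumerate_paths(net, max_len=max_len)}
        assert got == oracle


class TestNormalize:
    def test_threshold_maps_to_zero(self, small_matrix):
        _, fits = binarize_matrix(small_matrix)
        normalized = normalize_expression(small_matrix, fits)
        x = small_matrix.values[0]
        t = fits["g1"].threshold
        idx = np.argmin(np.abs(x - t))
        # value equal to t would map exactly to 0
        assert normalized.values[0][idx] == pytest.approx((x[idx] - t) / x.std())

    def test_constant_gene_all_zeros(self, small_matrix):
        _, fits = binarize_matrix(small_matrix)
        normalized = normalize_expression(small_matrix, fits)
        assert np.allclose(normalized.row("g3"), 0.0)

    def test_recomputation_oracle(self, rng):
        matrix = ExpressionMatrix(
            [f"g{i}" for i in range(20)], [f"s{j}" for j in range(30)],
            rng.normal(size=(20, 30)),
        )
        _, fits = binarize_matrix(matrix)
        normalized = normalize_expression(matrix, fits)
        for i, gene in enumerate(matrix.gene_ids):
            sd = matrix.values[i].std()
            expected = (matrix.values[i] - fits[gene].threshold) / (sd if sd else 1.0)
            assert np.allclose(normalized.values[i], expected)


class TestScoreSamples:
    def _normalized(self, values, genes, samples):
        return ExpressionMatrix(genes, samples, np.asarray(values, dtype=float))

    def test_two_cluster_arithmetic(self):
        # cluster means (0.8, -0.2) with weights (+1, -1) -> score 1.0
        normalized = self._normalized([[0.8], [-0.2]], ["a1", "b1"], ["s1"])
        clusters = [GeneCluster("C1", frozenset({"a1", "x1", "x2"})),
                    GeneCluster("C2", frozenset({"b1", "y1", "y2"}))]
        path = BooleanPath(("C1", "C2"), ("OPPOSITE",), (1.0, -1.0))
        scores = score_samples(path, normalized, clusters)
        assert scores["s1"] == pytest.approx(1.0)

    def test_empty_cluster_error(self):
        normalized = self._normalized([[0.5]], ["a1"], ["s1"])
        clusters = [GeneCluster("C1", frozenset({"zzz", "yyy", "xxx"}))]
        path = BooleanPath(("C1",), (), (1.0,))
        with pytest.raises(ValueError, match="no genes"):
            score_samples(path, normalized, clusters)

    def test_zero_weight_cluster_no_effect(self, rng):
        genes = [f"g{i}" for i in range(6)]
        normalized = self._normalized(rng.normal(size=(6, 10)), genes, [f"s{j}" for j in range(10)])
        clusters = [GeneCluster("C1", frozenset(genes[:3])),
                    GeneCluster("C2", frozenset(genes[3:]))]
        short = BooleanPath(("C1",), (), (1.0,))
        padded = BooleanPath(("C1", "C2"), ("OPPOSITE",), (1.0, 0.0))
        assert np.allclose(score_samples(short, normalized, clusters),
                           score_samples(padded, normalized, clusters))

    def test_weight_scaling_scales_scores(self, rng):
        genes = [f"g{i}" for i in range(6)]
        normalized = self._normalized(rng.normal(size=(6, 12)), genes, [f"s{j}" for j in range(12)])
        clusters = [GeneCluster("C1", frozenset(genes[:3])),
                    GeneCluster("C2", frozenset(genes[3:]))]
        base = BooleanPath(("C1", "C2"), ("OPPOSITE",), (1.0, -1.0))
        tripled = BooleanPath(("C1", "C2"), ("OPPOSITE",), (3.0, -3.0))
        s1 = score_samples(base, normalized, clusters).to_numpy()
        s3 = score_samples(tripled, normalized, clusters).to_numpy()
        assert np.allclose(s3, 3 * s1)
        labels = (rng.random(12) > 0.5).astype(int)
        if 0 < labels.sum() < 12:
            assert roc_auc(s1, labels) == pytest.approx(roc_auc(s3, labels))


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1]) == 1.0

    def test_all_ties(self):
        assert roc_auc([5, 5, 5, 5], [0, 1, 0, 1]) == 0.5

    def test_worked_example(self):
        assert roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_single_class_error(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([1, 2, 3], [1, 1, 1])

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=50, deadline=None)
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 40))
        scores = rng.integers(0, 6, n).astype(float)  # integer scores force ties
        labels = rng.integers(0, 2, n)
        if labels.sum() in (0, n):
            labels[0] = 1 - labels[0]
        assert roc_auc(scores, labels) == pytest.approx(brute_force_auc(scores, labels))


class TestFisher:
    def test_uniform_table(self):
        assert fisher_exact_2x2([[1, 1], [1, 1]]) == pytest.approx(1.0)

    def test_two_by_two_enumeration(self):
        assert fisher_exact_2x2([[2, 0], [0, 2]]) == pytest.approx(1 / 3)

    def test_ten_by_ten_enumeration(self):
        assert fisher_exact_2x2([[10, 0], [0, 10]]) == pytest.approx(2 / math.comb(20, 10))

    def test_all_zero_error(self):
        with pytest.raises(ValueError, match="all-zero"):
            fisher_exact_2x2([[0, 0], [0, 0]])

    def test_negative_error(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, -1], [1, 1]])

    @given(st.tuples(*[st.integers(0, 15)] * 4))
    @settings(max_examples=100, deadline=None)
    def test_matches_enumeration_oracle(self, counts):
        a, b, c, d = counts
        if a + b + c + d == 0:
            return
        table = [[a, b], [c, d]]
        assert fisher_exact_2x2(table) == pytest.approx(
            enumerate_fisher_two_sided(table), rel=1e-6
        )


def _cohort_with_clusters(seed=0, delta=3.0, n=100):
    from conftest import planted_spec
    from implinet.implication import all_pairs_network
    from implinet.network_builder import (
        build_cluster_network,
        build_equivalence_graph,
        cluster_genes,
        orient_clusters,
    )
    from implinet.stepminer import dynamic_range_filter
    from implinet.synthetic_data import generate_cohort

    matrix, ann, truth = generate_cohort(planted_spec(seed=seed, n_samples=n, delta=delta))
    ternary, fits = binarize_matrix(matrix)
    results = all_pairs_network(ternary, dynamic_range_filter(ternary))
    clusters = cluster_genes(build_equivalence_graph(results))
    clusters = orient_clusters(clusters, matrix, ann, fits)
    network = build_cluster_network(clusters, results)
    normalized = normalize_expression(matrix, fits)
    return matrix, ann, truth, clusters, network, normalized


class TestSelectBestPath:
    def test_single_candidate_returned(self, small_annotation):
        normalized = ExpressionMatrix(
            ["a1", "a2", "a3"], ["s1", "s2", "s3", "s4"],
            np.array([[1.0, 1.0, -1.0, -1.0]] * 3),
        )
        clusters = [GeneCluster("C1", frozenset({"a1", "a2", "a3"}), "healthy")]
        path = BooleanPath(("C1",), (), (1.0,))
        selection = select_best_path([path], normalized, clusters, small_annotation, "healthy")
        assert selection.chosen.path is path

    def test_perfectly_separating_path_chosen(self, small_annotation):
        genes = ["a1", "a2", "a3", "b1", "b2", "b3"]
        values = np.vstack([
            np.tile([1.0, 1.0, -1.0, -1.0], (3, 1)),       # tracks label exactly
            np.tile([0.1, -0.2, 0.15, -0.05], (3, 1)),     # noise
        ])
        normalized = ExpressionMatrix(genes, ["s1", "s2", "s3", "s4"], values)
        clusters = [GeneCluster("C1", frozenset({"a1", "a2", "a3"}), "healthy"),
                    GeneCluster("C2", frozenset({"b1", "b2", "b3"}), "healthy")]
        signal = BooleanPath(("C1",), (), (1.0,))
        noise = BooleanPath(("C2",), (), (1.0,))
        selection = select_best_path([noise, signal], normalized, clusters,
                                     small_annotation, "healthy")
        assert selection.chosen.path is signal
        assert selection.chosen.pvalue == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_labels_error(self):
        ann = SampleAnnotation.from_labels(["s1", "s2", "s3", "s4"], ["x"] * 4)
        normalized = ExpressionMatrix(["a1"], ["s1", "s2", "s3", "s4"],
                                      np.zeros((1, 4)))
        clusters = [GeneCluster("C1", frozenset({"a1"}))]
        path = BooleanPath(("C1",), (), (1.0,))
        with pytest.raises(ValueError, match="two classes"):
            select_best_path([path], normalized, clusters, ann)

    def test_noise_path_never_beats_signal_over_seeds(self):
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 60
            labels = np.array([1] * 30 + [0] * 30)
            signal_rows = labels[None, :] * 2.0 - 1.0 + rng.normal(0, 0.5, (3, n))
            noise_rows = rng.normal(0, 1, (3, n))
            normalized = ExpressionMatrix(
                ["a1", "a2", "a3", "b1", "b2", "b3"],
                [f"s{i}" for i in range(n)],
                np.vstack([signal_rows, noise_rows]),
            )
            ann = SampleAnnotation.from_labels(
                normalized.sample_ids, ["healthy" if l else "disease" for l in labels]
            )
            clusters = [GeneCluster("C1", frozenset({"a1", "a2", "a3"}), "healthy"),
                        GeneCluster("C2", frozenset({"b1", "b2", "b3"}), "healthy")]
            signal = BooleanPath(("C1",), (), (1.0,))
            noise = BooleanPath(("C2",), (), (1.0,))
            chosen = select_best_path([noise, signal], normalized, clusters, ann,
                                      "healthy").chosen
            wins += chosen.path is signal
        assert wins == 20

    def test_planted_path_scores_separate_classes(self):
        matrix, ann, truth, clusters, network, normalized = _cohort_with_clusters(seed=3)
        paths = enumerate_paths(network)
        selection = select_best_path(paths, normalized, clusters, ann, "healthy")
        scores = score_samples(selection.chosen.path, normalized, clusters)
        labels = [1 if truth["labels"][s] == "healthy" else 0 for s in normalized.sample_ids]
        assert roc_auc(scores.to_numpy(), labels) >= 0.95


class TestEvaluateSignature:
    def test_path_mode_matches_score_samples(self):
        matrix, ann, truth, clusters, network, normalized = _cohort_with_clusters(seed=4)
        paths = enumerate_paths(network)
        chosen = select_best_path(paths, normalized, clusters, ann, "healthy").chosen
        report = evaluate_signature(matrix, ann, chosen.path, clusters=clusters,
                                    positive_label="healthy")
        direct = score_samples(chosen.path, normalized, clusters)
        labels = [1 if truth["labels"][s] == "healthy" else 0 for s in matrix.sample_ids]
        assert report["auc"] == pytest.approx(roc_auc(direct.to_numpy(), labels))

    def test_gene_set_mode(self):
        matrix, ann, truth, clusters, network, normalized = _cohort_with_clusters(seed=5)
        up = set(truth["equivalence_classes"]["healthy_up"])
        down = set(truth["equivalence_classes"]["disease_up"])
        report = evaluate_signature(matrix, ann, (up, down), positive_label="healthy")
        assert report["auc"] >= 0.95
        assert report["fisher_p"] < 1e-6

    def test_label_shuffle_gives_half_auc(self):
        matrix, ann, truth, clusters, network, normalized = _cohort_with_clusters(seed=6)
        up = set(truth["equivalence_classes"]["healthy_up"])
        down = set(truth["equivalence_classes"]["disease_up"])
        rng = np.random.default_rng(0)
        labels = np.array(ann.table["class_label"])
        aucs = []
        for _ in range(50):
            rng.shuffle(labels)
            shuffled = SampleAnnotation.from_labels(ann.sample_ids, labels)
            aucs.append(
                evaluate_signature(matrix, shuffled, (up, down), positive_label="healthy")["auc"]
            )
        assert abs(float(np.mean(aucs)) - 0.5) <= 0.05

    def test_effect_size_ranks_cohorts(self):
        # deltas small enough that the composite score does not saturate
        from conftest import planted_spec
        from implinet.synthetic_data import generate_cohort

        reports = {}
        for delta in (0.2, 2.0):
            matrix, ann, truth = generate_cohort(
                planted_spec(seed=8, n_samples=150, delta=delta)
            )
            up = set(truth["equivalence_classes"]["healthy_up"])
            down = set(truth["equivalence_classes"]["disease_up"])
            reports[delta] = evaluate_signature(matrix, ann, (up, down),
                                                positive_label="healthy")["auc"]
        assert reports[2.0] > reports[0.2]

    def test_missing_genes_error(self, small_matrix, small_annotation):
        with pytest.raises(ValueError, match="missing"):
            evaluate_signature(small_matrix, small_annotation, ({"zz"}, {"qq"}))
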