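import networkx as nx
import numpy as np
import pytest

from essrank import AnnotationTable, PPINetwork, ProteinRegistry, features


def make_ppi(n, edges):
    net = PPINetwork(ProteinRegistry([f"p{i}" for i in range(n)]))
    for u, v in edges:
        net.add_edge(u, v)
    return net


class TestLocationScores:
    def test_counts_to_weights(self):
        ann = AnnotationTable()
        vocab = ["a", "b", "c"]
        # counts (30, 10, 20)
        for i in range(30):
            ann.subcellular[f"x{i}"] = {"a"}
        for i in range(10):
            ann.subcellular[f"y{i}"] = {"b"}
        for i in range(20):
            ann.subcellular[f"z{i}"] = {"c"}
        loc = features.location_scores(ann, vocab)
        assert loc.average == pytest.approx(20)
        assert loc.eve.tolist() == pytest.approx([1.5, 0.5, 1.0])
        # invariant: weights sum to the number of compartments
        assert loc.eve.sum() == pytest.approx(len(vocab))

    def test_uniform_counts_give_unit_weights(self):
        ann = AnnotationTable()
        for i, c in enumerate(["a", "b"]):
            ann.subcellular[f"p{i}"] = {c}
        loc = features.location_scores(ann, ["a", "b"])
        assert loc.eve.tolist() == [1.0, 1.0]

    def test_empty_vocabulary_rejected(self):
        with pytest.raises(ValueError):
            features.location_scores(AnnotationTable(), [])

    def test_prosub_sums_member_compartments(self):
        ann = AnnotationTable()
        for i in range(3):
            ann.subcellular[f"a{i}"] = {"a"}
        ann.subcellular["b0"] = {"b"}
        ann.subcellular["q"] = {"a", "b"}
        loc = features.location_scores(ann, ["a", "b"])
        got = features.prosub("q", loc, ann)
        assert got == pytest.approx(loc.eve.sum())  # member of all compartments
        assert features.prosub("missing", loc, ann) == 0.0


class TestProOrt:
    def test_max_normalization(self):
        assert features.proort(np.array([0, 5, 10])).tolist() == [0, 0.5, 1.0]

    def test_all_zero_guarded(self):
        assert features.proort(np.zeros(3)).tolist() == [0, 0, 0]

    def test_single_protein(self):
        assert features.proort(np.array([7])).tolist() == [1.0]


class TestPCC:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ([1, 2, 3], [2, 4, 6], 1.0),
            ([1, 2, 3], [3, 2, 1], -1.0),
            ([1, 0, 1, 0], [1, 0, 0, 1], 0.0),
        ],
    )
    def test_known_values(self, x, y, expected):
        assert features.pcc(np.array(x), np.array(y)) == pytest.approx(expected)

    def test_constant_vector_gives_zero(self):
        assert features.pcc(np.array([1.0, 1.0, 1.0]), np.array([1, 2, 3])) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            features.pcc(np.array([1, 2]), np.array([1, 2, 3]))

    def test_matches_numpy_corrcoef(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            x, y = rng.normal(size=(2, 10))
            assert features.pcc(x, y) == pytest.approx(np.corrcoef(x, y)[0, 1])


class TestProExp:
    def test_isolated_protein_scores_zero(self):
        net = make_ppi(3, [(0, 1)])
        ann = AnnotationTable()
        rng = np.random.default_rng(0)
        for i in range(3):
            ann.expression[f"p{i}"] = rng.normal(size=5)
        assert features.proexp(net, ann)[2] == 0.0

    def test_negative_sums_floored_before_normalization(self):
        # p0-p1 perfectly anticorrelated, p2-p3 perfectly correlated
        net = make_ppi(4, [(0, 1), (2, 3)])
        ann = AnnotationTable()
        ann.expression["p0"] = np.array([1.0, 2.0, 3.0])
        ann.expression["p1"] = np.array([3.0, 2.0, 1.0])
        ann.expression["p2"] = np.array([1.0, 2.0, 3.0])
        ann.expression["p3"] = np.array([2.0, 4.0, 6.0])
        out = features.proexp(net, ann)
        assert out[0] == 0.0 and out[1] == 0.0  # floored at 0
        assert out[2] == pytest.approx(1.0) and out[3] == pytest.approx(1.0)

    def test_missing_expression_contributes_zero(self):
        net = make_ppi(2, [(0, 1)])
        ann = AnnotationTable()
        ann.expression["p0"] = np.array([1.0, 2.0, 3.0])
        assert features.proexp(net, ann).tolist() == [0.0, 0.0]


class TestProTri:
    def test_triangle_all_nodes_max(self):
        net = make_ppi(3, [(0, 1), (0, 2), (1, 2)])
        raw = features.protri(net, normalize=False)
        assert raw.tolist() == [1.0, 1.0, 1.0]  # (1+1)/2 per node

    def test_star_center_zero(self):
        net = make_ppi(4, [(0, 1), (0, 2), (0, 3)])
        assert features.protri(net, normalize=False).tolist() == [0, 0, 0, 0]

    def test_path_middle_zero(self):
        net = make_ppi(3, [(0, 1), (1, 2)])
        assert features.protri(net, normalize=False)[1] == 0.0

    def test_matches_triangle_count_oracle(self):
        # raw score equals 2 * triangles(k) / degree(k)
        rng = np.random.default_rng(17)
        for _ in range(20):
            g = nx.gnp_random_graph(rng.integers(4, 21), 0.3, seed=int(rng.integers(1 << 30)))
            net = make_ppi(g.number_of_nodes(), g.edges())
            raw = features.protri(net, normalize=False)
            tri = nx.triangles(g)
            for k in g.nodes():
                deg = g.degree(k)
                expected = 2 * tri[k] / deg if deg else 0.0
                assert raw[k] == pytest.approx(expected)


class TestEntropyWeights:
    def test_constant_column_gets_zero_weight(self):
        bf = np.column_stack([np.full(10, 0.5), np.eye(10)[0]])
        e, w = features.entropy_weights(bf)
        assert e[0] == pytest.approx(1.0)
        assert e[1] == pytest.approx(0.0)
        assert w.tolist() == pytest.approx([0.0, 1.0])

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            bf = rng.random((rng.integers(2, 30), 3))
            _, w = features.entropy_weights(bf)
            assert w.sum() == pytest.approx(1.0)
            assert (w >= 0).all()

    def test_all_max_entropy_falls_back_to_uniform(self):
        bf = np.ones((5, 3))
        _, w = features.entropy_weights(bf)
        assert w.tolist() == pytest.approx([1 / 3] * 3)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(8)
        bf = rng.random((12, 3))
        _, w = features.entropy_weights(bf)
        _, w_perm = features.entropy_weights(bf[rng.permutation(12)])
        assert w.tolist() == pytest.approx(w_perm.tolist())

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            features.entropy_weights(np.array([[1.0, -0.1], [0.5, 0.2]]))


class TestFusion:
    def test_single_weight_selects_column(self):
        bf = np.array([[0.2, 9.0], [0.8, 9.0]])
        assert features.fuse(bf, np.array([1.0, 0.0])).tolist() == [0.2, 0.8]

    def test_dot_product(self):
        bf = np.array([[0.2, 0.4, 0.6]])
        assert features.fuse(bf, np.array([0.5, 0.3, 0.2]))[0] == pytest.approx(0.34)

    def test_initial_score_limits(self):
        bio = np.array([1.0, 0.0])
        tri = np.array([0.0, 1.0])
        assert features.initial_score(bio, tri, 1.0).tolist() == [1.0, 0.0]
        assert features.initial_score(bio, tri, 0.0).tolist() == [0.0, 1.0]

    def test_initial_score_sums_to_one(self):
        rng = np.random.default_rng(2)
        s = features.initial_score(rng.random(10), rng.random(10), 0.65)
        assert s.sum() == pytest.approx(1.0)

    def test_lambda_out_of_range(self):
        with pytest.raises(ValueError):
            features.initial_score(np.ones(2), np.ones(2), 1.5)


class TestComputeFeatures:
    def test_all_columns_in_unit_interval(self, small_dataset):
        ds = small_dataset
        ft = features.compute_features(ds.ppi, ds.annotations)
        for col in (ft.bf[:, 0], ft.bf[:, 1], ft.bf[:, 2], ft.pro_tri):
            assert col.min() >= 0 and col.max() <= 1 + 1e-12
        assert ft.weights.sum() == pytest.approx(1.0)
        assert ft.proscore.sum() == pytest.approx(1.0)
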