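import numpy as np
import pytest

from phenomkl import (EvalConfig, KernelMatrix, KernelStack, combine_kernels,
                      decision_values, learn_global_weights,
                      learn_hierarchical_weights, nearest_psd, parse_newick,
                      rbf_kernel, train_svm, FeatureTable)


def label_kernel(y, noise, rng):
    """PSD kernel aligned with the labels plus a PSD noise ridge."""
    n = len(y)
    base = 0.5 * np.outer(y, y).astype(float)
    a = rng.standard_normal((n, n))
    return base + 0.1 * (a @ a.T) / n + 0.5 * np.eye(n)


def noisy_feature_kernel(labels, rng, shift=0.8, d=12):
    """Linear kernel of noisy label-shifted features: informativeness grows
    smoothly with the kernel's weight in a combination."""
    n = len(labels)
    X = rng.standard_normal((n, d))
    X[:, 0] += shift * labels
    return X @ X.T / d


def random_problem(n=30, seed=0):
    rng = np.random.default_rng(seed)
    y = np.where(rng.random(n) < 0.5, 1, -1)
    X = rng.standard_normal((n, 4)) + 0.5 * y[:, None]
    ft = FeatureTable(tuple(f"s{i}" for i in range(n)),
                      tuple(f"f{j}" for j in range(4)), X)
    return rbf_kernel(ft, sigma=2.0), y


class TestCombineKernels:
    def setup_method(self):
        rng = np.random.default_rng(0)
        y = np.where(rng.random(8) < 0.5, 1, -1)
        ids = tuple(f"s{i}" for i in range(8))
        self.K1 = KernelMatrix(ids, label_kernel(y, 0.1, rng))
        self.K2 = KernelMatrix(ids, label_kernel(-y, 0.1, rng))

    def test_single_modality_identity(self):
        st = KernelStack(("a",), (self.K1,))
        assert np.allclose(combine_kernels(st).values, self.K1.values)

    def test_duplicated_modality_uniform_is_same_matrix(self):
        st = KernelStack(("a", "b"), (self.K1, self.K1))
        assert np.allclose(combine_kernels(st).values, self.K1.values)

    def test_degenerate_weight_selects_first(self):
        st = KernelStack(("a", "b"), (self.K1, self.K2))
        assert np.allclose(combine_kernels(st, (1.0, 0.0)).values, self.K1.values)

    def test_id_mismatch_rejected(self):
        other = KernelMatrix(tuple(f"x{i}" for i in range(8)), self.K2.values)
        with pytest.raises(ValueError):
            KernelStack(("a", "b"), (self.K1, other))


class TestLearnGlobalWeights:
    def test_single_modality_weight_one(self):
        K, y = random_problem(seed=1)
        st = KernelStack(("only",), (K,))
        assert learn_global_weights(st, y) == (1.0,)

    def test_informative_kernel_dominates(self):
        wins = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = 60
            y = np.where(rng.random(n) < 0.5, 1, -1)
            perm = rng.permutation(n)
            ids = tuple(f"s{i}" for i in range(n))
            K_good = KernelMatrix(ids, noisy_feature_kernel(y, rng))
            K_bad = KernelMatrix(ids, noisy_feature_kernel(y[perm], rng))
            st = KernelStack(("good", "bad"), (K_good, K_bad))
            w = learn_global_weights(st, y, EvalConfig(seed=seed))
            if w[0] > 0.5:
                wins += 1
        assert wins >= 4

    def test_weights_on_simplex(self):
        K, y = random_problem(seed=2)
        st = KernelStack(("a", "b"), (K, K))
        w = learn_global_weights(st, y, EvalConfig(seed=2))
        assert sum(w) == pytest.approx(1.0)
        assert all(x >= 0 for x in w)

    def test_single_class_rejected(self):
        K, _ = random_problem(seed=3)
        st = KernelStack(("a",), (K, ))
        with pytest.raises(ValueError):
            learn_global_weights(st, np.ones(K.n, dtype=int))


class TestTrainSVM:
    def test_separable_signs_match(self):
        ft = FeatureTable(("a", "b"), ("f",), np.array([[-1.0], [1.0]]))
        K = rbf_kernel(ft, 1.0)
        model = train_svm(K, [-1, 1], C=10.0)
        f = decision_values(model, K.values)
        assert np.sign(f[0]) == -1 and np.sign(f[1]) == 1

    def test_separable_training_accuracy_at_large_c(self):
        rng = np.random.default_rng(4)
        n = 40
        y = np.where(np.arange(n) < n // 2, 1, -1)
        X = rng.standard_normal((n, 3)) + 3.0 * y[:, None]
        ft = FeatureTable(tuple(map(str, range(n))), ("a", "b", "c"), X)
        K = rbf_kernel(ft, sigma=3.0)
        model = train_svm(K, y, C=1e4)
        assert (np.sign(decision_values(model, K.values)) == y).all()

    def test_kkt_conditions(self):
        K, y = random_problem(n=30, seed=5)
        C = 1.0
        model = train_svm(K, y, C)
        alpha = model.alphas
        assert (alpha >= -1e-9).all() and (alpha <= C + 1e-9).all()
        assert abs(model.alpha_signed.sum()) < 1e-6  # sum alpha_i y_i = 0
        f = decision_values(model, K.values)
        margins = y * f
        for i in range(len(y)):
            if alpha[i] < 1e-8:
                assert margins[i] >= 1 - 1e-3
            elif alpha[i] < C - 1e-8:
                assert abs(margins[i] - 1) <= 1e-3

    def test_support_vectors_cover_margin_band(self):
        K, y = random_problem(n=40, seed=6)
        model = train_svm(K, y, C=1.0)
        f = decision_values(model, K.values)
        inside = np.abs(f) < 1 - 1e-3
        assert (model.alphas[inside] > 0).all()

    def test_indefinite_kernel_refused(self):
        S = KernelMatrix(("a", "b"), np.array([[1.0, 2.0], [2.0, 1.0]]))
        with pytest.raises(ValueError, match="nearest_psd"):
            train_svm(S, [1, -1], C=1.0)
        corrected = nearest_psd(S.values, "flip", sample_ids=("a", "b"))
        train_svm(corrected, [1, -1], C=1.0)  # accepted after correction

    def test_label_flip_negates_decision_values(self):
        K, y = random_problem(n=24, seed=7)
        f1 = decision_values(train_svm(K, y, 1.0), K.values)
        f2 = decision_values(train_svm(K, -y, 1.0), K.values)
        # agreement up to the dual solver's stopping tolerance
        assert np.allclose(f1, -f2, atol=2e-3)

    def test_column_count_mismatch_rejected(self):
        K, y = random_problem(n=10, seed=8)
        model = train_svm(K, y, 1.0)
        with pytest.raises(ValueError):
            decision_values(model, K.values[:, :5])


class TestHierarchicalWeights:
    def test_single_task_tree_reduces_to_global(self):
        tree = parse_newick("(A);")
        rng = np.random.default_rng(9)
        n = 40
        y = np.where(rng.random(n) < 0.5, 1, -1)
        ids = tuple(f"s{i}" for i in range(n))
        K1 = KernelMatrix(ids, label_kernel(y, 0.1, rng))
        K2 = KernelMatrix(ids, label_kernel(y[rng.permutation(n)], 0.1, rng))
        st = KernelStack(("good", "bad"), (K1, K2))
        cfg = EvalConfig(seed=9)
        hw = learn_hierarchical_weights(tree, st, ["A"] * n, y, cfg)
        gw = learn_global_weights(st, y, cfg)
        # every node block is the full cohort, so node-level modality weights
        # match the global wrapper result
        for node_w in hw.per_node_modality_weights.values():
            assert node_w == pytest.approx(gw)

    def test_small_blocks_fall_back_to_uniform(self):
        tree = parse_newick("(A,B);")
        rng = np.random.default_rng(10)
        n = 8  # below the min_block threshold everywhere
        y = np.array([1, -1] * 4)
        ids = tuple(f"s{i}" for i in range(n))
        K1 = KernelMatrix(ids, label_kernel(y, 0.1, rng))
        st = KernelStack(("a", "b"), (K1, K1))
        hw = learn_hierarchical_weights(tree, st, ["A", "B"] * 4, y,
                                        EvalConfig(seed=10, min_block=10))
        for node in ("A", "B"):
            assert hw.per_node_modality_weights[node] == pytest.approx((0.5, 0.5))
        assert sum(hw.node_weights.values()) == pytest.approx(1.0)

    def test_planted_subset_signal_localizes_phenotype_weight(self):
        # phenotype kernel informative only inside the {A,B} subtree
        tree = parse_newick("((A,B),C);")
        wins = 0
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            n = 90
            tasks = [("A", "B", "C")[i % 3] for i in range(n)]
            y = np.where(rng.random(n) < 0.5, 1, -1)
            ids = tuple(f"s{i}" for i in range(n))
            in_ab = np.array([t in ("A", "B") for t in tasks])
            y_pheno = np.where(in_ab, y, y[rng.permutation(n)])
            K_pheno = KernelMatrix(ids, noisy_feature_kernel(y_pheno, rng))
            K_struct = KernelMatrix(ids, noisy_feature_kernel(y[rng.permutation(n)], rng))
            st = KernelStack(("structure", "phenotype"), (K_struct, K_pheno))
            hw = learn_hierarchical_weights(tree, st, tasks, y,
                                            EvalConfig(seed=seed))
            node_ab = next(nd for nd, s in tree.node_subsets.items()
                           if s == {"A", "B"})
            w_ab = hw.per_node_modality_weights[node_ab][1]
            w_c = hw.per_node_modality_weights["C"][1]
            if w_ab > w_c:
                wins += 1
        assert wins >= 4

    def test_empty_subset_rejected(self):
        tree = parse_newick("(A,B);")
        rng = np.random.default_rng(11)
        y = np.array([1, -1, 1, -1])
        ids = tuple(f"s{i}" for i in range(4))
        K = KernelMatrix(ids, label_kernel(y, 0.1, rng))
        st = KernelStack(("a",), (K,))
        with pytest.raises(ValueError, match="empty"):
            learn_hierarchical_weights(tree, st, ["A"] * 4, y, EvalConfig())
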