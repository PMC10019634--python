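import numpy as np
import pytest

from phenomkl import (HierWeights, KernelMatrix, TaskSimilarityMatrix,
                      check_psd, hierarchical_kernel, latent_task_similarity,
                      multitask_kernel, parse_newick, subset_kernels,
                      task_similarity)


@pytest.fixture()
def tree3():
    return parse_newick("((A,B),C);")


@pytest.fixture()
def tree2():
    return parse_newick("(A,B);")


class TestParseNewick:
    def test_three_leaf_subsets(self, tree3):
        assert len(tree3.nodes) == 5
        subsets = set(map(frozenset, tree3.node_subsets.values()))
        assert subsets == {frozenset({"A"}), frozenset({"B"}), frozenset({"C"}),
                           frozenset({"A", "B"}), frozenset({"A", "B", "C"})}

    def test_two_leaf_root_subset(self, tree2):
        assert len(tree2.nodes) == 3
        assert tree2.node_subsets[tree2.root] == {"A", "B"}

    def test_duplicate_leaf_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            parse_newick("(A,A);")

    def test_unbalanced_parentheses_rejected(self):
        with pytest.raises(ValueError):
            parse_newick("((A,B;")

    def test_file_roundtrip(self, tmp_path, tree3):
        p = tmp_path / "t.nwk"
        p.write_text(tree3.newick() + "\n")
        again = parse_newick(p)
        assert again.leaves == tree3.leaves
        assert set(map(frozenset, again.node_subsets.values())) == \
            set(map(frozenset, tree3.node_subsets.values()))


class TestTaskSimilarity:
    def test_two_leaf_baseline_one(self, tree2):
        K = task_similarity(tree2, a=1)
        i, j = K.index("A"), K.index("B")
        # leaves share only the root: c = 1, c_max = 2
        assert K.values[i, j] == pytest.approx(2 / 3)
        assert K.values[i, i] == pytest.approx(1.0)

    def test_max_depth_diagonal_is_one(self, tree3):
        K = task_similarity(tree3, a=5)
        i = K.index("A")
        assert K.values[i, i] == pytest.approx(1.0)

    def test_union_limit(self, tree3):
        K = task_similarity(tree3, a=1e9)
        assert np.allclose(K.values, 1.0, atol=1e-8)

    def test_entries_increase_with_a(self, tree3):
        lo = task_similarity(tree3, a=1).values
        hi = task_similarity(tree3, a=100).values
        off = ~np.eye(3, dtype=bool)
        assert (hi[off] >= lo[off] - 1e-12).all()

    def test_nonpositive_a_rejected(self, tree2):
        with pytest.raises(ValueError):
            task_similarity(tree2, a=0)


def toy_kernel(n, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.standard_normal((n, n + 1))
    K = a @ a.T
    d = np.sqrt(np.diag(K))
    return KernelMatrix(tuple(f"s{i}" for i in range(n)), K / np.outer(d, d))


class TestMultitaskKernel:
    def test_identity_task_kernel_is_block_diagonal(self):
        Kb = toy_kernel(4)
        tasks = ["A", "A", "B", "B"]
        Kt = TaskSimilarityMatrix(("A", "B"), np.eye(2))
        out = multitask_kernel(Kb, tasks, Kt)
        assert np.allclose(out.values[:2, 2:], 0.0)
        assert np.allclose(out.values[:2, :2], Kb.values[:2, :2])

    def test_all_ones_task_kernel_is_union(self):
        Kb = toy_kernel(4)
        Kt = TaskSimilarityMatrix(("A", "B"), np.ones((2, 2)))
        out = multitask_kernel(Kb, ["A", "B", "A", "B"], Kt)
        assert np.allclose(out.values, Kb.values)

    def test_two_by_two_entrywise(self):
        Kb = KernelMatrix(("s0", "s1"), np.array([[1.0, 0.4], [0.4, 1.0]]))
        Kt = TaskSimilarityMatrix(("A", "B"), np.array([[1.0, 0.5], [0.5, 1.0]]))
        out = multitask_kernel(Kb, ["A", "B"], Kt)
        assert np.allclose(out.values, [[1.0, 0.2], [0.2, 1.0]])

    def test_unknown_task_rejected(self):
        Kb = toy_kernel(2)
        Kt = TaskSimilarityMatrix(("A",), np.ones((1, 1)))
        with pytest.raises(ValueError, match="Z"):
            multitask_kernel(Kb, ["A", "Z"], Kt)

    def test_schur_product_preserves_psd(self, tree3):
        Kb = toy_kernel(9, seed=3)
        tasks = ["A", "B", "C"] * 3
        Kt = task_similarity(tree3, a=3)
        out = multitask_kernel(Kb, tasks, Kt)
        ok, _ = check_psd(out)
        assert ok


class TestSubsetAndHierarchical:
    def make(self, tree, n=6, seed=1):
        K = toy_kernel(n, seed)
        tasks = [tree.leaves[i % len(tree.leaves)] for i in range(n)]
        return K, tasks

    def test_root_subset_unchanged(self, tree3):
        K, tasks = self.make(tree3)
        subs = subset_kernels(tree3, K, tasks)
        assert np.allclose(subs[tree3.root].values, K.values)

    def test_leaf_subset_zero_outside_block(self, tree3):
        K, tasks = self.make(tree3)
        subs = subset_kernels(tree3, K, tasks)
        member = np.array([t == "C" for t in tasks])
        out = subs["C"].values
        assert np.allclose(out[~np.outer(member, member)], 0.0)
        assert np.allclose(out[np.outer(member, member)],
                           K.values[np.outer(member, member)])

    def test_internal_node_mask_oracle(self, tree3):
        K, tasks = self.make(tree3)
        node = next(n for n, s in tree3.node_subsets.items()
                    if s == {"A", "B"})
        member = np.array([t in {"A", "B"} for t in tasks])
        expect = np.where(np.outer(member, member), K.values, 0.0)
        assert np.allclose(subset_kernels(tree3, K, tasks)[node].values, expect)

    def test_root_weight_reproduces_union(self, tree3):
        K, tasks = self.make(tree3)
        subs = subset_kernels(tree3, K, tasks)
        w = HierWeights({n: (1.0 if n == tree3.root else 0.0)
                         for n in tree3.nodes}, {})
        assert np.allclose(hierarchical_kernel(subs, w).values, K.values)

    def test_leaf_weights_reproduce_scaled_dirac(self, tree3):
        K, tasks = self.make(tree3)
        subs = subset_kernels(tree3, K, tasks)
        leaves = set(tree3.leaves)
        w = HierWeights({n: (1 / 3 if n in leaves else 0.0)
                         for n in tree3.nodes}, {})
        out = hierarchical_kernel(subs, w).values
        same_task = np.equal.outer(np.array(tasks, dtype=object),
                                   np.array(tasks, dtype=object))
        expect = np.where(same_task, K.values / 3, 0.0)
        assert np.allclose(out, expect)

    def test_two_leaf_uniform_thirds(self, tree2):
        K, tasks = self.make(tree2, n=4, seed=2)
        subs = subset_kernels(tree2, K, tasks)
        w = HierWeights({n: 1 / 3 for n in tree2.nodes}, {})
        out = hierarchical_kernel(subs, w).values
        same = np.equal.outer(np.array(tasks, dtype=object),
                              np.array(tasks, dtype=object))
        expect = np.where(same, 2 / 3 * K.values, 1 / 3 * K.values)
        assert np.allclose(out, expect)

    def test_equals_brute_force_node_loop(self, tree3):
        K, tasks = self.make(tree3, n=9, seed=4)
        subs = subset_kernels(tree3, K, tasks)
        rng = np.random.default_rng(0)
        beta = rng.dirichlet(np.ones(len(tree3.nodes)))
        w = HierWeights(dict(zip(tree3.nodes, beta)), {})
        expect = np.zeros_like(K.values)
        for node, b in w.node_weights.items():
            member = np.array([t in tree3.node_subsets[node] for t in tasks])
            expect += b * np.where(np.outer(member, member), K.values, 0.0)
        assert np.allclose(hierarchical_kernel(subs, w).values, expect, atol=1e-12)

    def test_weight_node_mismatch_rejected(self, tree3):
        K, tasks = self.make(tree3)
        subs = subset_kernels(tree3, K, tasks)
        w = HierWeights({tree3.root: 1.0}, {})
        with pytest.raises(ValueError):
            hierarchical_kernel(subs, w)


class TestLatentTaskSimilarity:
    def test_root_only_gives_all_ones(self, tree3):
        w = HierWeights({n: (1.0 if n == tree3.root else 0.0)
                         for n in tree3.nodes}, {})
        g = latent_task_similarity(tree3, w)
        assert np.allclose(g.values, 1.0)

    def test_two_leaf_uniform_thirds(self, tree2):
        w = HierWeights({n: 1 / 3 for n in tree2.nodes}, {})
        g = latent_task_similarity(tree2, w)
        i, j = g.index("A"), g.index("B")
        assert g.values[i, j] == pytest.approx(1 / 3)
        assert g.values[i, i] == pytest.approx(2 / 3)

    def test_diagonal_dominance_and_brute_force(self, tree3):
        rng = np.random.default_rng(1)
        beta = rng.dirichlet(np.ones(len(tree3.nodes)))
        w = HierWeights(dict(zip(tree3.nodes, beta)), {})
        g = latent_task_similarity(tree3, w)
        for k, tk in enumerate(tree3.leaves):
            expect = sum(b for n, b in w.node_weights.items()
                         if tk in tree3.node_subsets[n])
            assert g.values[k, k] == pytest.approx(expect)
            assert g.values[k, k] >= g.values[k].max() - 1e-12
        assert np.allclose(g.values, g.values.T)
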