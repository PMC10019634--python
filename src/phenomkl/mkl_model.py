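"""Multiple-kernel combination and the kernel C-SVM.

Modality kernels (task, sequence/structure RBF, phenotype) are combined as a
convex sum K = Σ_m β_m K_m. Weights are either uniform, learned globally with
a wrapper (model-in-the-loop) search over the simplex, or learned per node of
the task taxonomy (hierarchical-decomposition localized MKL). The classifier
is a standard soft-margin C-SVM trained on the precomputed combined kernel;
GOF maps to +1 (the positive class), LOF to -1.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .kernels import KernelMatrix, check_psd
from .taskgraph import HierWeights, TaskTree, hierarchical_kernel, subset_kernels

__all__ = [
    "KernelStack",
    "SVMModel",
    "EvalConfig",
    "combine_kernels",
    "learn_global_weights",
    "learn_hierarchical_weights",
    "train_svm",
    "decision_values",
    "POSITIVE_LABEL",
]

POSITIVE_LABEL = "GOF"  # mapped to +1; LOF is the negative class


@dataclass(frozen=True)
class KernelStack:
    """Named modality kernels over identical samples, with convex weights."""

    names: tuple[str, ...]
    kernels: tuple[KernelMatrix, ...]
    weights: tuple[float, ...] | None = None  # None = uniform

    def __post_init__(self):
        if len(self.names) != len(self.kernels) or not self.kernels:
            raise ValueError("kernel stack needs one name per kernel")
        ids = self.kernels[0].sample_ids
        for k in self.kernels[1:]:
            if k.sample_ids != ids:
                raise ValueError("modality kernels have mismatched sample ids")
        if self.weights is not None:
            w = np.asarray(self.weights)
            if len(w) != len(self.kernels) or (w < -1e-12).any():
                raise ValueError("weights must be nonnegative, one per modality")

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return self.kernels[0].sample_ids

    def effective_weights(self) -> np.ndarray:
        m = len(self.kernels)
        if self.weights is None:
            return np.full(m, 1.0 / m)
        w = np.asarray(self.weights, dtype=float)
        return w / w.sum() if w.sum() > 0 else np.full(m, 1.0 / m)

    def subset(self, idx: np.ndarray) -> "KernelStack":
        kerns = tuple(
            KernelMatrix(
                tuple(np.asarray(k.sample_ids, dtype=object)[idx]),
                k.values[np.ix_(idx, idx)],
                psd_status=k.psd_status,
            )
            for k in self.kernels
        )
        return KernelStack(self.names, kerns, self.weights)


def combine_kernels(stack: KernelStack, weights: Sequence[float] | None = None) -> KernelMatrix:
    """Convex combination Σ β_m K_m (uniform when no weights are given)."""
    w = np.asarray(weights, dtype=float) if weights is not None else stack.effective_weights()
    if len(w) != len(stack.kernels):
        raise ValueError("one weight per modality required")
    acc = np.zeros_like(stack.kernels[0].values)
    for wi, k in zip(w, stack.kernels):
        acc += wi * k.values
    return KernelMatrix(stack.sample_ids, acc, psd_status="verified")


@dataclass(frozen=True)
class EvalConfig:
    """Inner-evaluation settings for wrapper weight search."""

    inner_k: int = 3
    C: float = 1.0
    seed: int = 0
    grid_resolution: float = 0.1
    max_sweeps: int = 20
    min_block: int = 10  # hierarchical fallback: smaller blocks get uniform weights


def _inner_auroc(K: np.ndarray, y: np.ndarray, cfg: EvalConfig) -> float:
    """Mean validation AU-ROC of a C-SVM on the given precomputed kernel."""
    skf = StratifiedKFold(n_splits=cfg.inner_k, shuffle=True, random_state=cfg.seed)
    scores = []
    for tr, va in skf.split(np.zeros(len(y)), y):
        if len(np.unique(y[va])) < 2 or len(np.unique(y[tr])) < 2:
            continue
        clf = SVC(C=cfg.C, kernel="precomputed")
        clf.fit(K[np.ix_(tr, tr)], y[tr])
        f = clf.decision_function(K[np.ix_(va, tr)])
        scores.append(roc_auc_score(y[va], f))
    if not scores:
        raise ValueError("no valid inner folds (degenerate class distribution)")
    return float(np.mean(scores))


def _simplex_grid(m: int, res: float):
    steps = int(round(1.0 / res))
    for cut in itertools.combinations_with_replacement(range(steps + 1), m - 1):
        parts = (0,) + cut + (steps,)
        yield tuple((parts[i + 1] - parts[i]) / steps for i in range(m))


def _wrapper_search(kernel_values: Sequence[np.ndarray], y: np.ndarray,
                    cfg: EvalConfig) -> tuple[float, ...]:
    """Simplex search for kernel weights maximizing inner-CV AU-ROC.

    Exhaustive grid at ``grid_resolution`` for up to 3 kernels; deterministic
    coordinate ascent from uniform for more. Ties keep the earlier candidate
    (grid enumerated in a fixed order starting from the most uniform-adjacent
    corner ordering).
    """
    m = len(kernel_values)
    if m == 1:
        return (1.0,)

    def score(w) -> float:
        K = sum(wi * Kv for wi, Kv in zip(w, kernel_values))
        return _inner_auroc(K, y, cfg)

    if m <= 3:
        best_w, best_s = None, -np.inf
        for w in _simplex_grid(m, cfg.grid_resolution):
            s = score(w)
            if s > best_s + 1e-12:
                best_w, best_s = w, s
        return best_w
    # coordinate ascent on the simplex
    w = np.full(m, 1.0 / m)
    best_s = score(w)
    step = cfg.grid_resolution
    for _ in range(cfg.max_sweeps):
        improved = False
        for i in range(m):
            for delta in (step, -step):
                cand = w.copy()
                cand[i] = max(0.0, cand[i] + delta)
                tot = cand.sum()
                if tot <= 0:
                    continue
                cand /= tot
                s = score(cand)
                if s > best_s + 1e-12:
                    w, best_s, improved = cand, s, True
        if not improved:
            break
    return tuple(float(x) for x in w)


def learn_global_weights(stack: KernelStack, labels: Sequence[int],
                         eval_config: EvalConfig | None = None) -> tuple[float, ...]:
    """Learn global convex modality weights with a wrapper search."""
    cfg = eval_config or EvalConfig()
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("weight learning requires both classes")
    return _wrapper_search([k.values for k in stack.kernels], y, cfg)


def learn_hierarchical_weights(tree: TaskTree, stack: KernelStack,
                               task_of: Sequence[str], labels: Sequence[int],
                               eval_config: EvalConfig | None = None) -> HierWeights:
    """Localized MKL over the task taxonomy.

    For every tree node, modality weights are learned by the wrapper on that
    node's sample block; blocks smaller than ``min_block`` samples or with a
    single class fall back to uniform modality weights. Each node kernel is the
    per-node weighted modality sum masked to the node's task block; the outer
    β over node kernels is then learned with the same wrapper.
    """
    cfg = eval_config or EvalConfig()
    y = np.asarray(labels)
    task_of = list(task_of)
    m = len(stack.kernels)
    per_node: dict[str, tuple[float, ...]] = {}
    node_kernels: dict[str, KernelMatrix] = {}
    for node in tree.nodes:
        sub = tree.node_subsets[node]
        idx = np.array([t in sub for t in task_of])
        block = np.nonzero(idx)[0]
        if block.size == 0:
            raise ValueError(f"empty sample block for node {node!r}")
        yb = y[block]
        if block.size < cfg.min_block or len(np.unique(yb)) < 2 or m == 1:
            w = tuple(np.full(m, 1.0 / m))
        else:
            w = _wrapper_search(
                [k.values[np.ix_(block, block)] for k in stack.kernels], yb, cfg
            )
        per_node[node] = w
        combined = combine_kernels(stack, w)
        node_kernels[node] = subset_kernels(tree, combined, task_of)[node]
    nodes = list(tree.nodes)
    beta = _wrapper_search([node_kernels[n].values for n in nodes], y, cfg)
    return HierWeights(node_weights=dict(zip(nodes, beta)),
                       per_node_modality_weights=per_node)


def hierarchical_combined_kernel(tree: TaskTree, stack: KernelStack,
                                 task_of: Sequence[str], weights: HierWeights) -> KernelMatrix:
    """Assemble K̂ from learned hierarchical weights on a (possibly new) stack."""
    node_kernels = {
        node: subset_kernels(
            tree, combine_kernels(stack, weights.per_node_modality_weights[node]), task_of
        )[node]
        for node in tree.nodes
    }
    return hierarchical_kernel(node_kernels, weights)


@dataclass(frozen=True)
class SVMModel:
    """Trained kernel C-SVM: full-length signed dual coefficients α_i y_i,
    bias, and the kernel recipe used to build the Gram matrix."""

    sample_ids: tuple[str, ...]
    alpha_signed: np.ndarray  # length n_train; zero off the support
    bias: float
    cost: float
    labels: np.ndarray
    kernel_recipe: Mapping = field(default_factory=dict)

    @property
    def support_indices(self) -> np.ndarray:
        return np.nonzero(self.alpha_signed != 0)[0]

    @property
    def alphas(self) -> np.ndarray:
        """Nonnegative dual variables α_i = |α_i y_i|."""
        return np.abs(self.alpha_signed)


def train_svm(K: KernelMatrix, labels: Sequence[int], C: float,
              check: bool = True, kernel_recipe: Mapping | None = None) -> SVMModel:
    """Train a C-SVM on a precomputed PSD kernel.

    Refuses indefinite kernels (an indefinite Gram matrix makes the dual
    problem non-convex); apply :func:`phenomkl.kernels.nearest_psd` first.
    """
    if not C > 0:
        raise ValueError("cost C must be positive")
    y = np.asarray(labels, dtype=int)
    if set(np.unique(y)) - {-1, 1}:
        raise ValueError("labels must be +1 (GOF) / -1 (LOF)")
    if check:
        ok, lam_min = check_psd(K)
        if not ok:
            raise ValueError(
                f"kernel is indefinite (min eigenvalue {lam_min:.3g}); apply "
                "nearest_psd(..., method='clip'|'flip'|'shift') before training"
            )
    clf = SVC(C=C, kernel="precomputed")
    clf.fit(K.values, y)
    alpha_signed = np.zeros(K.n)
    alpha_signed[clf.support_] = clf.dual_coef_[0]
    return SVMModel(K.sample_ids, alpha_signed, float(clf.intercept_[0]), float(C),
                    y, kernel_recipe or {})


def decision_values(model: SVMModel, K_test_train: np.ndarray) -> np.ndarray:
    """f(x) = Σ_i α_i y_i K(x_i, x) + b for each row of the test-train Gram."""
    K_test_train = np.atleast_2d(np.asarray(K_test_train, dtype=float))
    if K_test_train.shape[1] != len(model.sample_ids):
        raise ValueError(
            f"expected {len(model.sample_ids)} training columns, "
            f"got {K_test_train.shape[1]}"
        )
    return K_test_train @ model.alpha_signed + model.bias
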