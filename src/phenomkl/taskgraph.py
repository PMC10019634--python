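"""Task taxonomy: tree over channels (tasks), task-similarity kernels,
hierarchical task-subset kernels, and latent task similarity.

Each channel is a task corresponding to a leaf of a rooted taxonomy tree G.
Every node n of G induces a task subset S_n = leaves(subtree at n); the
hierarchical-decomposition kernel is K̂ = Σ_n β_n · K_leaves(n), where
K_leaves(n) restricts a base kernel to sample pairs whose tasks both lie in
S_n. With all weight on the root this is the pooled (Union) kernel; with
uniform weight on the leaves only, the block-diagonal per-task (Dirac) kernel.

Prior task similarity between two leaves s, t is derived from shared ancestry:

    K_task(s, t) = (a + c(s, t)) / (a + c_max)

with c(s,t) the number of common ancestor nodes (reflexive, up to the root),
c_max the maximal reflexive self-ancestor count, and a > 0 a baseline
similarity that pulls all entries toward 1 as a → ∞ (the Union limit).

Latent task similarity refines the prior from learned subset weights:
γ_{k,l} = Σ β_n over nodes n whose subset contains both tasks.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .kernels import KernelMatrix

__all__ = [
    "TaskTree",
    "TaskSimilarityMatrix",
    "HierWeights",
    "parse_newick",
    "task_similarity",
    "multitask_kernel",
    "subset_kernels",
    "hierarchical_kernel",
    "latent_task_similarity",
]


@dataclass(frozen=True)
class TaskTree:
    """Rooted taxonomy; nodes in deterministic preorder, leaves are tasks."""

    nodes: tuple[str, ...]                      # preorder
    children: Mapping[str, tuple[str, ...]]
    leaves: tuple[str, ...]
    node_subsets: Mapping[str, frozenset[str]]  # node -> leaves(subtree)
    ancestors: Mapping[str, tuple[str, ...]]    # leaf -> reflexive node path to root

    @property
    def root(self) -> str:
        return self.nodes[0]

    def newick(self) -> str:
        def rec(node: str) -> str:
            kids = self.children[node]
            if not kids:
                return node
            return "(" + ",".join(rec(c) for c in kids) + ")" + node
        return rec(self.root) + ";"


def _from_dendropy(tree: dendropy.Tree) -> TaskTree:
    seen_leaves: set[str] = set()
    nodes: list[str] = []
    children: dict[str, tuple[str, ...]] = {}
    subsets: dict[str, frozenset[str]] = {}
    parent: dict[str, str] = {}
    counter = [0]

    def name_of(nd) -> str:
        if nd.is_leaf():
            if nd.taxon is None or not nd.taxon.label:
                raise ValueError("unnamed leaf in task tree")
            return str(nd.taxon.label)
        if nd.label:
            return str(nd.label)
        counter[0] += 1
        return f"node{counter[0]}"

    names: dict[int, str] = {}

    def walk(nd, parent_name: str | None) -> frozenset[str]:
        nm = name_of(nd)
        if nm in names.values() or nm in seen_leaves:
            raise ValueError(f"duplicate node/leaf name in task tree: {nm!r}")
        names[id(nd)] = nm
        nodes.append(nm)
        if parent_name is not None:
            parent[nm] = parent_name
        kids = list(nd.child_nodes())
        if not kids:
            seen_leaves.add(nm)
            children[nm] = ()
            subsets[nm] = frozenset({nm})
            return subsets[nm]
        sub: set[str] = set()
        kid_names = []
        for c in kids:
            sub |= walk(c, nm)
            kid_names.append(names[id(c)])
        children[nm] = tuple(kid_names)
        subsets[nm] = frozenset(sub)
        return subsets[nm]

    walk(tree.seed_node, None)
    leaves = tuple(n for n in nodes if not children[n])
    anc: dict[str, tuple[str, ...]] = {}
    for lf in leaves:
        path = [lf]
        while path[-1] in parent:
            path.append(parent[path[-1]])
        anc[lf] = tuple(path)
    return TaskTree(tuple(nodes), children, leaves, subsets, anc)


def parse_newick(source) -> TaskTree:
    """Parse a Newick taxonomy from a path or a literal Newick string."""
    text = None
    s = str(source)
    if s.strip().startswith("(") or s.strip().endswith(";"):
        text = s
    if text is None:
        with open(s) as fh:
            text = fh.read()
    try:
        tree = dendropy.Tree.get(
            file=_io.StringIO(text), schema="newick",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"invalid Newick taxonomy: {exc}") from exc
    tt = _from_dendropy(tree)
    if len(set(tt.leaves)) != len(tt.leaves):
        raise ValueError("duplicate leaf names in task tree")
    return tt


@dataclass(frozen=True)
class TaskSimilarityMatrix:
    """Symmetric task-by-task similarity with entries in (0, 1]."""

    tasks: tuple[str, ...]
    values: np.ndarray
    baseline: float | None = None

    def index(self, task: str) -> int:
        return self.tasks.index(task)

    def expand(self, task_of: Sequence[str], sample_ids: Sequence[str]) -> KernelMatrix:
        """Expand to a sample-level kernel: entry (i,j) = K_task(task_i, task_j)."""
        idx = {t: i for i, t in enumerate(self.tasks)}
        try:
            rows = np.array([idx[t] for t in task_of])
        except KeyError as exc:
            raise ValueError(f"unknown task {exc.args[0]!r}") from None
        v = self.values[np.ix_(rows, rows)]
        return KernelMatrix(tuple(sample_ids), v, psd_status="verified")


@dataclass(frozen=True)
class HierWeights:
    """Hierarchical-decomposition weights: simplex β over tree nodes, plus a
    convex modality-weight vector per node."""

    node_weights: Mapping[str, float]
    per_node_modality_weights: Mapping[str, tuple[float, ...]]

    def __post_init__(self):
        b = np.array(list(self.node_weights.values()))
        if (b < -1e-12).any() or abs(b.sum() - 1.0) > 1e-9:
            raise ValueError("node weights must lie on the simplex")


def task_similarity(tree: TaskTree, a: float) -> TaskSimilarityMatrix:
    """Shared-ancestor-count task similarity (a + c(s,t)) / (a + c_max)."""
    if not a > 0:
        raise ValueError("baseline similarity a must be positive")
    leaves = tree.leaves
    anc = {lf: set(tree.ancestors[lf]) for lf in leaves}
    c_max = max(len(v) for v in anc.values())
    n = len(leaves)
    vals = np.empty((n, n))
    for i, s in enumerate(leaves):
        for j, t in enumerate(leaves):
            c = len(anc[s] & anc[t])
            vals[i, j] = (a + c) / (a + c_max)
    return TaskSimilarityMatrix(leaves, vals, baseline=float(a))


def multitask_kernel(K_base: KernelMatrix, task_of: Sequence[str],
                     K_task: TaskSimilarityMatrix) -> KernelMatrix:
    """Schur product of a base kernel with the expanded task kernel; PSD when
    both factors are."""
    if len(task_of) != K_base.n:
        raise ValueError("task assignment length does not match kernel order")
    Kt = K_task.expand(task_of, K_base.sample_ids)
    status = K_base.psd_status if K_base.psd_status != "verified" else "verified"
    return KernelMatrix(K_base.sample_ids, K_base.values * Kt.values, psd_status=status)


def subset_kernels(tree: TaskTree, K_modality: KernelMatrix,
                   task_of: Sequence[str]) -> dict[str, KernelMatrix]:
    """One masked kernel per tree node: zero outside the node's task block."""
    task_of = list(task_of)
    unknown = sorted(set(task_of) - set(tree.leaves))
    if unknown:
        raise ValueError(f"unknown tasks: {unknown}")
    out: dict[str, KernelMatrix] = {}
    for node in tree.nodes:
        member = np.array([t in tree.node_subsets[node] for t in task_of])
        mask = np.outer(member, member)
        out[node] = KernelMatrix(K_modality.sample_ids,
                                 np.where(mask, K_modality.values, 0.0),
                                 psd_status=K_modality.psd_status)
    return out


def hierarchical_kernel(kernels: Mapping[str, KernelMatrix],
                        weights: HierWeights) -> KernelMatrix:
    """Weighted node-kernel sum K̂ = Σ_n β_n K_leaves(n)."""
    if set(kernels) != set(weights.node_weights):
        raise ValueError("node-kernel / node-weight mismatch")
    nodes = list(kernels)
    first = kernels[nodes[0]]
    acc = np.zeros_like(first.values)
    for n in nodes:
        acc += weights.node_weights[n] * kernels[n].values
    return KernelMatrix(first.sample_ids, acc, psd_status="verified")


def latent_task_similarity(tree: TaskTree, weights: HierWeights) -> TaskSimilarityMatrix:
    """γ_{k,l} = Σ β_n over nodes whose leaf subset contains both tasks."""
    leaves = tree.leaves
    n = len(leaves)
    vals = np.zeros((n, n))
    for node, beta in weights.node_weights.items():
        sub = tree.node_subsets[node]
        member = np.array([lf in sub for lf in leaves])
        vals += beta * np.outer(member, member)
    return TaskSimilarityMatrix(leaves, vals)
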