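"""Synthetic cohort generation.

Every pipeline stage can be exercised without external downloads: this module
generates a random single-root multi-parent DAG ontology, a channel taxonomy,
per-variant term sets whose composition can depend on the class label and on
the task, class-shifted Gaussian feature vectors with task-level intercepts,
and GOF/LOF labels.

Signal knobs
------------
``phenotype_effect``
    Probability that an annotated term is drawn from a class-specific preferred
    term pool rather than uniformly — the synthetic analogue of a
    genotype-phenotype correlation. May be a single float or a per-task map,
    which plants phenotype signal only in chosen branches of the taxonomy.
``task_effect``
    Probability (among non-class draws) that a term comes from a task-specific
    pool, creating task-correlated but label-uninformative phenotype structure.
``feature_effect``
    Between-class mean shift, in SD units, applied to a small block of feature
    dimensions.

Defaults mirror the real-cohort annotation statistics the framework targets:
a mean of 9 raw terms per variant within a 3–42 range, 62 feature dimensions,
and 9 tasks in a two-level taxonomy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .dataset import Dataset
from .kernels import FeatureTable
from .ontology import OntologyGraph, TermSet
from .taskgraph import TaskTree, parse_newick

__all__ = ["SyntheticConfig", "SyntheticCohort", "generate_ontology", "generate_cohort"]

DEFAULT_TREE_9 = "(((CH1,CH2,CH3),(CH4,CH5)),((CH6,CH7),(CH8,CH9)));"


@dataclass(frozen=True)
class SyntheticConfig:
    n_terms: int = 250
    max_parents: int = 3
    n_tasks: int = 9
    tree_topology: str = "default"  # "default", "random", or a Newick string
    n_variants: int = 300
    class_balance: float = 0.45  # P(GOF); the framework's target cohorts skew LOF
    feature_dim: int = 62
    feature_effect: float = 0.0
    phenotype_effect: float | Mapping[str, float] = 0.0
    task_effect: float = 0.3
    terms_per_variant_mean: float = 9.0
    terms_per_variant_range: tuple[int, int] = (3, 42)
    seed: int = 0

    def __post_init__(self):
        if self.n_terms < 2 or self.max_parents < 1 or self.n_variants < 1:
            raise ValueError("counts must be positive (n_terms >= 2)")
        if not 0 < self.class_balance < 1:
            raise ValueError("class_balance must be in (0, 1)")
        lo, hi = self.terms_per_variant_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid terms-per-variant range")
        if hi > self.n_terms - 1:
            raise ValueError(
                f"terms-per-variant range {self.terms_per_variant_range} infeasible "
                f"for an ontology with {self.n_terms} terms (root is never annotated)"
            )


@dataclass(frozen=True)
class SyntheticCohort:
    """A generated cohort plus the ground-truth parameters that produced it."""

    dataset: Dataset
    config: SyntheticConfig
    ground_truth: dict = field(default_factory=dict)


def generate_ontology(n_terms: int, max_parents: int, seed: int) -> OntologyGraph:
    """Random single-root DAG: term i picks 1..max_parents parents among
    earlier terms, so acyclicity holds by construction."""
    if n_terms < 2 or max_parents < 1:
        raise ValueError("need n_terms >= 2 and max_parents >= 1")
    rng = np.random.default_rng(seed)
    ids = [f"T{i:04d}" for i in range(n_terms)]
    parents: dict[str, frozenset[str]] = {ids[0]: frozenset()}
    for i in range(1, n_terms):
        k = int(rng.integers(1, min(max_parents, i) + 1))
        choice = rng.choice(i, size=k, replace=False)
        parents[ids[i]] = frozenset(ids[j] for j in choice)
    return OntologyGraph(parents=parents, root=ids[0])


def _random_tree(n_tasks: int, rng: np.random.Generator) -> str:
    nodes = [f"CH{i + 1}" for i in range(n_tasks)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = f"({nodes[i]},{nodes[j]})"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return nodes[0] + ";"


def _resolve_tree(cfg: SyntheticConfig, rng: np.random.Generator) -> TaskTree:
    if cfg.tree_topology == "default":
        if cfg.n_tasks == 9:
            return parse_newick(DEFAULT_TREE_9)
        if cfg.n_tasks == 1:
            return parse_newick("(CH1);")
        return parse_newick(
            "(" + ",".join(f"CH{i + 1}" for i in range(cfg.n_tasks)) + ");"
        )
    if cfg.tree_topology == "random":
        return parse_newick(_random_tree(cfg.n_tasks, rng))
    tree = parse_newick(cfg.tree_topology)
    if len(tree.leaves) != cfg.n_tasks:
        raise ValueError(
            f"tree has {len(tree.leaves)} leaves but n_tasks = {cfg.n_tasks}"
        )
    return tree


def _set_sizes(cfg: SyntheticConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """Right-skewed raw term-set sizes (log-normal, clipped to the range)."""
    lo, hi = cfg.terms_per_variant_range
    mu = math.log(cfg.terms_per_variant_mean)
    sizes = np.rint(rng.lognormal(mean=mu, sigma=0.5, size=n)).astype(int)
    return np.clip(sizes, lo, hi)


def generate_cohort(cfg: SyntheticConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort per the configured signal structure."""
    rng = np.random.default_rng(cfg.seed)
    graph = generate_ontology(cfg.n_terms, cfg.max_parents, int(rng.integers(2**31)))
    tree = _resolve_tree(cfg, rng)
    tasks_pool = list(tree.leaves)
    n, d = cfg.n_variants, cfg.feature_dim

    ids = tuple(f"V{i:04d}" for i in range(n))
    tasks = tuple(tasks_pool[int(i)] for i in rng.integers(0, len(tasks_pool), size=n))
    y = np.where(rng.random(n) < cfg.class_balance, 1, -1)

    # features: standard normal + per-task intercept + class shift on a block
    X = rng.standard_normal((n, d))
    task_intercepts = {t: rng.normal(0.0, 0.3, size=d) for t in tasks_pool}
    n_signal = max(1, d // 6)
    for i in range(n):
        X[i] += task_intercepts[tasks[i]]
        X[i, :n_signal] += y[i] * cfg.feature_effect / 2.0
    features = FeatureTable(ids, tuple(f"feat{j + 1}" for j in range(d)), X)

    # term pools: disjoint class pools; per-task pools outside the class pools
    non_root = sorted(t for t in graph.terms if t != graph.root)
    pool_size = max(3, cfg.n_terms // 8)
    task_pool_size = max(3, cfg.n_terms // 12)
    shuffled = list(rng.permutation(non_root))
    gof_pool = sorted(shuffled[:pool_size])
    lof_pool = sorted(shuffled[pool_size: 2 * pool_size])
    rest = sorted(shuffled[2 * pool_size:])
    task_pools = {
        t: sorted(rng.choice(rest, size=min(task_pool_size, len(rest)), replace=False))
        for t in tasks_pool
    }

    def pheno_eff(task: str) -> float:
        if isinstance(cfg.phenotype_effect, Mapping):
            return float(cfg.phenotype_effect.get(task, 0.0))
        return float(cfg.phenotype_effect)

    term_index = {t: i for i, t in enumerate(non_root)}
    sizes = _set_sizes(cfg, n, rng)
    term_sets = []
    for i in range(n):
        pc = pheno_eff(tasks[i])
        pt = (1.0 - pc) * cfg.task_effect
        pu = max(0.0, 1.0 - pc - pt)
        p = np.zeros(len(non_root))
        cls_pool = gof_pool if y[i] == 1 else lof_pool
        p[[term_index[t] for t in cls_pool]] += pc / len(cls_pool)
        tp = task_pools[tasks[i]]
        p[[term_index[t] for t in tp]] += pt / len(tp)
        p += pu / len(non_root)
        p /= p.sum()
        support = int((p > 0).sum())
        size = min(int(sizes[i]), support)
        raw = rng.choice(non_root, size=size, replace=False, p=p)
        term_sets.append(TermSet.from_raw(ids[i], raw, graph))

    dataset = Dataset(ids, features, tuple(term_sets), tasks, y, graph, tree)
    truth = {
        "gof_pool": gof_pool,
        "lof_pool": lof_pool,
        "task_pools": task_pools,
        "signal_features": list(features.feature_names[:n_signal]),
        "feature_effect": cfg.feature_effect,
        "phenotype_effect": cfg.phenotype_effect,
        "task_effect": cfg.task_effect,
    }
    return SyntheticCohort(dataset=dataset, config=cfg, ground_truth=truth)
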