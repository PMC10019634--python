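"""Nested cross-validation over the hyperparameter grid, the model
configurations (Dirac, Union, MTL, MKL variants), and the metric panel.

Model configurations
--------------------
``dirac``
    One SVM per task (channel) — no sharing across tasks.
``union``
    One pooled SVM on the sequence/structure RBF kernel — full sharing.
``mtl``
    Multi-task kernel: RBF kernel Schur-multiplied with the taxonomy-derived
    task similarity.
``mkl_uniform`` / ``mkl_global`` / ``mkl_hierarchical``
    Three modality kernels — task similarity, sequence/structure RBF, and
    phenotype semantic similarity — combined with uniform weights, with
    globally learned weights (wrapper search), or with the localized
    hierarchical decomposition over the task taxonomy.

Hyperparameters (cost C, RBF bandwidth σ, task-similarity baseline a, the
semantic similarity measure, and the PSD correction) are selected by inner
k-fold CV on mean AU-ROC inside every outer training fold; outer folds are
stratified by label and provide the generalization estimate (mean ± SD over
folds). Ties in the grid search are broken toward smaller C, then larger σ.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .dataset import Dataset
from .kernels import (KernelMatrix, check_psd, median_sigma, nearest_psd,
                      normalize_kernel, rbf_kernel)
from .mkl_model import (EvalConfig, KernelStack, SVMModel, combine_kernels,
                        decision_values, hierarchical_combined_kernel,
                        learn_global_weights, learn_hierarchical_weights,
                        train_svm)
from .ontology import information_content, similarity_matrix
from .taskgraph import multitask_kernel, task_similarity

__all__ = [
    "HyperGrid",
    "Metrics",
    "CVReport",
    "KernelBank",
    "MODES",
    "compute_metrics",
    "nested_cv",
    "run_benchmark",
    "summarize_reports",
]

MODES = ("dirac", "union", "mtl", "mkl_uniform", "mkl_global", "mkl_hierarchical")
MODALITY_NAMES = ("task", "structure", "phenotype")


@dataclass(frozen=True)
class HyperGrid:
    """Grid-search space; defaults are the framework's canonical grid."""

    C: tuple[float, ...] = (1e-4, 1e-2, 1.0, 1e2, 1e4)
    sigma: tuple = (1e-5, 1e-4, 1e-3, 1e-2, 1e-1, 1.0)  # floats or "median"
    a: tuple[float, ...] = (1, 3, 5, 10, 100)
    measure: tuple[str, ...] = ("jaccard", "resnik", "lin")
    correction: tuple[str, ...] = ("clip", "flip", "shift")


@dataclass(frozen=True)
class Metrics:
    acc: float
    sensitivity: float
    specificity: float
    f1: float
    kappa: float
    mcc: float
    au_prc: float
    au_roc: float

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in
                ("acc", "sensitivity", "specificity", "f1", "kappa", "mcc",
                 "au_prc", "au_roc")}


def compute_metrics(y_true: Sequence[int], y_pred: Sequence[int],
                    scores: Sequence[float]) -> Metrics:
    """Full metric panel from true/predicted labels and ranking scores.

    GOF (+1) is the positive class. Degenerate 0/0 ratios are reported as 0;
    a single-class ``y_true`` is an error because the AUCs are undefined.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if not (len(y_true) == len(y_pred) == len(scores)):
        raise ValueError("metric inputs must have equal length")
    if len(np.unique(y_true)) < 2:
        raise ValueError("AU-ROC/AU-PRC undefined for single-class y_true; "
                         "folds must be stratified")
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    tn = int(((y_true == -1) & (y_pred == -1)).sum())
    fp = int(((y_true == -1) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == -1)).sum())
    n = tp + tn + fp + fn

    def safe(num: float, den: float) -> float:
        return num / den if den > 0 else 0.0

    acc = (tp + tn) / n
    sens = safe(tp, tp + fn)
    spec = safe(tn, tn + fp)
    prec = safe(tp, tp + fp)
    f1 = safe(2 * prec * sens, prec + sens)
    mcc_den = float(np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)))
    mcc = safe(tp * tn - fp * fn, mcc_den)
    pe = ((tp + fp) * (tp + fn) + (tn + fn) * (tn + fp)) / (n * n)
    kappa = safe(acc - pe, 1 - pe)
    au_roc = float(roc_auc_score(y_true, scores))
    au_prc = float(average_precision_score(y_true, scores, pos_label=1))
    return Metrics(acc, sens, spec, f1, kappa, mcc, au_prc, au_roc)


@dataclass
class CVReport:
    """Per-outer-fold metrics, chosen hyperparameters, and aggregates."""

    mode: str
    seed: int
    fold_metrics: list[Metrics] = field(default_factory=list)
    chosen_params: list[dict] = field(default_factory=list)
    k: int = 5

    def aggregate(self) -> dict[str, tuple[float, float]]:
        out = {}
        for key in Metrics.__dataclass_fields__:
            vals = np.array([getattr(m, key) for m in self.fold_metrics])
            out[key] = (float(vals.mean()), float(vals.std(ddof=1)) if len(vals) > 1 else 0.0)
        return out

    def mean(self, metric: str) -> float:
        return self.aggregate()[metric][0]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, (m, p) in enumerate(zip(self.fold_metrics, self.chosen_params)):
            row = {"mode": self.mode, "seed": self.seed, "fold": i, **m.as_dict()}
            row.update({f"param_{k}": v for k, v in p.items()})
            rows.append(row)
        return pd.DataFrame(rows)


class KernelBank:
    """Precomputed, normalized modality kernels over the full cohort.

    Phenotype similarity (and the IC corpus behind Resnik/Lin, and the
    spectrum-global PSD correction) is computed once over all annotation sets;
    fold blocks are sliced from the full matrices.
    """

    def __init__(self, dataset: Dataset, grid: HyperGrid,
                 aggregate: str = "bma"):
        self.dataset = dataset
        self.grid = grid
        ds = dataset
        self._sigma_cache: dict = {}
        self._pheno: dict[tuple[str, str], KernelMatrix] = {}
        self._rbf: dict[float, KernelMatrix] = {}
        self._task_sim: dict[float, object] = {}
        self._task_sample: dict[float, KernelMatrix] = {}
        self._mode_kernels: dict = {}

        ic = information_content(ds.ontology, ds.term_sets)
        for measure in grid.measure:
            sim = similarity_matrix(measure, list(ds.term_sets), ds.ontology, ic,
                                    aggregate=aggregate)
            ok, _ = check_psd(sim)
            for corr in grid.correction:
                if ok:
                    km = KernelMatrix(sim.sample_ids, sim.values, "verified")
                else:
                    km = nearest_psd(sim, corr)
                self._pheno[(measure, corr)] = normalize_kernel(km)
        for s in grid.sigma:
            sv = self.resolve_sigma(s)
            self._rbf[sv] = rbf_kernel(ds.features, sv)
        for a in grid.a:
            ts = task_similarity(ds.tree, a)
            self._task_sim[a] = ts
            self._task_sample[a] = normalize_kernel(ts.expand(ds.tasks, ds.ids))

    def resolve_sigma(self, sigma) -> float:
        if sigma == "median":
            if "median" not in self._sigma_cache:
                self._sigma_cache["median"] = median_sigma(self.dataset.features)
            return self._sigma_cache["median"]
        return float(sigma)

    def phenotype(self, measure: str, correction: str) -> KernelMatrix:
        return self._pheno[(measure, correction)]

    def rbf(self, sigma) -> KernelMatrix:
        return self._rbf[self.resolve_sigma(sigma)]

    def task_sim(self, a: float):
        return self._task_sim[a]

    def task_sample(self, a: float) -> KernelMatrix:
        return self._task_sample[a]

    def stack(self, params: Mapping) -> KernelStack:
        return KernelStack(
            MODALITY_NAMES,
            (self.task_sample(params["a"]), self.rbf(params["sigma"]),
             self.phenotype(params["measure"], params["correction"])),
        )

    def mode_kernel(self, mode: str, params: Mapping) -> KernelMatrix:
        """Full-cohort kernel for a mode/parameter combination (cached)."""
        key = (mode, tuple(sorted((k, v) for k, v in params.items() if k != "C")))
        if key in self._mode_kernels:
            return self._mode_kernels[key]
        ds = self.dataset
        if mode in ("dirac", "union"):
            km = self.rbf(params["sigma"])
        elif mode == "mtl":
            km = multitask_kernel(self.rbf(params["sigma"]), ds.tasks,
                                  self.task_sim(params["a"]))
        elif mode in ("mkl_uniform", "mkl_global", "mkl_hierarchical"):
            km = combine_kernels(self.stack(params))
        else:
            raise ValueError(f"unknown mode {mode!r}")
        self._mode_kernels[key] = km
        return km


def _mode_configs(mode: str, grid: HyperGrid) -> list[dict]:
    dims: dict[str, tuple] = {"C": grid.C, "sigma": grid.sigma}
    if mode in ("mtl", "mkl_uniform", "mkl_global", "mkl_hierarchical"):
        dims["a"] = grid.a
    if mode.startswith("mkl"):
        dims["measure"] = grid.measure
        dims["correction"] = grid.correction
    keys = list(dims)
    configs = [dict(zip(keys, combo)) for combo in itertools.product(*dims.values())]
    # tie-break ordering: smaller C first, then larger sigma (smoother model)
    configs.sort(key=lambda c: (c["C"], -(1e30 if c["sigma"] == "median" else c["sigma"])))
    return configs


def _dirac_scores(Kv: np.ndarray, y: np.ndarray, tasks: Sequence[str],
                  tr: np.ndarray, te: np.ndarray, C: float) -> np.ndarray:
    """Per-task SVM scores for test samples; tasks untrainable in the fold
    (missing or single-class) score with the training-block class prior."""
    scores = np.zeros(len(te))
    tasks = np.asarray(tasks, dtype=object)
    for task in np.unique(tasks[te]):
        te_mask = tasks[te] == task
        tr_task = tr[tasks[tr] == task]
        if len(tr_task) >= 2 and len(np.unique(y[tr_task])) == 2:
            model = train_svm(
                KernelMatrix(tuple(map(str, tr_task)), Kv[np.ix_(tr_task, tr_task)]),
                y[tr_task], C, check=False)
            f = decision_values(model, Kv[np.ix_(te[te_mask], tr_task)])
        else:
            prior = float(y[tr_task].mean()) if len(tr_task) else float(y[tr].mean())
            f = np.full(int(te_mask.sum()), prior)
        scores[te_mask] = f
    return scores


def _fit_predict(mode: str, bank: KernelBank, params: Mapping, y: np.ndarray,
                 tr: np.ndarray, te: np.ndarray,
                 weight_cfg: EvalConfig | None = None) -> np.ndarray:
    """Train under a mode/params on ``tr`` and return decision values on ``te``."""
    ds = bank.dataset
    C = params["C"]
    if mode == "dirac":
        Kv = bank.mode_kernel(mode, params).values
        return _dirac_scores(Kv, y, ds.tasks, tr, te, C)
    if mode == "mkl_global":
        cfg = weight_cfg or EvalConfig(C=C)
        sub = bank.stack(params).subset(tr)
        w = learn_global_weights(sub, y[tr], cfg)
        Kv = combine_kernels(bank.stack(params), w).values
    elif mode == "mkl_hierarchical":
        cfg = weight_cfg or EvalConfig(C=C)
        sub = bank.stack(params).subset(tr)
        hw = learn_hierarchical_weights(ds.tree, sub,
                                        list(np.asarray(ds.tasks, dtype=object)[tr]),
                                        y[tr], cfg)
        Kv = hierarchical_combined_kernel(ds.tree, bank.stack(params),
                                          ds.tasks, hw).values
    else:
        Kv = bank.mode_kernel(mode, params).values
    model = train_svm(KernelMatrix(tuple(map(str, tr)), Kv[np.ix_(tr, tr)]),
                      y[tr], C, check=False)
    return decision_values(model, Kv[np.ix_(te, tr)])


def _select_config(mode: str, bank: KernelBank, y: np.ndarray, tr: np.ndarray,
                   configs: list[dict], inner_k: int, seed: int) -> dict:
    """Inner-CV grid search on the outer-training indices only (no access to
    the outer test fold); criterion = mean inner AU-ROC."""
    if len(configs) == 1:
        return configs[0]
    inner = StratifiedKFold(n_splits=inner_k, shuffle=True, random_state=seed)
    # weight learning inside the inner grid search is combinatorial; uniform
    # weights stand in during selection for the learned-weight modes
    sel_mode = "mkl_uniform" if mode.startswith("mkl") else mode
    best, best_score = configs[0], -np.inf
    for cfg in configs:
        fold_scores = []
        for itr_rel, iva_rel in inner.split(np.zeros(len(tr)), y[tr]):
            itr, iva = tr[itr_rel], tr[iva_rel]
            if len(np.unique(y[iva])) < 2 or len(np.unique(y[itr])) < 2:
                continue
            f = _fit_predict(sel_mode, bank, cfg, y, itr, iva)
            fold_scores.append(roc_auc_score(y[iva], f))
        score = float(np.mean(fold_scores)) if fold_scores else -np.inf
        if score > best_score + 1e-12:
            best, best_score = cfg, score
    return best


def nested_cv(dataset: Dataset, mode: str, grid: HyperGrid | None = None,
              k: int = 5, seed: int = 0, inner_k: int | None = None,
              bank: KernelBank | None = None,
              weight_cfg: EvalConfig | None = None,
              outer_folds: Sequence[tuple[np.ndarray, np.ndarray]] | None = None,
              ) -> CVReport:
    """Nested stratified k-fold cross-validation for one model configuration.

    Outer folds estimate generalization; inner folds (default also k) select
    hyperparameters by mean AU-ROC. Deterministic given ``seed``.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if k < 2:
        raise ValueError("k must be >= 2")
    grid = grid or HyperGrid()
    y = dataset.y
    if len(np.unique(y)) < 2:
        raise ValueError("nested CV requires both classes")
    bank = bank or KernelBank(dataset, grid)
    configs = _mode_configs(mode, grid)
    inner_k = inner_k or k
    if outer_folds is None:
        outer = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        outer_folds = list(outer.split(np.zeros(dataset.n), y))
    report = CVReport(mode=mode, seed=seed, k=k)
    for fold_i, (tr, te) in enumerate(outer_folds):
        tr, te = np.asarray(tr), np.asarray(te)
        if len(np.unique(y[te])) < 2:
            raise ValueError(f"outer fold {fold_i} has a single class; "
                             "stratification failed")
        chosen = _select_config(mode, bank, y, tr, configs, inner_k, seed)
        wc = weight_cfg or EvalConfig(C=chosen["C"], seed=seed)
        f = _fit_predict(mode, bank, chosen, y, tr, te, weight_cfg=wc)
        y_pred = np.where(f >= 0, 1, -1)
        report.fold_metrics.append(compute_metrics(y[te], y_pred, f))
        report.chosen_params.append(dict(chosen))
    return report


def run_benchmark(dataset: Dataset, modes: Sequence[str],
                  grid: HyperGrid | None = None, seeds: Sequence[int] = (0,),
                  k: int = 5, inner_k: int | None = None) -> tuple[pd.DataFrame, list[CVReport]]:
    """Nested CV for each mode and seed; returns a summary table plus reports."""
    if not modes:
        raise ValueError("at least one mode required")
    grid = grid or HyperGrid()
    bank = KernelBank(dataset, grid)
    reports = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for mode in modes:
            for seed in seeds:
                reports.append(nested_cv(dataset, mode, grid, k=k, seed=seed,
                                         inner_k=inner_k, bank=bank))
    return summarize_reports(reports), reports


def summarize_reports(reports: Sequence[CVReport]) -> pd.DataFrame:
    """One row per (mode, seed) with mean and SD of every metric."""
    rows = []
    for r in reports:
        agg = r.aggregate()
        row: dict = {"mode": r.mode, "seed": r.seed}
        for metric, (m, s) in agg.items():
            row[f"{metric}_mean"] = m
            row[f"{metric}_sd"] = s
        rows.append(row)
    return pd.DataFrame(rows)
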