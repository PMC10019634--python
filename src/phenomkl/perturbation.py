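"""Simulated phenotypic sparsity and noise.

Raw term sets are perturbed *before* similarity computation, expressed as a
term ratio r:

* r < 1 (sparsity): keep round(r·|raw|) terms chosen at random (never fewer
  than one) — e.g. ratio 0.25 removes 3 out of 4 terms from a set;
* r = 1: unchanged;
* r > 1 (noise): add (r−1)·|raw| terms sampled without replacement from the
  ontology's terms outside the set — e.g. ratio 4 adds 3 random terms for
  each original term.

Ancestor propagation is re-applied after perturbation. Rounding is
half-up with a floor of one kept term.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace as _dc_replace
from typing import Sequence

import pandas as pd
import numpy as np

from .dataset import Dataset
from .ontology import OntologyGraph, TermSet, propagate

__all__ = ["PerturbationConfig", "perturb_termsets", "perturb_dataset",
           "robustness_sweep"]


@dataclass(frozen=True)
class PerturbationConfig:
    ratio: float
    seed: int
    universe: frozenset[str]

    def __post_init__(self):
        if not self.ratio > 0:
            raise ValueError("ratio must be positive")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def perturb_termsets(corpus: Sequence[TermSet], cfg: PerturbationConfig,
                     graph: OntologyGraph) -> list[TermSet]:
    """Apply the term-ratio perturbation to every raw set and re-propagate."""
    rng = np.random.default_rng(cfg.seed)
    r = cfg.ratio
    out = []
    for ts in corpus:
        raw = sorted(ts.raw_terms)
        if not raw:
            raise ValueError(f"{ts.variant_id}: empty raw term set")
        if r == 1:
            out.append(ts)
            continue
        if r < 1:
            keep = max(1, _round_half_up(r * len(raw)))
            kept = rng.choice(raw, size=keep, replace=False)
            new_raw = frozenset(kept)
        else:
            n_add = _round_half_up((r - 1) * len(raw))
            candidates = sorted(cfg.universe - set(raw) - {graph.root})
            if len(candidates) < n_add:
                raise ValueError(
                    f"{ts.variant_id}: universe exhausted — need {n_add} novel "
                    f"terms, only {len(candidates)} available"
                )
            added = rng.choice(candidates, size=n_add, replace=False)
            new_raw = frozenset(raw) | frozenset(added)
        out.append(TermSet(ts.variant_id, new_raw, propagate(graph, new_raw)))
    return out


def perturb_dataset(dataset: Dataset, ratio: float, seed: int) -> Dataset:
    """Dataset copy with perturbed (and re-propagated) term sets."""
    cfg = PerturbationConfig(ratio=ratio, seed=seed,
                             universe=frozenset(dataset.ontology.terms))
    return dataset.with_term_sets(
        perturb_termsets(dataset.term_sets, cfg, dataset.ontology)
    )


def robustness_sweep(dataset: Dataset, ratios: Sequence[float],
                     measures: Sequence[str], grid, seeds: Sequence[int],
                     modes: Sequence[str] = ("mkl_uniform",), k: int = 5,
                     inner_k: int | None = None) -> pd.DataFrame:
    """Sparsity/noise sweep: perturb, rebuild the phenotype kernel, re-run
    nested CV; one row per (mode, measure, ratio, seed) with ACC and AU-ROC."""
    from .evaluation import HyperGrid, KernelBank, nested_cv

    if not ratios:
        raise ValueError("at least one ratio required")
    grid = grid or HyperGrid()
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for measure in measures:
            mgrid = _dc_replace(grid, measure=(measure,))
            for ratio in ratios:
                for seed in seeds:
                    ds = perturb_dataset(dataset, ratio, seed)
                    bank = KernelBank(ds, mgrid)
                    for mode in modes:
                        rep = nested_cv(ds, mode, mgrid, k=k, seed=seed,
                                        inner_k=inner_k, bank=bank)
                        agg = rep.aggregate()
                        rows.append({
                            "mode": mode, "measure": measure, "ratio": ratio,
                            "seed": seed,
                            "acc_mean": agg["acc"][0], "acc_sd": agg["acc"][1],
                            "au_roc_mean": agg["au_roc"][0],
                            "au_roc_sd": agg["au_roc"][1],
                        })
    return pd.DataFrame(rows)
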