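"""Cohort container binding variants, features, phenotypes, tasks and labels."""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .kernels import FeatureTable
from .ontology import OntologyGraph, TermSet
from .taskgraph import TaskTree

__all__ = ["Dataset", "LABEL_TO_INT", "INT_TO_LABEL"]

LABEL_TO_INT = {"GOF": 1, "LOF": -1}
INT_TO_LABEL = {1: "GOF", -1: "LOF"}


@dataclass(frozen=True)
class Dataset:
    """A variant cohort: one task (channel), label, term set and feature
    vector per variant, plus the shared ontology and task taxonomy."""

    ids: tuple[str, ...]
    features: FeatureTable
    term_sets: tuple[TermSet, ...]
    tasks: tuple[str, ...]
    y: np.ndarray  # +1 = GOF, -1 = LOF
    ontology: OntologyGraph
    tree: TaskTree

    def __post_init__(self):
        n = len(self.ids)
        if not (len(self.term_sets) == len(self.tasks) == len(self.y) == n
                and self.features.values.shape[0] == n):
            raise ValueError("inconsistent cohort component lengths")
        if self.features.sample_ids != self.ids:
            raise ValueError("feature table ids do not match cohort ids")
        if set(np.unique(self.y)) - {-1, 1}:
            raise ValueError("labels must be +1 (GOF) / -1 (LOF)")
        unknown = sorted(set(self.tasks) - set(self.tree.leaves))
        if unknown:
            raise ValueError(f"tasks not present in the taxonomy: {unknown}")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def label_names(self) -> list[str]:
        return [INT_TO_LABEL[int(v)] for v in self.y]

    def with_term_sets(self, term_sets: Sequence[TermSet]) -> "Dataset":
        return replace(self, term_sets=tuple(term_sets))
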