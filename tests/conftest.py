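import numpy as np
import pytest

from phenomkl import (HyperGrid, OntologyGraph, SyntheticConfig, TermSet,
                      generate_cohort)

SMALL_GRID = HyperGrid(C=(1.0, 100.0), sigma=("median",), a=(1, 5),
                       measure=("jaccard",), correction=("clip",))


@pytest.fixture(scope="session")
def small_grid():
    return SMALL_GRID


@pytest.fixture()
def diamond():
    """R <- A, R <- C, A <- D, C <- D (two parents for D), plus leaf B under A."""
    return OntologyGraph(
        parents={
            "R": frozenset(),
            "A": frozenset({"R"}),
            "B": frozenset({"A"}),
            "C": frozenset({"R"}),
            "D": frozenset({"A", "C"}),
        },
        root="R",
    )


def make_corpus(graph, raw_sets):
    return [TermSet.from_raw(f"v{i}", raw, graph) for i, raw in enumerate(raw_sets)]


@pytest.fixture(scope="session")
def signal_cohort():
    """Moderate cohort with both phenotype and feature class signal."""
    return generate_cohort(SyntheticConfig(
        n_variants=120, n_terms=120, phenotype_effect=0.8, feature_effect=0.8,
        seed=11)).dataset


@pytest.fixture(scope="session")
def null_cohort():
    return generate_cohort(SyntheticConfig(
        n_variants=120, n_terms=120, seed=5)).dataset


def write_obo(tmp_path, text, name="mini.obo"):
    p = tmp_path / name
    p.write_text(text)
    return p
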