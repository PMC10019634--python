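"""File formats and dataset assembly.

On-disk cohort layout (all plain text):

* ``ontology.obo`` — OBO flat file (id, name, is_a; obsolete terms skipped);
* ``taxonomy.nwk`` — Newick task taxonomy, leaves = channels/tasks;
* ``annotations.tsv`` — columns ``variant_id``, ``terms`` (pipe-separated);
* ``features.csv`` — ``variant_id`` plus numeric feature columns;
* ``labels.csv`` — ``variant_id``, ``task``, ``label`` (GOF/LOF).

``load_dataset`` inner-joins the per-variant files on ``variant_id``; variants
missing any component are dropped with a logged count, term sets are
propagated, and structural problems (duplicate ids, unknown terms, zero
overlap) are hard errors.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import LABEL_TO_INT, Dataset
from .kernels import FeatureTable, KernelMatrix
from .ontology import OntologyGraph, TermSet, parse_obo
from .synthetic import SyntheticCohort
from .taskgraph import parse_newick

__all__ = ["RunConfig", "load_dataset", "load_dataset_dir", "write_cohort",
           "write_kernel", "read_kernel"]

log = logging.getLogger("phenomkl")

FILE_NAMES = {
    "ontology": "ontology.obo",
    "tree": "taxonomy.nwk",
    "annotations": "annotations.tsv",
    "features": "features.csv",
    "labels": "labels.csv",
}


@dataclass(frozen=True)
class RunConfig:
    ontology: Path
    annotations: Path
    features: Path
    tree: Path
    labels: Path

    def __post_init__(self):
        for name in ("ontology", "annotations", "features", "tree", "labels"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise FileNotFoundError(f"{name} file not found: {p}")

    @classmethod
    def from_dir(cls, directory) -> "RunConfig":
        d = Path(directory)
        return cls(**{k: d / v for k, v in FILE_NAMES.items()})


def _check_unique(ids: pd.Series, what: str) -> None:
    dup = ids[ids.duplicated()].tolist()
    if dup:
        raise ValueError(f"duplicate variant ids in {what}: {dup[:5]}")


def load_dataset(config: RunConfig) -> Dataset:
    """Assemble a :class:`Dataset` from the on-disk cohort files."""
    graph = parse_obo(config.ontology)
    tree = parse_newick(config.tree)

    ann = pd.read_csv(config.annotations, sep="\t", dtype=str)
    if not {"variant_id", "terms"} <= set(ann.columns):
        raise ValueError("annotations.tsv needs columns variant_id, terms")
    _check_unique(ann["variant_id"], "annotations")

    feats = pd.read_csv(config.features)
    if "variant_id" not in feats.columns:
        raise ValueError("features.csv needs a variant_id column")
    _check_unique(feats["variant_id"].astype(str), "features")
    feats = feats.set_index("variant_id")
    feats.index = feats.index.astype(str)

    lab = pd.read_csv(config.labels, dtype=str)
    if not {"variant_id", "task", "label"} <= set(lab.columns):
        raise ValueError("labels.csv needs columns variant_id, task, label")
    _check_unique(lab["variant_id"], "labels")
    bad = sorted(set(lab["label"]) - set(LABEL_TO_INT))
    if bad:
        raise ValueError(f"labels must be GOF/LOF, found: {bad}")

    ids_ann = set(ann["variant_id"])
    ids_feat = set(feats.index)
    ids_lab = set(lab["variant_id"])
    common = ids_ann & ids_feat & ids_lab
    if not common:
        raise ValueError("no variant ids shared across annotations, features, labels")
    dropped = (ids_ann | ids_feat | ids_lab) - common
    if dropped:
        log.info("dropping %d variants missing at least one component", len(dropped))

    lab = lab[lab["variant_id"].isin(common)].reset_index(drop=True)
    ids = tuple(lab["variant_id"])
    ann_map = dict(zip(ann["variant_id"], ann["terms"]))
    term_sets = []
    for vid in ids:
        raw = [t for t in str(ann_map[vid]).split("|") if t]
        term_sets.append(TermSet.from_raw(vid, raw, graph))
    feats = feats.loc[list(ids)]
    if feats.isna().any().any():
        raise ValueError("missing values in the feature table")
    features = FeatureTable.from_frame(feats)
    y = np.array([LABEL_TO_INT[v] for v in lab["label"]])
    return Dataset(ids, features, tuple(term_sets), tuple(lab["task"]), y,
                   graph, tree)


def load_dataset_dir(directory) -> Dataset:
    return load_dataset(RunConfig.from_dir(directory))


def write_ontology_obo(graph: OntologyGraph, path) -> None:
    lines = ["format-version: 1.2", ""]
    for term in sorted(graph.terms):
        lines += [f"[Term]", f"id: {term}", f"name: {term}"]
        for p in sorted(graph.parents[term]):
            lines.append(f"is_a: {p}")
        lines.append("")
    Path(path).write_text("\n".join(lines))


def write_cohort(cohort: SyntheticCohort | Dataset, directory) -> Path:
    """Serialize a cohort to the directory layout ``load_dataset`` reads."""
    ds = cohort.dataset if isinstance(cohort, SyntheticCohort) else cohort
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_ontology_obo(ds.ontology, d / FILE_NAMES["ontology"])
    (d / FILE_NAMES["tree"]).write_text(ds.tree.newick() + "\n")
    pd.DataFrame({
        "variant_id": list(ds.ids),
        "terms": ["|".join(sorted(ts.raw_terms)) for ts in ds.term_sets],
    }).to_csv(d / FILE_NAMES["annotations"], sep="\t", index=False)
    feats = ds.features.to_frame()
    feats.index.name = "variant_id"
    feats.to_csv(d / FILE_NAMES["features"])
    pd.DataFrame({
        "variant_id": list(ds.ids),
        "task": list(ds.tasks),
        "label": ds.label_names,
    }).to_csv(d / FILE_NAMES["labels"], index=False)
    if isinstance(cohort, SyntheticCohort):
        meta = {"config": {k: (list(v) if isinstance(v, tuple) else v)
                           for k, v in vars(cohort.config).items()
                           if not isinstance(v, dict)}}
        (d / "cohort_meta.json").write_text(json.dumps(meta, indent=2, default=str))
    return d


def write_kernel(K: KernelMatrix, path, metadata: dict | None = None) -> None:
    """Kernel round-trip as CSV with a sample-id header plus a JSON sidecar."""
    path = Path(path)
    df = pd.DataFrame(K.values, index=list(K.sample_ids), columns=list(K.sample_ids))
    df.to_csv(path)
    side = {"psd_status": K.psd_status}
    side.update(metadata or {})
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(side, indent=2))


def read_kernel(path) -> KernelMatrix:
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    side = path.with_suffix(path.suffix + ".json")
    status = "verified"
    if side.exists():
        status = json.loads(side.read_text()).get("psd_status", "verified")
    return KernelMatrix(tuple(map(str, df.index)), df.to_numpy(dtype=float),
                        psd_status=status)
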