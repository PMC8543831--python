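"""End-to-end orchestration: label -> features -> select -> train -> predict
-> cluster -> standard regions -> evaluate.

The in-memory core (:func:`run_stages`) is deterministic given its seed; the
file-based wrapper (:func:`run_pipeline`) reads the documented CSV/PDB inputs,
writes every stage artifact into an append-only run directory, and records
the configuration (with a content hash) alongside the outputs so a rerun with
identical config and inputs is bit-identical for the deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import clustering, evaluation, features, gnb, labeling, mrmr, standard_regions

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    mutations: Optional[str] = None
    raw_features: Optional[str] = None
    pdb_dir: Optional[str] = None
    out_dir: str = "hotregion_run"
    threshold: float = labeling.DEFAULT_THRESHOLD
    scheme: str = "single"
    expansion_ids: list[str] = field(default_factory=list)
    min_interface_size: int = 3
    bins: int = mrmr.DEFAULT_BINS
    cv_folds: int = 5
    seed: int = 17
    classifier: str = "gnb"
    min_grid: list[int] = field(default_factory=lambda: list(clustering.DEFAULT_MIN_GRID))
    eps_grid: list[float] = field(default_factory=lambda: [float(e) for e in clustering.DEFAULT_EPS_GRID])
    coverage: float = evaluation.DEFAULT_COVERAGE
    contact_tolerance: float = standard_regions.DEFAULT_CONTACT_TOLERANCE
    volume_table: Optional[dict[str, float]] = None
    skip_selection: bool = False

    def validate(self) -> None:
        if self.scheme not in ("single", "window"):
            raise StageError("config", f"unknown labeling scheme {self.scheme!r}")
        if not 0 < self.coverage <= 1:
            raise StageError("config", "coverage must be in (0, 1]")
        for path_attr in ("mutations", "raw_features", "pdb_dir"):
            p = getattr(self, path_attr)
            if p is not None and not Path(p).exists():
                raise StageError("config", f"{path_attr} path does not exist: {p}")

    def content_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunResult:
    residues: list[labeling.LabeledResidue]
    split: labeling.DatasetSplit
    table_train: features.FeatureTable
    table_test: features.FeatureTable
    selected_features: list[str]
    selection_table: Optional[pd.DataFrame]
    model: gnb.GNBModel
    predictions: np.ndarray  # over the test table rows
    residue_counts: evaluation.ConfusionCounts
    residue_metrics: evaluation.MetricSet
    grid: clustering.GridSearchResult
    predicted_regions: list[clustering.HotRegion]
    standard_regions: list[clustering.HotRegion]
    region_counts: evaluation.ConfusionCounts
    region_metrics: evaluation.MetricSet
    per_region: pd.DataFrame

    def metrics_dict(self) -> dict:
        return {
            "residue": self.residue_metrics.rounded(),
            "region": self.region_metrics.rounded(),
            "region_counts": dataclasses.asdict(self.region_counts),
            "best_params": {
                "min_pts": self.grid.best.min_pts,
                "eps": self.grid.best.eps,
            },
            "selected_features": self.selected_features,
        }


def default_classifier_factory(name: str) -> Callable[[], gnb.GaussianNaiveBayes]:
    if name != "gnb":
        raise StageError(
            "train",
            f"classifier {name!r} is not built in; pass a factory implementing "
            "the Classifier protocol (e.g. an SklearnAdapter)",
        )
    return gnb.GaussianNaiveBayes


def attach_coordinates(
    residues: Sequence[labeling.LabeledResidue],
    coords: Mapping[tuple[str, str, int], np.ndarray],
) -> list[labeling.LabeledResidue]:
    """Attach alpha-carbon coordinates by site; sites without one are dropped."""
    out = []
    missing = 0
    for r in residues:
        ca = coords.get(r.site)
        if ca is None:
            missing += 1
            continue
        out.append(r.with_coordinate(ca))
    if missing:
        logger.warning("%d labeled residues had no coordinate and were dropped", missing)
    return out


def run_stages(
    records: Sequence[labeling.MutationRecord],
    raw_features: pd.DataFrame,
    coords: Mapping[tuple[str, str, int], np.ndarray],
    config: RunConfig,
    classifier_factory: Optional[Callable[[], gnb.Classifier]] = None,
) -> RunResult:
    """Run the full pipeline in memory; see module docstring for the stages."""
    if classifier_factory is None:
        classifier_factory = default_classifier_factory(config.classifier)

    # -- label ------------------------------------------------------------
    ddg = labeling.aggregate_sites(records)
    residues = labeling.label_sites(ddg, config.threshold, config.scheme)
    if not residues:
        raise StageError("label", "no labeled residues produced")
    residues = attach_coordinates(residues, coords)

    # -- split ------------------------------------------------------------
    split = labeling.split_by_complex(
        residues, set(config.expansion_ids), config.min_interface_size
    )
    if not split.testing:  # no held-out complexes: evaluate on the training side
        split = labeling.DatasetSplit(training=split.training, testing=split.training)

    # -- features ---------------------------------------------------------
    def table_for(subset: Sequence[labeling.LabeledResidue]) -> features.FeatureTable:
        return features.assemble_feature_table(
            raw_features, labeling.residues_to_frame(subset)
        )

    table_train = table_for(split.training)
    table_test = table_for(split.testing)
    if table_train.n == 0 or table_test.n == 0:
        raise StageError("features", "empty feature table after assembly")

    # -- select -----------------------------------------------------------
    if config.skip_selection:
        selected = table_train.feature_names
        selection_table = None
    else:
        ranking = mrmr.mrmr_rank(table_train, config.bins)
        selected, selection_table = mrmr.incremental_select(
            ranking,
            table_train,
            classifier_factory,
            n_folds=config.cv_folds,
            seed=config.seed,
        )

    # -- train / predict ---------------------------------------------------
    clf = classifier_factory()
    clf.fit(table_train.subset_features(selected))
    predictions = clf.predict(table_test.subset_features(selected).x.to_numpy())
    model = getattr(clf, "model_", None)

    residue_counts, residue_metric_set = evaluation.residue_metrics(
        predictions, table_test.labels
    )

    # -- regions -----------------------------------------------------------
    by_site = {r.site: r for r in split.testing}
    predicted_hot = [by_site[s] for s, p in zip(table_test.sites, predictions) if p == 1]
    true_hot = [r for r in split.testing if r.is_hot]
    standard = standard_regions.build_standard_regions(
        true_hot,
        tolerance=config.contact_tolerance,
        volumes=config.volume_table,
    )
    grid = clustering.grid_search(
        predicted_hot,
        standard,
        min_grid=config.min_grid,
        eps_grid=config.eps_grid,
        coverage=config.coverage,
    )
    predicted_regions = clustering.predict_regions(predicted_hot, grid.best)

    region_counts = evaluation.match_regions(predicted_regions, standard, config.coverage)
    region_metric_set = evaluation.region_metrics(region_counts)
    per_region = evaluation.per_region_report(predicted_regions, standard)

    return RunResult(
        residues=residues,
        split=split,
        table_train=table_train,
        table_test=table_test,
        selected_features=list(selected),
        selection_table=selection_table,
        model=model,
        predictions=predictions,
        residue_counts=residue_counts,
        residue_metrics=residue_metric_set,
        grid=grid,
        predicted_regions=predicted_regions,
        standard_regions=standard,
        region_counts=region_counts,
        region_metrics=region_metric_set,
        per_region=per_region,
    )


def read_coordinate_dir(pdb_dir) -> dict[tuple[str, str, int], np.ndarray]:
    """Read every ``<complex>.pdb`` in a directory into a site -> CA mapping."""
    coords: dict[tuple[str, str, int], np.ndarray] = {}
    for path in sorted(Path(pdb_dir).glob("*.pdb")):
        for rc in features.read_ca_coordinates(path, complex_id=path.stem):
            coords[rc.site] = rc.ca
    return coords


def run_pipeline(config: RunConfig) -> Path:
    """File-based pipeline run; returns the run directory path."""
    config.validate()
    for path_attr in ("mutations", "raw_features", "pdb_dir"):
        if getattr(config, path_attr) is None:
            raise StageError("config", f"{path_attr} input is required")

    records = labeling.read_mutation_table(config.mutations)
    sep = "\t" if str(config.raw_features).endswith((".tsv", ".tab")) else ","
    raw = pd.read_csv(config.raw_features, sep=sep)
    coords = read_coordinate_dir(config.pdb_dir)
    result = run_stages(records, raw, coords, config)

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    run_hash = config.content_hash()

    labeling.residues_to_frame(result.residues).to_csv(out / "labeled.csv", index=False)
    labeling.composition_report(result.residues).to_csv(
        out / "composition.csv", index=False
    )
    result.table_train.x.assign(label=result.table_train.labels).to_csv(
        out / "features_train.csv", index=False
    )
    if result.selection_table is not None:
        result.selection_table.to_csv(out / "selection.csv", index=False)
    (out / "selected_features.json").write_text(
        json.dumps(result.selected_features, indent=2)
    )
    if result.model is not None:
        (out / "model.json").write_text(result.model.to_json())
    pd.DataFrame(
        {
            "complex": [s[0] for s in result.table_test.sites],
            "chain": [s[1] for s in result.table_test.sites],
            "position": [s[2] for s in result.table_test.sites],
            "predicted": result.predictions,
            "true": result.table_test.labels,
        }
    ).to_csv(out / "predictions.csv", index=False)
    result.grid.table.to_csv(out / "grid_search.csv", index=False)
    clustering.regions_to_frame(result.predicted_regions).to_csv(
        out / "regions_predicted.csv", index=False
    )
    clustering.regions_to_frame(result.standard_regions).to_csv(
        out / "regions_standard.csv", index=False
    )
    result.per_region.to_csv(out / "per_region.csv", index=False)
    metrics = result.metrics_dict()
    metrics["config_hash"] = run_hash
    (out / "metrics.json").write_text(json.dumps(metrics, indent=2))
    (out / "config.json").write_text(
        json.dumps(dataclasses.asdict(config), indent=2, default=str)
    )
    return out
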