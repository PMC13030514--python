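"""End-to-end orchestration: simulate -> preprocess -> PCA -> split -> train
-> evaluate, with explicit seeds, config hashing and per-stage logging.

One top-level seed deterministically derives per-stage seeds, so a stage can
be rerun in isolation and a full rerun with the same config reproduces the
same tables byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import classifiers, evaluation_report, pca_explorer, roi_sampling, spectral_metrics
from .reference_ranges import REFERENCE_ROI_COUNTS
from .synthetic_data import NoiseModel, default_wavelength_grid, generate_cohort

log = logging.getLogger(__name__)

_STAGE_SEEDS = {"simulate": 1, "split": 2, "train": 3, "pca": 4}


@dataclass
class PipelineConfig:
    """Everything a run needs; round-trips losslessly through YAML."""

    out_dir: str = "weedspec_run"
    n_bands: int = 61
    n_plants_per_species: int = 25
    pixels_per_roi: int = 60
    use_reference_roi_counts: bool = True
    smoothing_window: int = 5
    snv_enabled: bool = True
    metric_window: tuple[float, float] = (500.0, 780.0)
    train_fraction: float = 0.7
    pca_components: int = 6
    algorithms: tuple[str, ...] = classifiers.ALGORITHMS
    seed: int = 0
    noise: dict = field(default_factory=lambda: dataclasses.asdict(NoiseModel()))

    def __post_init__(self) -> None:
        for algo in self.algorithms:
            if algo not in classifiers.ALGORITHMS:
                raise ValueError(
                    f"config field 'algorithms' names unknown algorithm {algo!r}"
                )

    def stage_seed(self, stage: str) -> int:
        # top-level seed deterministically derives stage seeds (< 2**31)
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31)

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["metric_window"] = list(self.metric_window)
        d["algorithms"] = list(self.algorithms)
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        d = yaml.safe_load(text)
        d["metric_window"] = tuple(d["metric_window"])
        d["algorithms"] = tuple(d["algorithms"])
        return cls(**d)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full synthetic analysis; returns the artifact directory.

    Outputs: ROI table, split plan, spectral-statistics tables, per-algorithm
    evaluation reports and a JSON summary, all stamped with the config hash.
    Any stage failure aborts with the stage name and cause.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("weedspec")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    (out / "config.yaml").write_text(config.to_yaml())
    summary: dict = {"config_hash": config.config_hash}

    stage = "simulate"
    try:
        t0 = time.perf_counter()
        log.info("stage %s (seed %d)", stage, config.stage_seed(stage))
        dataset = generate_cohort(
            n_plants_per_species=config.n_plants_per_species,
            pixels_per_roi=config.pixels_per_roi,
            wavelengths=default_wavelength_grid(config.n_bands),
            noise=NoiseModel(**config.noise),
            roi_counts=REFERENCE_ROI_COUNTS if config.use_reference_roi_counts else None,
            seed=config.stage_seed(stage),
        )
        dataset.write_table(out / "roi_table.tsv")
        summary["n_rois"] = len(dataset)
        summary["n_plants"] = len(dataset.plant_ids)
        log.info("simulated %d ROIs in %.1fs", len(dataset), time.perf_counter() - t0)

        stage = "metrics"
        measured = spectral_metrics.stats_table(dataset, window=config.metric_window)
        measured.to_csv(out / "metrics_measured.tsv", sep="\t", index=False)
        reference = spectral_metrics.reference_stats_table()
        reference.to_csv(out / "metrics_reference.tsv", sep="\t", index=False)
        summary["n_species_rows"] = int(len(measured))

        stage = "pca"
        pixels = np.vstack([r.spectra for r in dataset.rois[:200]])
        model = pca_explorer.fit_pixel_pca(pixels, k=config.pca_components,
                                           wavelengths=dataset.wavelengths)
        model.save(out / "pca_model.json")
        summary["pc1_explained_pct"] = float(pca_explorer.explained_variance(model)[0])
        summary["cumulative_pc2_pct"] = pca_explorer.cumulative_variance(model, 2)

        stage = "split"
        plan = roi_sampling.plant_wise_split(
            dataset, train_fraction=config.train_fraction,
            seed=config.stage_seed(stage),
        )
        plan.write(out / "split_plan.tsv")
        train_rois, test_rois = roi_sampling.split_rois(dataset, plan)
        summary["n_train_rois"] = len(train_rois)
        summary["n_test_rois"] = len(test_rois)

        stage = "train"
        fm_train = classifiers.build_feature_matrix(
            train_rois, window=config.smoothing_window, apply_snv=config.snv_enabled
        )
        fm_test = classifiers.build_feature_matrix(
            test_rois, window=config.smoothing_window, apply_snv=config.snv_enabled
        )
        reports = []
        reports_dir = out / "reports"
        reports_dir.mkdir(exist_ok=True)
        for algo in config.algorithms:
            t1 = time.perf_counter()
            clf = classifiers.train(algo, fm_train, seed=config.stage_seed(stage))
            report = evaluation_report.evaluate(clf, fm_test)
            reports.append(report)
            report.to_frame().to_csv(reports_dir / f"{algo}_report.tsv", sep="\t")
            np.savetxt(reports_dir / f"{algo}_confusion.tsv", report.confusion,
                       fmt="%d", delimiter="\t")
            summary[f"{algo}_overall_accuracy"] = report.overall_accuracy
            summary[f"{algo}_log_loss"] = report.log_loss
            log.info("%s: accuracy %.1f%% (%.1fs)", algo, report.overall_accuracy,
                     time.perf_counter() - t1)

        stage = "report"
        ranking = evaluation_report.compare_report(reports)
        ranking.to_csv(out / "ranking.tsv", sep="\t")
        summary["ranking"] = ranking["algorithm"].tolist()
    except Exception as exc:
        root.removeHandler(handler)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    root.removeHandler(handler)
    handler.close()
    return out
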