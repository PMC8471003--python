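"""End-to-end orchestration: simulate -> preprocess -> train -> evaluate -> rank.

A :class:`PipelineConfig` (plain YAML on disk) fully determines a run: study
design, forward-model parameters, CNN protocol, fiber specs to evaluate, and
the master seed. ``run_pipeline`` executes the stages, writes per-spec
summaries, the fiber ranking, pooled confusion matrices and a JSON report
into the output directory, and is reproducible from config + seed alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import yaml

from .cnn import CNNConfig, fiber_spec_name, train_replicates
from .constructs import StudyDesign, enumerate_study_classes
from .evaluation import evaluate_replicates, rank_fiber_combinations
from .io import Dataset, write_dataset
from .spectra import default_grid
from .synthetic import TissueOpticalModel, simulate_study

logger = logging.getLogger("fibrospec")

DEFAULT_FIBER_SPECS = ["R1", "R2", "R3", "R4", "R5"]


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one pipeline run."""

    study: str = "binary"
    seed: int = 0
    out_dir: str = "results/pipeline"
    fiber_specs: List[str] = field(default_factory=lambda: list(DEFAULT_FIBER_SPECS))
    calibrate: bool = False
    n_wavelengths: int = 3587
    n_rebuilds: int = 3
    spectra_per_fiber_per_rebuild: int = 10
    model_params: Dict = field(default_factory=dict)
    cnn_params: Dict = field(default_factory=dict)
    exclusion_threshold: Optional[float] = None
    write_dataset_csv: bool = False

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def build_design(self) -> StudyDesign:
        return enumerate_study_classes(
            self.study,
            n_rebuilds=self.n_rebuilds,
            spectra_per_fiber_per_rebuild=self.spectra_per_fiber_per_rebuild,
        )

    def build_model(self) -> TissueOpticalModel:
        return TissueOpticalModel(
            wavelengths=default_grid(self.n_wavelengths), **self.model_params
        )

    def build_cnn_config(self) -> CNNConfig:
        return CNNConfig(**self.cnn_params)


def calibrate_dataset(dataset: Dataset) -> Dataset:
    """Calibrate every tissue spectrum against the mean standard spectrum.

    Tissue rows and the mean of the ``standard`` rows are mean-normalized,
    divided pointwise, and re-normalized; the standard rows are dropped from
    the returned dataset.
    """
    roles = dataset.manifest["role"].to_numpy()
    std_rows = np.flatnonzero(roles == "standard")
    if std_rows.size == 0:
        raise ValueError("dataset holds no standard spectra to calibrate against")
    ref = dataset.intensities[std_rows].mean(axis=0)
    if np.any(ref <= 0):
        raise ValueError("mean standard spectrum must be strictly positive")
    ref = ref / ref.mean()
    tissue_rows = np.flatnonzero(roles == "tissue")
    tissue = dataset.intensities[tissue_rows]
    norm = tissue / tissue.mean(axis=1, keepdims=True)
    ratio = norm / ref
    calibrated = ratio / ratio.mean(axis=1, keepdims=True)
    return Dataset(
        wavelengths=dataset.wavelengths,
        intensities=calibrated,
        manifest=dataset.manifest.iloc[tissue_rows].reset_index(drop=True),
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the report dict written to disk."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    design = config.build_design()
    model = config.build_model()
    cnn_config = config.build_cnn_config()
    logger.info("study=%s seed=%d classes=%d", config.study, config.seed, design.n_classes)

    dataset = simulate_study(
        design, model, seed=config.seed,
        n_reference_spectra=10 if config.calibrate else 0,
    )
    if config.calibrate:
        dataset = calibrate_dataset(dataset)
    if config.write_dataset_csv:
        write_dataset(dataset, out / "spectra.csv", out / "manifest.csv")

    summaries = {}
    report_specs = {}
    for i, spec in enumerate(config.fiber_specs):
        name = fiber_spec_name(spec)
        spec_seed = config.seed + 10007 * (i + 1)
        replicates = train_replicates(dataset, design, cnn_config, spec, base_seed=spec_seed)
        results, summary, pooled = evaluate_replicates(
            replicates, design, config.exclusion_threshold
        )
        summaries[name] = summary
        pooled.to_csv(out / f"confusion_{name}.csv")
        for rep, res in zip(replicates, results):
            logger.info(
                "spec=%s replicate=%d epochs=%d accuracy=%.4f",
                name, rep.replicate_index, rep.n_epochs, res.accuracy,
            )
        for exc in summary.excluded:
            logger.warning("spec=%s excluded replicate: %s", name, exc["reason"])
        report_specs[name] = {
            "mean_accuracy": summary.mean_accuracy,
            "stddev_accuracy": summary.stddev_accuracy,
            "replicate_accuracies": summary.replicate_accuracies,
            "excluded": summary.excluded,
            "epochs": [rep.n_epochs for rep in replicates],
            "seed": spec_seed,
        }

    ranking = rank_fiber_combinations(summaries)
    ranking.table.to_csv(out / "fiber_ranking.csv", index=False)
    report = {
        "study": config.study,
        "seed": config.seed,
        "n_classes": design.n_classes,
        "chance_accuracy": design.chance_accuracy,
        "calibrate": config.calibrate,
        "fiber_specs": report_specs,
        "ranking": ranking.table.to_dict(orient="records"),
        "pair_minus_single_gap": ranking.pair_minus_single_gap,
    }
    (out / "report.json").write_text(json.dumps(report, indent=2))
    config.to_yaml(out / "config.yaml")
    return report
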