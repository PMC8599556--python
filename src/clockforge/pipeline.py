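"""End-to-end orchestration: QC -> clock training -> cross-validation
-> cross-species transfer -> EWAS, driven by a single flat config.

Every stage writes its outputs under the configured directory and the
run ends with a ``manifest.json`` listing each artifact's relative
path and SHA-256 content hash.  All randomness is funneled through
named seeds in the config, so two runs of the same config produce
bit-identical manifests — reproducibility is the artifact's core
promise.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clock as clock_mod
from . import cross_species, ewas, qc, synthetic
from . import io as cfio

__all__ = ["PipelineConfig", "run_pipeline", "make_demo"]

log = logging.getLogger("clockforge")


@dataclass
class PipelineConfig:
    """Flat pipeline configuration.

    Paths are resolved relative to the config file's directory when
    loaded from disk.  Stage toggles (``run_*``) switch whole stages;
    stage parameters are explicit so the manifest pins every choice.
    """

    matrix: str = ""
    sample_sheet: str = ""
    species_params: str = ""
    annotation: str = ""
    out_dir: str = "clockforge_out"

    run_qc: bool = True
    run_train: bool = True
    run_cv: bool = True
    run_transfer: bool = True
    run_ewas: bool = True

    clock_targets: tuple = ("raw_age", "loglinear_age", "relative_age")
    train_species: tuple = ()  # empty = all species in the sheet
    transfer_species: tuple = ()  # species scored but never trained on
    alpha: float = 0.5
    n_lambda: int = 50
    cv_scheme: str = "kfold"  # "kfold" | "loo"
    cv_k: int = 10
    qc_knn: int = 5
    qc_trees: int = 500
    ewas_p_threshold: float = 1e-8
    ewas_cap: int = 500
    seed_train: int = 0
    seed_cv: int = 0
    seed_qc: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        for attr in ("matrix", "sample_sheet", "species_params", "annotation", "out_dir"):
            value = getattr(cfg, attr)
            if value and not Path(value).is_absolute():
                setattr(cfg, attr, str(path.parent / value))
        for attr in ("clock_targets", "train_species", "transfer_species"):
            setattr(cfg, attr, tuple(getattr(cfg, attr)))
        return cfg

    def validate(self) -> None:
        for attr in ("matrix", "sample_sheet", "species_params"):
            value = getattr(self, attr)
            if not value or not Path(value).exists():
                raise FileNotFoundError(f"config {attr} file not found: {value!r}")
        if self.run_ewas and self.annotation and not Path(self.annotation).exists():
            raise FileNotFoundError(f"annotation file not found: {self.annotation!r}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages in dependency order and return the
    manifest.  A stage failure aborts the run with the failing stage
    named; outputs of completed stages are retained."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    matrix = cfio.read_matrix(config.matrix)
    sheet = cfio.read_sample_sheet(config.sample_sheet)
    species_params = cfio.read_species_params(config.species_params)
    matrix, sheet = cfio.align(matrix, sheet)

    train_species = tuple(config.train_species) or tuple(
        sp for sp in sorted(sheet["species"].unique())
        if sp not in set(config.transfer_species))
    train_mask = sheet["species"].isin(train_species).to_numpy()
    train_matrix = matrix.loc_samples(sheet.index[train_mask])
    train_sheet = sheet.loc[sheet.index[train_mask]]

    outputs = []
    stage = "setup"
    try:
        if config.run_qc:
            stage = "qc"
            log.info("stage qc: %d samples", matrix.shape[0])
            report = qc.run_qc(matrix, sheet, k=config.qc_knn,
                               n_trees=config.qc_trees, seed=config.seed_qc)
            _write_json(report.to_dict(), out / "qc_report.json")
            (out / "dendrogram.nwk").write_text(report.dendrogram.to_newick() + "\n")
            outputs += ["qc_report.json", "dendrogram.nwk"]

        clocks = {}
        if config.run_train:
            stage = "train"
            for target in config.clock_targets:
                log.info("stage train: %s clock on %s", target, train_species)
                model = clock_mod.train_clock(
                    train_matrix, train_sheet, species_params=species_params,
                    target=target, alpha=config.alpha, seed=config.seed_train,
                    n_lambda=config.n_lambda)
                fname = f"clock_{target}.tsv"
                cfio.write_clock(model, out / fname)
                clocks[target] = model
                outputs.append(fname)

        if config.run_cv:
            stage = "cv"
            metrics_all = {}
            for target in config.clock_targets:
                log.info("stage cv: %s (%s)", target, config.cv_scheme)
                if config.cv_scheme == "loo":
                    result = clock_mod.loocv(
                        train_matrix, train_sheet, species_params=species_params,
                        target=target, alpha=config.alpha, seed=config.seed_cv,
                        n_lambda=config.n_lambda)
                else:
                    result = clock_mod.kfold_cv(
                        train_matrix, train_sheet, species_params=species_params,
                        target=target, k=config.cv_k, alpha=config.alpha,
                        seed=config.seed_cv, n_lambda=config.n_lambda)
                fname = f"cv_{target}.tsv"
                result.predictions.rename_axis("sample_id").to_csv(out / fname, sep="\t")
                metrics_all[target] = {
                    grp: {k: float(v) for k, v in row.items()}
                    for grp, row in result.metrics().to_dict(orient="index").items()}
                outputs.append(fname)
            _write_json(metrics_all, out / "cv_metrics.json")
            outputs.append("cv_metrics.json")

        if config.run_transfer and config.transfer_species and clocks:
            stage = "transfer"
            transfer_mask = sheet["species"].isin(config.transfer_species).to_numpy()
            if transfer_mask.sum() >= 3:
                t_matrix = matrix.loc_samples(sheet.index[transfer_mask])
                t_sheet = sheet.loc[sheet.index[transfer_mask]]
                report_all = {}
                for target, model in clocks.items():
                    log.info("stage transfer: %s clock", target)
                    rep = cross_species.transfer_evaluate(
                        model, t_matrix, t_sheet, species_params=species_params)
                    report_all[target] = rep.to_dict()
                _write_json(report_all, out / "transfer_report.json")
                outputs.append("transfer_report.json")

        if config.run_ewas:
            stage = "ewas"
            log.info("stage ewas: %d probes", matrix.shape[1])
            first_species = train_species[0]
            sp_mask = (sheet["species"] == first_species).to_numpy()
            records = ewas.ewas_screen(
                matrix.loc_samples(sheet.index[sp_mask]),
                sheet.loc[sheet.index[sp_mask], "age"])
            records.to_csv(out / "ewas.tsv", sep="\t")
            outputs.append("ewas.tsv")
            topset = ewas.select_top_cpgs(
                records, p_threshold=config.ewas_p_threshold, cap=config.ewas_cap)
            top_summary = {
                "n_hyper": len(topset.hyper), "n_hypo": len(topset.hypo),
                "p_threshold": config.ewas_p_threshold, "cap": config.ewas_cap,
                "hyper": topset.hyper, "hypo": topset.hypo,
            }
            if config.annotation:
                annotation = cfio.read_probe_annotation(config.annotation)
                if len(topset.hyper) + len(topset.hypo) > 0:
                    region = ewas.region_summary(topset, annotation)
                    region.rename_axis("region").to_csv(out / "ewas_regions.tsv", sep="\t")
                    outputs.append("ewas_regions.tsv")
                island = ewas.island_association_summary(records, annotation)
                top_summary["island_contrast"] = island
            _write_json(top_summary, out / "ewas_top.json")
            outputs.append("ewas_top.json")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()
                   if k not in ("matrix", "sample_sheet", "species_params",
                                "annotation", "out_dir")},
        "inputs": {
            "matrix": _sha256(Path(config.matrix)),
            "sample_sheet": _sha256(Path(config.sample_sheet)),
            "species_params": _sha256(Path(config.species_params)),
        },
        "outputs": {name: _sha256(out / name) for name in sorted(outputs)},
    }
    _write_json(manifest, out / "manifest.json")
    return manifest


def make_demo(out_dir, seed: int = 0) -> Path:
    """Emit a self-contained demo: a small two-training-species panel
    with an off-species group, plus a ready-to-run config.  Sized so
    the full pipeline finishes in a few minutes on one core.

    Returns the path of the written config file.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = synthetic.GeneratorConfig(
        n_probes=800,
        n_age_probes=120,
        n_sex_probes=40,
        n_species_marker_probes=60,
        species={
            "cat": synthetic.SpeciesDesign(n_samples=60, age_range=(0.2, 21.0),
                                           max_lifespan=30.0, maturity=1.0),
            "human": synthetic.SpeciesDesign(n_samples=60, age_range=(0.0, 93.0),
                                             max_lifespan=122.0, maturity=15.0),
            "cheetah": synthetic.SpeciesDesign(n_samples=14, age_range=(1.0, 12.4),
                                               max_lifespan=21.0, maturity=2.0),
        },
        age_probe_offset_sd=0.05,
        seed=int(seed),
    )
    matrix, sheet, annotation, truth = synthetic.generate_panel(config)
    cfio.write_matrix(matrix, out / "betas.tsv")
    cfio.write_sample_sheet(sheet, out / "samples.tsv")
    cfio.write_probe_annotation(annotation, out / "probes.tsv")
    cfio.write_species_params(config.species_params(), out / "species.tsv")
    truth.to_frame().rename_axis("probe_id").to_csv(out / "ground_truth.tsv", sep="\t")

    cfg = {
        "matrix": "betas.tsv",
        "sample_sheet": "samples.tsv",
        "species_params": "species.tsv",
        "annotation": "probes.tsv",
        "out_dir": "results",
        "transfer_species": ["cheetah"],
        "cv_scheme": "kfold",
        "cv_k": 5,
        "n_lambda": 30,
        "qc_trees": 200,
        "seed_train": int(seed),
        "seed_cv": int(seed),
        "seed_qc": int(seed),
    }
    cfg_path = out / "config.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return cfg_path


def _configure_logging(verbose: bool = True) -> None:
    if not log.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        log.addHandler(handler)
    log.setLevel(logging.INFO if verbose else logging.WARNING)
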