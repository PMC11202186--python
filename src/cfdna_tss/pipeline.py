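"""End-to-end orchestration: simulate → coverage → select → pathscore → train.

A run is described by one YAML config (per-stage sections mirroring the
module parameters) and leaves a ``manifest.json`` recording every stage's
outputs with SHA-256 checksums, the seeds used and the package version.
Re-running skips stages whose outputs already exist with matching
checksums unless forced; a failing stage halts the run with its name and
its partial outputs quarantined under ``<outdir>/quarantine``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, List, Optional

import pandas as pd
import yaml

from . import __version__
from .coverage import CoverageMatrix, TssAnnotation, build_coverage_matrix, read_fragments
from .model import RfSpec, SplitSpec, TssClassifier, stratified_split
from .normalize import NormalizationParams, apply_normalization, fit_normalization
from .pathways import (
    PathwayDB,
    egfr_feature_set,
    gene_level_values,
    path_score_matrix,
    pathway_group_test,
)
from .select import FeaturePanel, select_features
from .simulate import SimConfig, simulate_cohort

logger = logging.getLogger(__name__)

STAGE_ORDER = ["simulate", "coverage", "select", "pathscore", "train"]


@dataclass
class RunConfig:
    """Parsed pipeline configuration.

    ``stages`` lists the enabled stages in canonical order; every other
    section is a plain kwargs mapping handed to the matching module.
    The config round-trips losslessly through :meth:`to_yaml` /
    :meth:`from_yaml`.
    """

    outdir: str
    seed: int = 0
    stages: List[str] = field(default_factory=lambda: list(STAGE_ORDER))
    simulate: Dict[str, Any] = field(default_factory=dict)
    coverage: Dict[str, Any] = field(default_factory=dict)
    select: Dict[str, Any] = field(default_factory=dict)
    split: Dict[str, Any] = field(default_factory=dict)
    pathscore: Dict[str, Any] = field(default_factory=dict)
    train: Dict[str, Any] = field(default_factory=dict)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGE_ORDER)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}; known: {STAGE_ORDER}")
        self.stages = [s for s in STAGE_ORDER if s in self.stages]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=False)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class PipelineRun:
    """Executes the enabled stages and maintains the run manifest."""

    def __init__(self, config: RunConfig, force: bool = False) -> None:
        self.config = config
        self.force = force
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        probe = self.outdir / ".write_test"
        probe.write_text("ok")
        probe.unlink()
        self.manifest_path = self.outdir / "manifest.json"
        self.manifest: Dict[str, Any] = {
            "version": __version__,
            "seed": config.seed,
            "stages": {},
        }
        if self.manifest_path.exists():
            self.manifest.update(json.loads(self.manifest_path.read_text()))

    # -- helpers ---------------------------------------------------------

    def _stage_fresh(self, stage: str, outputs: List[Path]) -> bool:
        rec = self.manifest["stages"].get(stage)
        if self.force or rec is None:
            return False
        for path, digest in rec["outputs"].items():
            p = Path(path)
            if not p.exists() or _sha256(p) != digest:
                return False
        return set(rec["outputs"]) == {str(p) for p in outputs}

    def _record(self, stage: str, outputs: List[Path]) -> None:
        self.manifest["stages"][stage] = {
            "outputs": {str(p): _sha256(p) for p in outputs}
        }
        self.manifest_path.write_text(json.dumps(self.manifest, indent=2))

    def _quarantine(self, outputs: List[Path]) -> None:
        qdir = self.outdir / "quarantine"
        qdir.mkdir(exist_ok=True)
        for p in outputs:
            if p.exists():
                shutil.move(str(p), qdir / p.name)

    def _run_stage(self, stage: str, fn, outputs: List[Path]) -> None:
        if self._stage_fresh(stage, outputs):
            logger.info("stage %s: outputs up to date, skipping", stage)
            return
        try:
            fn()
        except Exception:
            self._quarantine(outputs)
            raise RuntimeError(f"pipeline halted: stage {stage!r} failed") from None
        self._record(stage, outputs)

    # -- stages ----------------------------------------------------------

    def run(self) -> Dict[str, Any]:
        cfg = self.config
        logging.basicConfig(level=cfg.log_level)
        sim_dir = self.outdir / "sim"

        if "simulate" in cfg.stages:
            outputs = [sim_dir / n for n in ("tss.bed", "samples.tsv", "pathways.gmt", "truth.tsv")]

            def do_sim() -> None:
                cohort = simulate_cohort(SimConfig(seed=cfg.seed, **cfg.simulate))
                cohort.write(sim_dir)

            self._run_stage("simulate", do_sim, outputs)

        tss_bed = Path(cfg.coverage.get("tss_bed", sim_dir / "tss.bed"))
        sheet_path = Path(cfg.coverage.get("sample_sheet", sim_dir / "samples.tsv"))
        frag_dir = Path(cfg.coverage.get("fragment_dir", sim_dir / "fragments"))
        matrix_path = self.outdir / "matrix.tsv"

        if "coverage" in cfg.stages:
            for p, hint in [(tss_bed, "TSS BED"), (sheet_path, "sample sheet"), (frag_dir, "fragment dir")]:
                if not p.exists():
                    raise FileNotFoundError(f"coverage stage input missing ({hint}): {p}")

            def do_cov() -> None:
                ann = TssAnnotation.from_bed(tss_bed)
                sheet = pd.read_csv(sheet_path, sep="\t")

                def items():
                    for sid in sheet["sample_id"]:
                        bed = frag_dir / f"{sid}.bed"
                        bam = frag_dir / f"{sid}.bam"
                        yield sid, read_fragments(bed if bed.exists() else bam)

                build_coverage_matrix(items(), ann).to_tsv(
                    matrix_path, self.outdir / "matrix.mask.tsv"
                )

            self._run_stage("coverage", do_cov, [matrix_path, self.outdir / "matrix.mask.tsv"])

        needs_matrix = {"select", "pathscore", "train"} & set(cfg.stages)
        if needs_matrix and not matrix_path.exists():
            raise FileNotFoundError(
                f"stage(s) {sorted(needs_matrix)} need {matrix_path}; enable the "
                "coverage stage or provide the matrix"
            )

        if needs_matrix:
            matrix = CoverageMatrix.from_tsv(matrix_path)
            sheet = pd.read_csv(sheet_path, sep="\t", dtype={"stage": str})
            labels = sheet.set_index("sample_id")["label"]
            stages_col = sheet.set_index("sample_id")["stage"]
            split_spec = SplitSpec(seed=cfg.seed, **cfg.split)
            train_ids, val_ids = stratified_split(sheet, split_spec)
            params = fit_normalization(matrix, train_ids)
            zmat = apply_normalization(matrix, params)

        panel_path = self.outdir / "panel.tsv"
        if "select" in cfg.stages:

            def do_select() -> None:
                params.to_json(self.outdir / "normalization.json")
                panel = select_features(
                    zmat.loc[train_ids], labels, stages_col, **cfg.select
                )
                panel.to_tsv(panel_path)
                pd.Series(train_ids).to_csv(
                    self.outdir / "train_ids.txt", index=False, header=False
                )

            self._run_stage(
                "select",
                do_select,
                [panel_path, self.outdir / "normalization.json", self.outdir / "train_ids.txt"],
            )

        if "pathscore" in cfg.stages:
            gmt = Path(cfg.pathscore.get("gmt", sim_dir / "pathways.gmt"))

            def do_path() -> None:
                db = PathwayDB.from_gmt(gmt, anchor=cfg.pathscore.get("anchor", "EGFR"))
                ann = TssAnnotation.from_bed(tss_bed)
                gmat = gene_level_values(zmat, ann)
                scores = path_score_matrix(gmat, db)
                scores.to_csv(self.outdir / "path_scores.tsv", sep="\t", index_label="sample_id")
                egfr = sheet.set_index("sample_id")["egfr_status"]
                known = egfr[egfr.isin(["positive", "wild-type"])]
                res = pathway_group_test(scores.loc[known.index], known, db,
                                         alpha=cfg.pathscore.get("alpha", 0.01))
                res.fraction_table().to_csv(
                    self.outdir / "pathway_fractions.tsv", sep="\t", index=False
                )
                genes = egfr_feature_set(gmat.loc[known.index], db, known,
                                         alpha=cfg.pathscore.get("alpha", 0.01))
                (self.outdir / "egfr_genes.txt").write_text("\n".join(genes) + "\n")

            self._run_stage(
                "pathscore",
                do_path,
                [
                    self.outdir / "path_scores.tsv",
                    self.outdir / "pathway_fractions.tsv",
                    self.outdir / "egfr_genes.txt",
                ],
            )

        if "train" in cfg.stages:
            if not panel_path.exists():
                raise FileNotFoundError(
                    f"train stage needs {panel_path}; enable the select stage first"
                )

            def do_train() -> None:
                panel = FeaturePanel.from_tsv(panel_path)
                spec = RfSpec(seed=cfg.seed, **cfg.train)
                clf = TssClassifier.from_dataframe(
                    zmat,
                    sheet,
                    train_ids,
                    positive_label="cancer",
                    spec=spec,
                    feature_ids=panel.transcript_ids,
                )
                results = clf.fit()
                ev = results.evaluate(zmat.loc[val_ids], labels.loc[val_ids])
                ev.table.to_csv(self.outdir / "auc_report.tsv", sep="\t", index=False)
                ev.curves["all"].to_csv(self.outdir / "roc_validation.tsv", sep="\t", index=False)
                (self.outdir / "model_summary.txt").write_text(results.summary() + "\n")

            self._run_stage(
                "train",
                do_train,
                [
                    self.outdir / "auc_report.tsv",
                    self.outdir / "roc_validation.tsv",
                    self.outdir / "model_summary.txt",
                ],
            )

        return self.manifest


def run_pipeline(config: RunConfig, force: bool = False) -> Dict[str, Any]:
    """Execute the enabled stages; returns the run manifest."""
    return PipelineRun(config, force=force).run()
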