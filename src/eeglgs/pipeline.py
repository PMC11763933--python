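"""End-to-end orchestration: segment -> bands -> z-score -> Granger ->
LGS x8 -> quantifiers x3 -> feature tables -> OVA cross-validation.

Stages communicate through files (feature CSVs, JSON reports) so each
can be re-run in isolation; a run manifest records checksums, shapes,
warnings and the fully resolved configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import ClassifierConfig, CVReport, evaluate_all, summary_percent
from .connectivity import GrangerConfig, granger_matrix
from .exceptions import EEGLGSError
from .io_preprocess import (
    DEFAULT_BANDS,
    BandDefinition,
    EEGRecording,
    extract_bands,
    read_delimited,
    read_edf,
    segment_recording,
    zscore_normalize,
)
from .lgs import apply_all
from .quantify import build_features, write_feature_tables
from .simulate import SimulationConfig, make_cohort, write_cohort

log = logging.getLogger("eeglgs")


@dataclass
class PipelineConfig:
    """Resolved configuration of every stage; YAML round-trippable."""

    segment_len: int = 30_000
    n_segments: int = 5
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS
    filter_order: int = 2
    zero_phase: bool = True
    granger: GrangerConfig = field(default_factory=GrangerConfig)
    lgs_comparison: str = "source_minus_neighbor"
    lgs_bit_order: str = "msb"
    lgs_stride: int = 1
    logenergy_mode: str = "eq_hist"
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    n_folds: int = 10
    grouping: str = "segment"
    seed: int = 0

    def select_bands(self, names: list[str] | None) -> tuple[BandDefinition, ...]:
        if not names:
            return self.bands
        by_name = {b.name: b for b in self.bands}
        return tuple(by_name[n] for n in names)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["bands"] = [dataclasses.asdict(b) for b in self.bands]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "bands" in d:
            d["bands"] = tuple(BandDefinition(**b) for b in d["bands"])
        if isinstance(d.get("granger"), dict):
            d["granger"] = GrangerConfig(**d["granger"])
        if isinstance(d.get("classifier"), dict):
            d["classifier"] = ClassifierConfig(**d["classifier"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def extract_subject_features(
    rec: EEGRecording, cfg: PipelineConfig, bands: tuple[BandDefinition, ...] | None = None
) -> tuple[list, dict]:
    """All code matrices for one recording, plus stage warnings."""
    bands = bands if bands is not None else cfg.bands
    warnings = {"saturated_matrices": 0}
    code_matrices = []
    segments = segment_recording(rec, cfg.segment_len, cfg.n_segments)
    for seg in segments:
        for bs in extract_bands(seg, rec.fs, bands, cfg.filter_order, cfg.zero_phase):
            bs = zscore_normalize(bs)
            cm = granger_matrix(bs, cfg.granger)
            off_diag = cm.values[~np.eye(cm.n_channels, dtype=bool)]
            if cm.binary and np.all(off_diag == 1.0):
                warnings["saturated_matrices"] += 1
            code_matrices.extend(
                apply_all(
                    cm,
                    stride=cfg.lgs_stride,
                    comparison=cfg.lgs_comparison,
                    bit_order=cfg.lgs_bit_order,
                )
            )
    return code_matrices, warnings


def extract_features(
    recordings: list[EEGRecording],
    cfg: PipelineConfig,
    bands: tuple[BandDefinition, ...] | None = None,
    skip_errors: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Feature table for a list of recordings; returns (table, warnings)."""
    all_codes = []
    warnings = {"saturated_matrices": 0, "skipped_subjects": []}
    for rec in recordings:
        try:
            codes, w = extract_subject_features(rec, cfg, bands)
        except EEGLGSError:
            if not skip_errors:
                raise
            log.warning("skipping subject %s after stage error", rec.subject_id)
            warnings["skipped_subjects"].append(rec.subject_id)
            continue
        warnings["saturated_matrices"] += w["saturated_matrices"]
        all_codes.extend(codes)
        log.info(
            "extracted %s: %d code matrices", rec.subject_id, len(codes)
        )
    table = build_features(all_codes, logenergy_mode=cfg.logenergy_mode)
    return table, warnings


def load_recordings(
    indir: str | Path, fs: float | None = None, orientation: str = "channels-by-samples"
) -> list[EEGRecording]:
    """Read every .edf/.csv recording in a directory; manifest.csv (columns
    subject_id, class) supplies class labels when present."""
    indir = Path(indir)
    labels = {}
    manifest = indir / "manifest.csv"
    if manifest.exists():
        mf = pd.read_csv(manifest)
        labels = dict(zip(mf["subject_id"].astype(str), mf["class"].astype(str)))
    recs = []
    for p in sorted(indir.iterdir()):
        if p.suffix.lower() == ".edf":
            rec = read_edf(p)
        elif p.suffix.lower() == ".csv" and p.name != "manifest.csv":
            if fs is None:
                raise EEGLGSError("reading CSV recordings requires a sampling rate")
            rec = read_delimited(p, fs=fs, orientation=orientation)
        else:
            continue
        rec.class_label = labels.get(rec.subject_id)
        recs.append(rec)
    return recs


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(outdir: Path, cfg: PipelineConfig, files: list[Path], warnings: dict) -> Path:
    payload = {
        "version": __version__,
        "config": cfg.to_dict(),
        "warnings": warnings,
        "files": {str(p.relative_to(outdir)): _sha256(p) for p in sorted(set(files))},
    }
    mpath = outdir / "run_manifest.json"
    mpath.write_text(json.dumps(payload, indent=1, sort_keys=True))
    return mpath


def run_all(
    cfg: PipelineConfig,
    sim_cfg: SimulationConfig,
    outdir: str | Path,
    reference_proportions: bool = False,
    write_recordings: bool = False,
) -> tuple[pd.DataFrame, CVReport, Path]:
    """Simulate a cohort, extract features, cross-validate, write outputs.

    Returns (feature table, CV report, manifest path). Determinism
    contract: one config + one seed -> byte-identical feature tables and
    classification JSON.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []

    recordings, truths, cohort_manifest = make_cohort(sim_cfg, reference_proportions)
    mpath = outdir / "cohort_manifest.csv"
    cohort_manifest.to_csv(mpath, index=False)
    files.append(mpath)
    if write_recordings:
        files.extend(write_cohort(recordings, cohort_manifest, outdir / "recordings"))
        files = [p for p in files if outdir in p.parents or p.parent == outdir]

    table, warnings = extract_features(recordings, cfg)
    files.extend(write_feature_tables(table, outdir))

    report = evaluate_all(
        table, cfg.classifier, n_folds=cfg.n_folds, grouping=cfg.grouping
    )
    rpath = outdir / "cv_report.json"
    report.to_json(rpath)
    files.append(rpath)
    spath = outdir / "cv_summary_percent.csv"
    summary_percent(report).to_csv(spath, index=False)
    files.append(spath)

    warnings["zero_division_folds"] = int((report.records["zero_division"] != "").sum())
    cfg_path = outdir / "resolved_config.yaml"
    cfg.to_yaml(cfg_path)
    files.append(cfg_path)
    manifest = write_manifest(outdir, cfg, files, warnings)
    return table, report, manifest
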