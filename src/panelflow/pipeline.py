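"""End-to-end phase-I recipe and reproducibility plumbing.

``run_phase1_pipeline`` wires the stages together — integrate → quantify →
stats → train → predict — writing every artifact with a JSON manifest
(package version, stage seed, parameter hash, SHA-256 of each output) so a
re-run with an identical configuration is byte-identical and auditable.
Every stochastic stage derives its own seed from the single configured
seed plus a stage tag, keeping stages reproducible independently of one
another.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .chromio import (
    read_chromatograms,
    read_runsheet,
    write_area_matrix,
)
from .discriminant import repeated_cv_metrics, train_svm_rfe
from .opls import fit_oplsda
from .panel import PanelConfig, PipelineParams, load_panel
from .peaks import integrate_batch, peak_results_frame
from .qc import FeatureTable, run_qc_chain
from .stats import compare_groups

__all__ = ["RunConfig", "ConfigError", "derive_seed", "run_phase1_pipeline",
           "write_feature_table", "read_feature_table"]

METADATA_PREFIX = "meta_"


class ConfigError(ValueError):
    pass


def derive_seed(seed: int, stage: str) -> int:
    """Stage-specific seed below 2^31, stable across runs and platforms."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunConfig:
    """Paths, parameters and stage toggles for the composite run."""

    panel_path: str
    traces_path: str
    runsheet_path: str
    out_dir: str
    params: PipelineParams = field(default_factory=PipelineParams)
    blank_subtraction: bool = True
    drift_correction: bool = True
    outlier_masking: bool = True
    control_group: str = "HC"
    affected_group: str = "PD"
    predict_groups: tuple[str, ...] = ("iRBD", "OND")

    def validate(self) -> None:
        for name in ("panel_path", "traces_path", "runsheet_path"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise ConfigError(f"{name} does not exist: {p}")

    def param_hash(self) -> str:
        payload = json.dumps(
            {**asdict(self.params), "blank": self.blank_subtraction,
             "drift": self.drift_correction, "outliers": self.outlier_masking,
             "control": self.control_group, "affected": self.affected_group},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Feature-table CSV: protein columns plus ``meta_``-prefixed metadata."""
    out = table.values.copy()
    for col in table.metadata.columns:
        out[METADATA_PREFIX + str(col)] = table.metadata[col].to_numpy()
    out.index.name = "sample_id"
    out.to_csv(path, na_rep="")


def read_feature_table(path: str | Path) -> FeatureTable:
    df = pd.read_csv(path, index_col="sample_id")
    df.index.name = None
    meta_cols = [c for c in df.columns if c.startswith(METADATA_PREFIX)]
    meta = df[meta_cols].rename(columns=lambda c: c[len(METADATA_PREFIX):])
    return FeatureTable(df.drop(columns=meta_cols), meta)


def _write_manifest(out_dir: Path, stage: str, seed: int, cfg: RunConfig,
                    artifacts: list[Path]) -> Path:
    manifest = {
        "stage": stage,
        "panelflow_version": __version__,
        "seed": seed,
        "param_hash": cfg.param_hash(),
        "artifacts": {p.name: _sha256(p) for p in sorted(artifacts)},
    }
    path = out_dir / f"manifest_{stage}.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def run_phase1_pipeline(cfg: RunConfig) -> dict[str, Path]:
    """Execute the composite recipe; returns a name → path map of artifacts.

    Stages run in order and never mutate a prior stage's files; any stage
    error is re-raised annotated with the stage name.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = cfg.params
    artifacts: dict[str, Path] = {}

    def _stage(name: str):
        class _Ctx:
            def __enter__(self):
                return self

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
                return False

        return _Ctx()

    with _stage("integrate"):
        panel = load_panel(cfg.panel_path)
        runsheet = read_runsheet(cfg.runsheet_path)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            traces = read_chromatograms(cfg.traces_path, known_keys=[t.key for t in panel.transitions])
            areas, peak_results = integrate_batch(traces, panel, params, runsheet)
        areas_path = out / "areas.csv"
        write_area_matrix(areas, areas_path)
        peaks_path = out / "peaks.tsv"
        peak_results_frame(peak_results).to_csv(peaks_path, sep="\t", index=False)
        artifacts["areas"] = areas_path
        artifacts["peaks"] = peaks_path
        _write_manifest(out, "integrate", derive_seed(params.seed, "integrate"), cfg,
                        [areas_path, peaks_path])

    with _stage("quantify"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table, reports = run_qc_chain(
                areas, panel, params,
                blank_subtraction=cfg.blank_subtraction,
                drift_correction=cfg.drift_correction,
                outlier_masking=cfg.outlier_masking,
            )
        features_path = out / "features.csv"
        write_feature_table(table, features_path)
        artifacts["features"] = features_path
        _write_manifest(out, "quantify", derive_seed(params.seed, "quantify"), cfg,
                        [features_path])

    groups = table.metadata.get("group")
    has_groups = groups is not None and groups.notna().any()
    if has_groups:
        with _stage("stats"):
            two = table.subset_groups([cfg.control_group, cfg.affected_group])
            comparisons = compare_groups(two, cfg.affected_group, cfg.control_group,
                                         alpha=params.fdr_alpha)
            stats_path = out / "comparisons.tsv"
            comparisons.to_csv(stats_path, sep="\t", index=False)
            artifacts["comparisons"] = stats_path
            _write_manifest(out, "stats", derive_seed(params.seed, "stats"), cfg, [stats_path])

        with _stage("train"):
            svm = train_svm_rfe(
                two, two.metadata["group"],
                seed=derive_seed(params.seed, "train"),
                classes=[cfg.control_group, cfg.affected_group],
                test_fraction=params.test_fraction,
                cv_folds=params.rfe_cv_folds,
            )
            model_path = out / "model.json"
            svm.to_json(model_path)
            opls = fit_oplsda(two.values.fillna(two.values.median()),
                              two.metadata["group"].to_numpy(),
                              seed=derive_seed(params.seed, "oplsda"))
            cv = repeated_cv_metrics(two, two.metadata["group"],
                                     splits=params.repeat_cv_splits,
                                     reps=params.repeat_cv_reps,
                                     seed=derive_seed(params.seed, "cv"))
            summary_path = out / "model_summary.txt"
            summary_path.write_text(
                svm.summary() + "\n\n" + opls.summary() + "\n\nRepeated CV\n"
                + cv.as_frame().to_string(index=False) + "\n"
            )
            artifacts["model"] = model_path
            artifacts["model_summary"] = summary_path
            _write_manifest(out, "train", derive_seed(params.seed, "train"), cfg,
                            [model_path, summary_path])

        with _stage("predict"):
            pred_groups = [g for g in cfg.predict_groups
                           if (table.metadata["group"] == g).any()]
            rows = []
            if pred_groups:
                new = table.subset_groups(pred_groups)
                svm_pred = svm.predict(new.values)
                opls_pred = opls.predict(new.values.fillna(two.values.median()))
                for i, s in enumerate(new.samples):
                    rows.append({"sample_id": s, "group": new.metadata.loc[s, "group"],
                                 "svm_class": svm_pred[s], "oplsda_class": opls_pred[i]})
            pred_path = out / "predictions.tsv"
            pd.DataFrame(rows, columns=["sample_id", "group", "svm_class", "oplsda_class"]
                         ).to_csv(pred_path, sep="\t", index=False)
            artifacts["predictions"] = pred_path
            _write_manifest(out, "predict", derive_seed(params.seed, "predict"), cfg, [pred_path])

    manifest_paths = sorted(out.glob("manifest_*.json"))
    combined = {p.name: json.loads(p.read_text()) for p in manifest_paths}
    run_manifest = out / "manifest_run.json"
    run_manifest.write_text(json.dumps(combined, indent=2, sort_keys=True))
    artifacts["manifest"] = run_manifest
    return artifacts
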