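"""End-to-end orchestration of the discovery-and-prediction workflow.

``run_pipeline`` chains the stages:

    simulate (optional) -> differential expression -> pathway enrichment
    -> key-gene selection -> ensemble training -> evaluation

writing every intermediate artifact as TSV/JSON plus a run manifest with
parameter echo, per-stage row counts and file checksums. A re-run with
the same configuration reproduces the manifest checksums exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datasets import (
    ExpressionDataset,
    map_probes_to_genes,
    read_annotation_tsv,
    read_expression_tsv,
    read_gmt,
    read_metadata_tsv,
)
from .diffexpr import (
    Contrast,
    de_summary,
    moderated_t_test,
    rle_statistics,
    select_de_genes,
    transform_counts,
    volcano_table,
)
from .enrichment import enrich_all
from .ensemble import EnsembleClassifier, evaluate
from .selection import (
    PanelReport,
    apply_allowlist,
    cross_arm_intersect,
    spca_reduce,
    stage1_select,
    t_and_f_test,
)
from .simulate import (
    default_chip_config,
    default_rnaseq_config,
    simulate_chip_arm,
    simulate_rnaseq_arm,
    write_fixture_bundle,
)

log = logging.getLogger("sahpanel")
if not log.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)


@dataclasses.dataclass
class PipelineConfig:
    """Declarative configuration for a full run.

    Leave the path fields ``None`` to simulate both arms in place of
    reading files (the default, self-contained mode).
    """

    # inputs (file mode)
    chip_expression: str | None = None
    chip_metadata: str | None = None
    rnaseq_expression: str | None = None
    rnaseq_metadata: str | None = None
    gmt: str | None = None
    annotation: str | None = None
    out_dir: str = "sahpanel_run"
    # stage parameters (defaults follow the workflow's printed thresholds)
    de_fc_threshold: float = 1.5
    de_p_threshold: float = 0.05
    de_use_adjusted: bool = False
    enrich_p_report: float = 0.001
    enrich_mode: str = "upper_tail"
    stage1_fc_threshold: float = 2.0
    stage1_p_threshold: float = 0.05
    top_k: int = 100
    tf_alpha: float = 0.05
    spca_components: int = 2
    spca_max_genes: int = 5
    allowlist: list[str] | None = None
    boost_rounds: int = 10
    fusion: str = "mean"
    vote_threshold: float = 0.5
    eval_scheme: str | None = None
    seed: int = 0
    verbosity: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(doc) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        doc.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**doc)

    def validate(self) -> None:
        if not 0 < self.de_p_threshold < 1 or not 0 < self.stage1_p_threshold < 1:
            raise ValueError("p thresholds must lie in (0, 1)")
        if self.de_fc_threshold < 1 or self.stage1_fc_threshold < 1:
            raise ValueError("fold-change thresholds must be >= 1 (linear scale)")
        if not 0 < self.enrich_p_report < 1:
            raise ValueError("enrich_p_report must lie in (0, 1)")
        if self.fusion not in ("mean", "sum"):
            raise ValueError("fusion must be 'mean' or 'sum'")
        file_fields = [
            self.chip_expression,
            self.chip_metadata,
            self.rnaseq_expression,
            self.rnaseq_metadata,
            self.gmt,
            self.annotation,
        ]
        given = [f for f in file_fields if f is not None]
        if given and len(given) != len(file_fields):
            raise ValueError(
                "file mode needs all of chip_expression, chip_metadata, "
                "rnaseq_expression, rnaseq_metadata, gmt and annotation"
            )
        out = Path(self.out_dir).resolve()
        for f in given:
            if Path(f).resolve() == out:
                raise ValueError("out_dir must differ from every input path")


def validate_inputs(
    expression: str | Path, metadata: str | Path, gmt: str | Path | None = None
) -> list[dict]:
    """Schema checks on input files; returns a machine-readable report
    (a list of ``{"file", "problem", "detail"}`` entries, empty = clean)."""
    report: list[dict] = []
    meta = None
    try:
        meta = read_metadata_tsv(metadata)
    except Exception as exc:
        report.append({"file": str(metadata), "problem": "unreadable_metadata", "detail": str(exc)})
    try:
        frame = pd.read_csv(expression, sep="\t")
        if frame.columns[0] != "gene_id":
            report.append(
                {"file": str(expression), "problem": "bad_header", "detail": "first column must be gene_id"}
            )
        dup = frame["gene_id"][frame["gene_id"].duplicated()] if "gene_id" in frame else []
        for g in list(dup)[:20]:
            report.append({"file": str(expression), "problem": "duplicate_gene_id", "detail": str(g)})
        if frame.iloc[:, 1:].isna().any().any():
            report.append({"file": str(expression), "problem": "missing_values", "detail": "NaN in matrix"})
        if meta is not None:
            mat_samples = set(frame.columns[1:])
            meta_samples = set(meta["sample_id"])
            for s in sorted(mat_samples - meta_samples):
                report.append({"file": str(expression), "problem": "sample_missing_from_metadata", "detail": s})
            for s in sorted(meta_samples - mat_samples):
                report.append({"file": str(metadata), "problem": "sample_missing_from_matrix", "detail": s})
    except Exception as exc:
        report.append({"file": str(expression), "problem": "unreadable_matrix", "detail": str(exc)})
    if gmt is not None:
        try:
            read_gmt(gmt)
        except Exception as exc:
            report.append({"file": str(gmt), "problem": "bad_gmt", "detail": str(exc)})
    return report


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(frame: pd.DataFrame, path: Path, index_label: str | None = None) -> None:
    if index_label:
        frame.to_csv(path, sep="\t", index_label=index_label, float_format="%.6g")
    else:
        frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full workflow; returns the run manifest."""
    config.validate()
    log.setLevel(config.verbosity)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool_version": __version__,
        "seed": config.seed,
        "parameters": dataclasses.asdict(config),
        "stages": {},
        "files": {},
    }

    def _register(name: str, path: Path) -> None:
        manifest["files"][name] = _sha256(path)

    # ------------------------------------------------------------- simulate
    simulate_mode = config.chip_expression is None
    if simulate_mode:
        log.info("stage simulate: generating both arms (seed=%d)", config.seed)
        chip_cfg = default_chip_config(config.seed)
        chip, chip_truth = simulate_chip_arm(chip_cfg)
        rna_cfg = default_rnaseq_config(config.seed)
        rnaseq, rna_truth = simulate_rnaseq_arm(rna_cfg, panel=chip_truth.biomarker_panel)
        annotation = chip_truth.annotation
        pathways = chip_truth.pathway_membership
        write_fixture_bundle(chip, chip_truth, out / "fixtures" / "chip")
        write_fixture_bundle(rnaseq, rna_truth, out / "fixtures" / "rnaseq")
        manifest["stages"]["simulate"] = {
            "chip_shape": [chip.n_genes, chip.n_samples],
            "rnaseq_shape": [rnaseq.n_genes, rnaseq.n_samples],
            "panel": sorted(chip_truth.biomarker_panel),
        }
    else:
        log.info("stage load: reading input files")
        problems = validate_inputs(config.chip_expression, config.chip_metadata, config.gmt)
        problems += validate_inputs(config.rnaseq_expression, config.rnaseq_metadata)
        if problems:
            raise ValueError(f"input validation failed: {problems[:5]}")
        chip = read_expression_tsv(
            config.chip_expression, read_metadata_tsv(config.chip_metadata), dialect="log"
        )
        rnaseq = read_expression_tsv(
            config.rnaseq_expression, read_metadata_tsv(config.rnaseq_metadata), dialect="counts"
        )
        annotation = read_annotation_tsv(config.annotation)
        pathways = read_gmt(config.gmt)
        chip_truth = rna_truth = None
        manifest["stages"]["load"] = {
            "chip_shape": [chip.n_genes, chip.n_samples],
            "rnaseq_shape": [rnaseq.n_genes, rnaseq.n_samples],
        }

    chip_groups = list(dict.fromkeys(chip.metadata["group"]))
    chip_contrast = Contrast.between(chip_groups[0], chip_groups[1])
    rna_groups = list(dict.fromkeys(rnaseq.metadata["group"]))
    rna_control = rna_groups[-1]

    # ------------------------------------------------------------------- de
    log.info("stage de: moderated t on the chip arm (%s)", chip_contrast.name)
    de_table = moderated_t_test(chip, chip_contrast)
    de_table, up, down = select_de_genes(
        de_table, config.de_fc_threshold, config.de_p_threshold, config.de_use_adjusted
    )
    n_sel = int(de_table["passes_filter"].sum())
    summary = de_summary(n_sel, chip.n_genes, up, down)
    _write_tsv(
        de_table[["log2_fc", "t_stat", "p_raw", "p_adj", "regulation"]],
        out / "chip_de.tsv",
        index_label="gene_id",
    )
    _register("chip_de.tsv", out / "chip_de.tsv")
    _write_tsv(volcano_table(de_table), out / "chip_volcano.tsv")
    _register("chip_volcano.tsv", out / "chip_volcano.tsv")
    rle = rle_statistics(chip)
    _write_tsv(rle, out / "chip_rle.tsv", index_label="sample_id")
    _register("chip_rle.tsv", out / "chip_rle.tsv")

    log.info("stage de: count transform + per-contrast tables on the rnaseq arm")
    rnaseq_log = transform_counts(rnaseq)
    rna_rows = []
    for grp in rna_groups[:-1]:
        contrast = Contrast.between(grp, rna_control)
        table = moderated_t_test(rnaseq_log, contrast)
        table, g_up, g_down = select_de_genes(
            table, config.de_fc_threshold, config.de_p_threshold, config.de_use_adjusted
        )
        rna_rows.append(
            {
                "contrast": contrast.name,
                "n_genes": rnaseq.n_genes,
                "n_selected": int(table["passes_filter"].sum()),
                "up": g_up,
                "down": g_down,
            }
        )
    rna_de = pd.DataFrame(rna_rows)
    _write_tsv(rna_de, out / "rnaseq_de_summary.tsv")
    _register("rnaseq_de_summary.tsv", out / "rnaseq_de_summary.tsv")
    manifest["stages"]["de"] = {"chip": summary, "rnaseq_contrasts": len(rna_rows)}

    # --------------------------------------------------------------- enrich
    log.info("stage enrich: Fisher's exact test over %d pathways", len(pathways))
    de_probes = list(de_table.index[de_table["passes_filter"]])
    de_genes = map_probes_to_genes(de_probes, annotation)
    universe = sorted(set(annotation["gene_id"]))
    enrichment = enrich_all(
        de_genes, universe, pathways, p_report=config.enrich_p_report, mode=config.enrich_mode
    )
    _write_tsv(enrichment, out / "chip_enrichment.tsv")
    _register("chip_enrichment.tsv", out / "chip_enrichment.tsv")
    manifest["stages"]["enrich"] = {
        "n_pathways": int(len(enrichment)),
        "n_significant": int(enrichment["significant"].sum()),
    }

    # --------------------------------------------------------------- select
    log.info("stage select: three-module key-gene screen")
    stage1 = stage1_select(
        chip,
        chip_contrast,
        annotation,
        fc_threshold=config.stage1_fc_threshold,
        p_threshold=config.stage1_p_threshold,
        top_k=config.top_k,
        alpha_level=config.tf_alpha,
    )
    per_arm: dict[str, set[str]] = {}
    lcn2_groups = [g for g in rna_groups if "LCN2" in g] or rna_groups[:2]
    for grp in lcn2_groups:
        contrast = Contrast.between(grp, rna_control)
        tf = t_and_f_test(
            rnaseq_log, contrast, genes=stage1.stage1_genes, alpha_level=config.tf_alpha
        )
        per_arm[contrast.name] = set(tf.index[tf["significant"]])
    intersection = cross_arm_intersect(per_arm)
    if len(intersection) >= config.spca_components:
        loadings = spca_reduce(
            rnaseq_log,
            intersection,
            n_components=config.spca_components,
            max_genes=config.spca_max_genes,
        )
        candidates = loadings.selected_genes
    else:
        candidates = list(intersection)
    final_panel = apply_allowlist(candidates, config.allowlist)
    report = PanelReport(
        ebayes_set=stage1.ebayes_probes,
        rfe_top_set=stage1.rfe_top_probes,
        stage1_set=set(stage1.stage1_genes),
        per_arm_significant=per_arm,
        intersection_set=set(intersection),
        spca_candidates=set(candidates),
        final_panel=set(final_panel),
    )
    report.validate()
    (out / "panel_report.json").write_text(json.dumps(report.to_json(), indent=1, sort_keys=True))
    _register("panel_report.json", out / "panel_report.json")
    manifest["stages"]["select"] = {
        "stage1": len(report.stage1_set),
        "intersection": len(report.intersection_set),
        "spca_candidates": len(report.spca_candidates),
        "final_panel": sorted(report.final_panel),
    }

    # ---------------------------------------------------------------- train
    panel = sorted(report.final_panel)
    if not panel:
        raise RuntimeError("stage train: empty final panel")
    log.info("stage train: boosting three families on %d panel genes", len(panel))
    X = rnaseq_log.subset_genes(panel).values.to_numpy(dtype=float).T
    y = (rnaseq.metadata["group"] != rna_control).to_numpy().astype(int)
    model = EnsembleClassifier(
        T=config.boost_rounds,
        fusion=config.fusion,
        threshold=config.vote_threshold,
        random_state=config.seed,
    ).fit(X, y)
    model.save(out / "ensemble_model.json")
    _register("ensemble_model.json", out / "ensemble_model.json")
    manifest["stages"]["train"] = {
        "n_samples": int(len(y)),
        "rounds": {f: len(m.rounds_) for f, m in model.members_.items()},
    }

    # ------------------------------------------------------------- evaluate
    log.info("stage evaluate: cross-validated metrics")
    report_eval = evaluate(
        X,
        y,
        T=config.boost_rounds,
        fusion=config.fusion,
        threshold=config.vote_threshold,
        scheme=config.eval_scheme,
        seed=config.seed,
    )
    metrics = pd.DataFrame(
        [
            {
                "model": "ensemble",
                "accuracy": report_eval.accuracy,
                "precision": report_eval.precision,
                "sensitivity": report_eval.sensitivity,
                "specificity": report_eval.specificity,
                "auc": report_eval.auc,
            }
        ]
        + [
            {"model": fam, "accuracy": acc, "precision": np.nan, "sensitivity": np.nan, "specificity": np.nan, "auc": np.nan}
            for fam, acc in report_eval.base_accuracy.items()
            if fam != "ensemble"
        ]
    )
    _write_tsv(metrics, out / "evaluation.tsv")
    _register("evaluation.tsv", out / "evaluation.tsv")
    roc = pd.DataFrame(report_eval.roc_points, columns=["fpr", "tpr"])
    _write_tsv(roc, out / "roc_points.tsv")
    _register("roc_points.tsv", out / "roc_points.tsv")
    manifest["stages"]["evaluate"] = {
        "accuracy": report_eval.accuracy,
        "auc": report_eval.auc,
        "base_accuracy": report_eval.base_accuracy,
    }

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    log.info("run complete: %s", out / "manifest.json")
    return manifest
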