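"""End-to-end orchestration: correlate -> select -> weights -> score ->
survival -> ablate, with a machine-readable run manifest.

The pipeline reads a YAML config (see :class:`PipelineConfig`), either
pointing at TSV inputs or asking for synthetic inputs, runs the six stages
in order, persists every stage's output under the output directory, and
writes ``manifest.json`` recording parameters, seed, and per-stage row
counts.  Re-running an identical config reproduces identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .ablation import ablate
from .io import (
    read_annotation,
    read_clinical,
    read_drug_response,
    read_expression,
    write_table,
)
from .score import compute_score, fit_weights
from .screen import screen_all
from .selection import select_resistance_genes
from .simulate import CohortConfig, PanelConfig, simulate_cohort, simulate_panel
from .survival import logrank_test, score_group_cox, stratify_by_score

logger = logging.getLogger(__name__)

STAGES = ("correlate", "select", "weights", "score", "survival", "ablate")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: str):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Resolved configuration for one end-to-end run."""

    out_dir: str
    # file inputs (ignored when `synthetic` is set)
    expression: str | None = None
    response: str | None = None
    annotation: str | None = None
    cohort_expression: str | None = None
    clinical: str | None = None
    metric: str = "LN_IC50"
    # selection parameters
    top_k: int = 50
    min_drugs: int = 20
    alpha: float = 0.05
    min_samples: int = 9
    # score context
    drug: str = ""
    lineage: str = ""
    # survival
    stratify: str = "MEDIAN"
    covariates: list = field(default_factory=lambda: ["age", "stage", "grade"])
    ablation_sizes: list = field(default_factory=lambda: [1])
    seed: int = 0
    synthetic: dict | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _load_inputs(cfg: PipelineConfig):
    if cfg.synthetic is not None:
        panel_cfg = PanelConfig(**{**cfg.synthetic.get("panel", {}), "seed": cfg.seed})
        expr, resp, annot, truth = simulate_panel(panel_cfg)
        return expr, resp, annot, truth
    expr = read_expression(cfg.expression, zscore_on_load=True)
    resp = read_drug_response(cfg.response, metric=cfg.metric)
    annot = read_annotation(cfg.annotation)
    return expr, resp, annot, None


def run_end_to_end(cfg: PipelineConfig) -> dict:
    """Run the six stages in order; returns the manifest dictionary.

    Any stage failure aborts with :class:`StageError`; outputs of completed
    stages are retained and the manifest carries a FAILED marker.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "parameters": {k: v for k, v in asdict(cfg).items() if k != "synthetic"},
        "synthetic": cfg.synthetic is not None,
        "stages": {},
    }
    current = "correlate"
    try:
        expr, resp, annot, truth = _load_inputs(cfg)
        if cfg.synthetic is not None:
            inputs = out / "inputs"
            inputs.mkdir(exist_ok=True)
            expr.to_tsv(inputs / "expression.tsv")
            resp.to_tsv(inputs / "response.tsv")
            annot.to_tsv(inputs / "annotation.tsv")
        screens = screen_all(expr, resp, min_samples=cfg.min_samples)
        corr_dir = out / "correlations"
        corr_dir.mkdir(exist_ok=True)
        for drug_id, rec in screens.items():
            write_table(rec, corr_dir / f"{drug_id}.tsv")
        manifest["stages"]["correlate"] = {
            "status": "OK", "drugs": len(screens), "failed_drugs": sorted(screens.failed),
        }
        logger.info("[correlate] %d drugs screened, %d failed", len(screens), len(screens.failed))

        current = "select"
        selection = select_resistance_genes(
            screens, top_k=cfg.top_k, min_drugs=cfg.min_drugs, alpha=cfg.alpha
        )
        write_table(selection.to_frame(), out / "signature.tsv")
        manifest["stages"]["select"] = {
            "status": "OK", "selected_genes": len(selection.selected_genes),
        }
        logger.info("[select] %d genes selected", len(selection.selected_genes))
        if not selection.selected_genes:
            raise StageError("weights", "empty signature: no gene met the selection rule")

        current = "weights"
        drug = cfg.drug or sorted(screens.keys())[0]
        lineage = cfg.lineage or annot.lineages[0]
        weights = fit_weights(expr, resp, selection.selected_genes, drug, lineage,
                              annot, min_samples=cfg.min_samples)
        write_table(weights.to_frame(), out / "weights.tsv")
        manifest["stages"]["weights"] = {
            "status": "OK", "genes": weights.n_genes, "drug": drug, "lineage": lineage,
        }

        current = "score"
        if cfg.synthetic is not None:
            cohort_cfg = CohortConfig(**{**cfg.synthetic.get("cohort", {}), "seed": cfg.seed})
            cohort_expr, clinical, _ = simulate_cohort(cohort_cfg, weights)
        else:
            cohort_expr = read_expression(cfg.cohort_expression, zscore_on_load=True)
            clinical = read_clinical(cfg.clinical)
        score = compute_score(weights, cohort_expr)
        write_table(score.to_frame(), out / "scores.tsv")
        manifest["stages"]["score"] = {
            "status": "OK", "samples": len(score.scores),
            "genes_used": score.genes_used, "genes_missing": score.genes_missing,
        }

        current = "survival"
        shared = clinical.index.intersection(score.scores.index)
        strata = stratify_by_score(score.scores.loc[shared], method=cfg.stratify)
        low = clinical.loc[strata.samples("LOW")]
        high = clinical.loc[strata.samples("HIGH")]
        chi2, logrank_p = logrank_test(low, high)
        uni = score_group_cox(clinical, score.scores, covariates=(), stratify=cfg.stratify)
        multi = score_group_cox(clinical, score.scores, covariates=cfg.covariates,
                                stratify=cfg.stratify)
        surv_tab = pd.concat(
            [uni.summary.assign(model="UNIVARIATE"), multi.summary.assign(model="MULTIVARIATE")],
            ignore_index=True,
        )
        write_table(surv_tab, out / "survival.tsv")
        manifest["stages"]["survival"] = {
            "status": "OK", "n": int(len(shared)),
            "logrank_chi2": chi2, "logrank_p": logrank_p,
            "hr_univariate": uni.hazard_ratio("score_high"),
            "hr_multivariate": multi.hazard_ratio("score_high"),
        }

        current = "ablate"
        report = ablate(weights, cohort_expr, clinical, covariates=cfg.covariates,
                        subset_sizes=tuple(cfg.ablation_sizes))
        write_table(report.results, out / "ablation.tsv")
        manifest["stages"]["ablate"] = {
            "status": "OK", "removals": len(report.results),
            "full_hr": report.full_hazard_ratio,
        }
    except StageError as exc:
        manifest["stages"].setdefault(exc.stage, {})["status"] = "FAILED"
        manifest["stages"][exc.stage]["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise
    except Exception as exc:  # annotate with the failing stage
        manifest["stages"][current] = {"status": "FAILED", "error": str(exc)}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise StageError(current, str(exc)) from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
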