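"""End-to-end run of the six-step cross-cancer prediction pipeline.

Step order: (1) discover initial drug-sensitivity biomarkers on the cell
panel; (2) gate candidate cancer types by comparing their bCOXEN against
the weakest original-type wCOXEN; (3) triage the initial biomarkers to the
three-way concordant set; (4) train PC-regression candidates over the
biomarker-size grid and select the final model and Youden threshold on the
original-type evaluation cohort; (5, 6) validate the frozen model
prospectively on every held-out cohort.  Cohort roles come from the
configuration, and the runner enforces that validation cohorts are never
read before the final step.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from . import concordance, discovery, modeling, validation
from .io import (RunConfig, read_drug_activity, read_expression_matrix,
                 read_phenotype_table)
from .matrix import DataError, ExpressionMatrix, PhenotypeTable

log = logging.getLogger("coxen.pipeline")


@dataclass
class PipelineResult:
    config: RunConfig
    biomarkers: discovery.BiomarkerSet
    discovery_fallback: bool
    gate: Optional[concordance.CoxenGateResult]
    chosen_candidate: Optional[str]
    concordant: Optional[concordance.ConcordBiomarkerSet]
    threeway_fallback: bool
    selection: modeling.ModelSelectionReport
    model: modeling.PCRModel
    threshold: float
    validations: dict               # cohort name -> ValidationReport
    seed: int
    no_transferable_type: bool = False

    def model_json(self) -> str:
        return self.model.to_json()


def _load_cohort(spec, need_phenotype: bool) -> tuple[ExpressionMatrix, Optional[PhenotypeTable]]:
    expr = read_expression_matrix(spec.expression, system_label=spec.name)
    pheno = None
    if spec.phenotype:
        pheno = read_phenotype_table(spec.phenotype)
    elif need_phenotype:
        raise DataError(f"cohort {spec.name!r} needs a phenotype file for its role")
    return expr, pheno


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute discovery -> gate -> three-way triage -> model selection ->
    prospective validation from one configuration; deterministic given the
    configured seed."""
    cfg = config
    for path_key in ("cell_expression", "drug_activity"):
        p = getattr(cfg, path_key)
        if not p or not Path(p).exists():
            raise FileNotFoundError(f"config key {path_key!r}: missing input file {p!r}")
    for spec in cfg.cohorts:
        if not Path(spec.expression).exists():
            raise FileNotFoundError(
                f"cohort {spec.name!r}: missing expression file {spec.expression!r}")

    roles = {r: [s for s in cfg.cohorts if s.role == r]
             for r in ("original_coxen", "original_evaluation",
                       "candidate_coxen", "validation")}
    if len(roles["original_coxen"]) < 1 or len(roles["original_evaluation"]) != 1:
        raise ValueError("need >= 1 original_coxen cohort and exactly one "
                         "original_evaluation cohort")

    cell_expr = read_expression_matrix(cfg.cell_expression, system_label="cell_panel")
    act = read_drug_activity(cfg.drug_activity, drug_name=cfg.drug_name)

    # Step 1: discovery on the cell panel.
    if cfg.discovery_method == "ttest":
        classing = discovery.classify_sensitivity(act, cfg.lower_frac, cfg.upper_frac)
        initial = discovery.discover_ttest(cell_expr, classing, cfg.discovery_fdr,
                                           drug_name=cfg.drug_name)
    else:
        initial = discovery.discover_correlation(cell_expr, act, cfg.discovery_fdr)
    discovery_fallback = False
    if len(initial) < cfg.min_model_genes:
        discovery_fallback = True
        top = sorted([r for r in initial.full_table if not r.flagged],
                     key=lambda r: (-abs(r.statistic), r.gene_id))[:max(cfg.min_model_genes, 20)]
        warnings.warn(f"only {len(initial)} genes significant at FDR "
                      f"{cfg.discovery_fdr}; falling back to the top {len(top)} "
                      "by |statistic|")
        initial = discovery.BiomarkerSet(top, initial.panel_label, initial.drug_name,
                                         initial.method, full_table=initial.full_table)
    log.info("step 1: %d initial biomarkers (%s)", len(initial), initial.method)

    orig_sets = [(s, *_load_cohort(s, need_phenotype=False)) for s in roles["original_coxen"]]
    eval_spec = roles["original_evaluation"][0]
    eval_expr, eval_pheno = _load_cohort(eval_spec, need_phenotype=True)

    # Step 2: wCOXEN among original-type cohorts, bCOXEN for each candidate.
    original_exprs = [e for _, e, _ in orig_sets] + [eval_expr]
    wsets = []
    for i in range(len(original_exprs)):
        for j in range(i + 1, len(original_exprs)):
            wsets.append(concordance.coxen_distribution(
                initial.gene_ids, original_exprs[i], original_exprs[j],
                cfg.diagonal_mode))
    gate = None
    chosen_candidate = None
    cand_exprs = {}
    if roles["candidate_coxen"]:
        bsets = []
        for spec in roles["candidate_coxen"]:
            e, _ = _load_cohort(spec, need_phenotype=False)
            cand_exprs[spec.name] = e
            bsets.append(concordance.coxen_distribution(
                initial.gene_ids, original_exprs[0], e, cfg.diagonal_mode))
        gate = concordance.gate_cancer_types(wsets, bsets, cfg.gate_alpha)
        suitable = gate.suitable_labels()
        log.info("step 2: gate — %d/%d candidates suitable", len(suitable), len(bsets))
        if suitable:
            # highest-median suitable candidate becomes the new cancer type
            by_label = {c.label: c for c in gate.candidates}
            best = max(suitable, key=lambda l: by_label[l].median_bcoxen)
            for spec in roles["candidate_coxen"]:
                lab = f"{original_exprs[0].system_label}~{spec.name}"
                if lab == best:
                    chosen_candidate = spec.name

    no_transfer = chosen_candidate is None

    # Step 3: three-way triage (falls back to two-way when no candidate
    # cancer type passed the gate).
    concordant = None
    threeway_fallback = False
    if chosen_candidate is not None:
        concordant = concordance.threeway_select(
            initial, cell_expr, original_exprs[0], cand_exprs[chosen_candidate],
            fdr=cfg.threeway_fdr, B=cfg.n_permutations, seed=cfg.seed,
            percentile=cfg.null_percentile, diagonal_mode=cfg.diagonal_mode,
            selection=cfg.coxen_selection)
        model_genes = list(concordant.gene_ids)
    else:
        res = concordance.coxen_null(
            cell_expr, original_exprs[0], initial.gene_ids,
            B=cfg.n_permutations, seed=cfg.seed, percentile=cfg.null_percentile,
            diagonal_mode=cfg.diagonal_mode)
        p = res.coefficients.p_values
        ok = np.isfinite(p)
        q = np.full_like(p, np.nan)
        q[ok] = discovery.bh_fdr(p[ok])
        model_genes = [g for g, qq in zip(res.coefficients.gene_ids, q)
                       if np.isfinite(qq) and qq < cfg.threeway_fdr]
        log.warning("no transferable cancer type; using two-way concordant "
                    "genes (%d) for modeling", len(model_genes))
    if len(model_genes) < cfg.min_model_genes:
        threeway_fallback = True
        ranked = sorted(initial.gene_ids,
                        key=lambda g: (-abs(initial.statistic_of(g)), g))
        model_genes = ranked[:cfg.min_model_genes]
        warnings.warn("fewer concordant biomarkers than the minimum model "
                      f"size; falling back to the top {len(model_genes)} "
                      "initial biomarkers")
    log.info("step 3: %d concordant biomarkers", len(model_genes))

    # Step 4: candidate models over the size grid, selection + threshold on
    # the original-type evaluation cohort.
    if concordant is not None and not threeway_fallback:
        grids = modeling.candidate_grid(concordant, initial,
                                        cfg.grid_start, cfg.grid_step)
    else:
        ranked = sorted(model_genes, key=lambda g: (-abs(initial.statistic_of(g)), g))
        sizes = sorted({m for m in list(range(cfg.grid_start, len(ranked), cfg.grid_step))
                        + [len(ranked)] if 2 <= m <= len(ranked)})
        grids = [ranked[:m] for m in sizes]
    candidates = [modeling.fit_pcr(cell_expr, act, g, cfg.variance_frac,
                                   drug_name=cfg.drug_name) for g in grids]
    selection = modeling.select_model(candidates, eval_expr, eval_pheno)
    model = selection.chosen.model
    threshold = selection.threshold
    log.info("step 4: chose %d-gene model, AUC %.3f, threshold %.3f",
             selection.chosen.n_genes, selection.chosen.auc, threshold)

    # Reference wCOXEN on the final model genes, for per-cohort re-checks.
    ref_w = min(
        (concordance.coxen_distribution(model.gene_ids, original_exprs[i],
                                        original_exprs[j], cfg.diagonal_mode)
         for i in range(len(original_exprs)) for j in range(i + 1, len(original_exprs))),
        key=lambda s: s.median)

    # Steps 5-6: prospective validation; only now are validation cohorts read.
    validations = {}
    for spec in roles["validation"]:
        expr, pheno = _load_cohort(spec, need_phenotype=True)
        validations[spec.name] = validation.validate_cohort(
            model, threshold, expr, pheno, reference_wcoxen=ref_w,
            reference_expr=original_exprs[0], gate_alpha=cfg.gate_alpha)
        log.info("validated %s: suitable=%s", spec.name,
                 validations[spec.name].suitable)

    return PipelineResult(cfg, initial, discovery_fallback, gate, chosen_candidate,
                          concordant, threeway_fallback, selection, model,
                          threshold, validations, cfg.seed,
                          no_transferable_type=no_transfer)


def summarize(result: PipelineResult) -> dict:
    """JSON-serializable run summary (counts through each filter, gate
    outcome, chosen model, per-cohort validation statistics)."""
    out: dict = {
        "seed": result.seed,
        "n_initial_biomarkers": len(result.biomarkers),
        "discovery_fallback": result.discovery_fallback,
        "no_transferable_type": result.no_transferable_type,
        "chosen_candidate": result.chosen_candidate,
        "n_model_genes": len(result.model.gene_ids),
        "threshold": result.threshold,
        "youden_j": result.selection.youden_j,
        "evaluation": {
            "auc": result.selection.chosen.auc,
            "p_value": result.selection.chosen.p_value,
        },
        "candidates": [
            {"n_genes": c.n_genes, "auc": c.auc, "p_value": c.p_value}
            for c in result.selection.candidates
        ],
        "validation": {},
    }
    if result.gate is not None:
        out["gate"] = {
            "reference_median": result.gate.reference_median,
            "candidates": [
                {"label": c.label, "median": c.median_bcoxen, "p_raw": c.p_raw,
                 "p_adjusted": c.p_adjusted, "suitable": c.suitable}
                for c in result.gate.candidates
            ],
        }
    if result.concordant is not None:
        out["n_concordant_biomarkers"] = len(result.concordant.gene_ids)
        out["per_pair_survivors"] = result.concordant.per_pair_survivors
    for name, rep in result.validations.items():
        entry: dict = {"suitable": rep.suitable, "note": rep.note}
        if rep.roc is not None:
            entry["auc"] = rep.roc.auc
            entry["auc_se"] = rep.roc.se
            entry["auc_ci95"] = list(rep.roc.ci95)
            entry["auc_p"] = rep.roc.p_value
        if rep.ppv is not None:
            entry["ppv"] = rep.ppv.ppv
            entry["baseline_rate"] = rep.ppv.baseline_rate
            entry["ppv_p"] = rep.ppv.p_value
        if rep.survival is not None:
            entry["logrank_statistic"] = rep.survival.statistic
            entry["logrank_p"] = rep.survival.p_value
        out["validation"][name] = entry
    return out


def config_hash(cfg: RunConfig) -> str:
    from dataclasses import asdict
    return hashlib.sha256(json.dumps(asdict(cfg), sort_keys=True).encode()).hexdigest()[:16]
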