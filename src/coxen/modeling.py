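"""Principal-component regression of drug activity on biomarker expression.

Models are trained on the cell-line panel: biomarker genes are standardized
by training means/SDs, the leading principal components (smallest number
explaining >= `variance_frac` of variance) are extracted, and drug activity
is regressed on the component scores by ordinary least squares.  Patient
cohorts are scored by standardizing within the cohort (the minimal
harmonization across microarray platforms), projecting onto the stored
loadings and applying the regression; raw scores are converted to in-cohort
percentile scores (1 = most sensitive).  The final model and its decision
threshold are selected once on the largest original-cancer cohort and then
frozen.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .concordance import ConcordBiomarkerSet
from .discovery import BiomarkerSet
from .matrix import DataError, DrugActivity, ExpressionMatrix, PhenotypeTable, zscore_genes


@dataclass
class PCRModel:
    """A frozen principal-component regression predictor.

    Stores everything needed to score new samples without the training
    data: the model genes, training standardization constants, orthonormal
    PC loadings (genes x k) and the OLS intercept/coefficients on the k
    component scores.
    """

    gene_ids: list[str]
    train_gene_means: np.ndarray
    train_gene_sds: np.ndarray
    pc_loadings: np.ndarray
    intercept: float
    coefficients: np.ndarray
    k: int
    drug_name: str = ""
    train_fitted: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        g = len(self.gene_ids)
        self.train_gene_means = np.asarray(self.train_gene_means, dtype=float)
        self.train_gene_sds = np.asarray(self.train_gene_sds, dtype=float)
        self.pc_loadings = np.asarray(self.pc_loadings, dtype=float)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.k < 1:
            raise DataError("need at least one principal component")
        if self.pc_loadings.shape != (g, self.k):
            raise DataError("loadings shape must be (genes, k)")
        if self.coefficients.shape != (self.k,):
            raise DataError("coefficient length must equal k")
        gram = self.pc_loadings.T @ self.pc_loadings
        if not np.allclose(gram, np.eye(self.k), atol=1e-8):
            raise DataError("loading columns must be orthonormal")

    def to_json(self, path=None) -> str:
        data = {
            "gene_ids": self.gene_ids,
            "train_gene_means": self.train_gene_means.tolist(),
            "train_gene_sds": self.train_gene_sds.tolist(),
            "pc_loadings": self.pc_loadings.tolist(),
            "intercept": self.intercept,
            "coefficients": self.coefficients.tolist(),
            "k": self.k,
            "drug_name": self.drug_name,
            "train_fitted": None if self.train_fitted is None else self.train_fitted.tolist(),
        }
        text = json.dumps(data, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "PCRModel":
        if isinstance(source, (str, Path)) and Path(str(source)).exists():
            data = json.loads(Path(source).read_text())
        else:
            data = json.loads(source)
        tf = data.get("train_fitted")
        return cls(
            data["gene_ids"], np.array(data["train_gene_means"]),
            np.array(data["train_gene_sds"]), np.array(data["pc_loadings"]),
            float(data["intercept"]), np.array(data["coefficients"]),
            int(data["k"]), data.get("drug_name", ""),
            None if tf is None else np.array(tf),
        )


@dataclass
class PatientScores:
    sample_ids: list[str]
    raw_score: np.ndarray
    percentile: np.ndarray
    predicted_class: Optional[np.ndarray] = None   # bool, positive = True

    def __post_init__(self) -> None:
        self.raw_score = np.asarray(self.raw_score, dtype=float)
        self.percentile = np.asarray(self.percentile, dtype=float)
        n = len(self.sample_ids)
        if self.raw_score.shape != (n,) or self.percentile.shape != (n,):
            raise DataError("score vectors must match sample_ids")
        if np.any((self.percentile <= 0) | (self.percentile > 1)):
            raise DataError("percentile scores must lie in (0, 1]")


@dataclass
class CandidateResult:
    n_genes: int
    gene_ids: list[str]
    model: PCRModel
    auc: float
    p_value: float


@dataclass
class ModelSelectionReport:
    candidates: list[CandidateResult]
    chosen: CandidateResult
    threshold: float
    youden_j: float
    selection_note: str = ""


def fit_pcr(cell_expr: ExpressionMatrix, act: DrugActivity, genes: Sequence[str],
            variance_frac: float = 0.8, drug_name: str = "") -> PCRModel:
    """Fit the PC regression of activity on the standardized expression of
    `genes` across the training cell lines."""
    genes = list(genes)
    if len(genes) < 2:
        raise DataError("need at least 2 model genes")
    sub = cell_expr.subset_genes(genes)
    if sub.n_samples < 4:
        raise DataError("need at least 4 training samples")
    act = act.reorder(sub.sample_ids)
    x = sub.values.T                                   # samples x genes
    means = x.mean(axis=0)
    sds = x.std(axis=0, ddof=1)
    flat = np.flatnonzero(sds == 0)
    if flat.size:
        raise DataError(f"constant training gene {genes[flat[0]]!r}")
    z = (x - means) / sds
    # PCA via SVD of the centered (already standardized) data matrix
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    var = s ** 2
    total = var.sum()
    frac = np.cumsum(var) / total if total > 0 else np.ones_like(var)
    k = int(np.searchsorted(frac, variance_frac - 1e-12) + 1)
    k = max(1, k)
    k_max = max(1, min(len(genes), sub.n_samples - 2))
    if k > k_max:
        warnings.warn(f"retained components clamped from {k} to {k_max}")
        k = k_max
    loadings = vt[:k].T                                # genes x k
    scores = z @ loadings
    design = np.column_stack([np.ones(len(scores)), scores])
    beta, *_ = np.linalg.lstsq(design, act.activity, rcond=None)
    fitted = design @ beta
    return PCRModel(genes, means, sds, loadings, float(beta[0]), beta[1:], k,
                    drug_name or act.drug_name, train_fitted=fitted)


def percentile_scores(raw: np.ndarray) -> np.ndarray:
    """Within-cohort percentile: average rank / n, so 1 = most sensitive."""
    return stats.rankdata(raw, method="average") / len(raw)


def score_cohort(model: PCRModel, cohort_expr: ExpressionMatrix) -> PatientScores:
    """Score a cohort: z-score its genes within the cohort, project on the
    stored loadings, apply the regression, then rank into percentiles.

    A single-patient cohort cannot be standardized against itself; it is
    standardized with the training constants instead and assigned
    percentile 1.0 with a warning.
    """
    missing = [g for g in model.gene_ids if g not in set(cohort_expr.gene_ids)]
    if missing:
        raise DataError(f"cohort lacks model genes: {missing}")
    sub = cohort_expr.subset_genes(model.gene_ids)
    if sub.n_samples == 1:
        warnings.warn("single-patient cohort: using training standardization, percentile 1.0")
        z = (sub.values.T - model.train_gene_means) / model.train_gene_sds
        raw = model.intercept + (z @ model.pc_loadings) @ model.coefficients
        return PatientScores(sub.sample_ids, raw, np.ones(1))
    z = zscore_genes(sub).values.T                     # samples x genes
    raw = model.intercept + (z @ model.pc_loadings) @ model.coefficients
    return PatientScores(sub.sample_ids, raw, percentile_scores(raw))


def candidate_grid(concord: ConcordBiomarkerSet, initial_ranking: BiomarkerSet,
                   grid_start: int = 4, grid_step: int = 4) -> list[list[str]]:
    """Nested top-m subsets of the concordant genes ranked by the absolute
    initial discovery statistic (ties broken lexicographically), for
    m = start, start+step, ... plus always the full set."""
    genes = list(concord.gene_ids)
    if not genes:
        raise DataError("empty concordant biomarker set")
    ranked = sorted(genes, key=lambda g: (-abs(initial_ranking.statistic_of(g)), g))
    n = len(ranked)
    sizes = [m for m in range(grid_start, n, grid_step)]
    if n >= 2:
        sizes.append(n)
    sizes = sorted({m for m in sizes if 2 <= m <= n})
    if not sizes:
        raise DataError("grid produces no usable subset (need >= 2 genes)")
    return [ranked[:m] for m in sizes]


def _youden_threshold(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Best percentile-score threshold by Youden's J (sensitivity +
    specificity - 1), with positive = score >= threshold.  Candidate
    thresholds are midpoints between consecutive distinct scores; ties on J
    go to the larger cut (higher specificity)."""
    distinct = np.unique(scores)
    if distinct.size < 2:
        raise DataError("all evaluation scores tied; no threshold exists")
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    pos = labels == 1
    neg = ~pos
    best_j, best_t = -np.inf, None
    for t in mids:
        pred = scores >= t
        sens = (pred & pos).sum() / pos.sum()
        spec = (~pred & neg).sum() / neg.sum()
        j = sens + spec - 1.0
        if j > best_j or (j == best_j and t > best_t):
            best_j, best_t = j, float(t)
    return best_t, float(best_j)


def _auc_and_p(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    res = stats.mannwhitneyu(pos, neg, alternative="greater", method="asymptotic")
    auc = res.statistic / (len(pos) * len(neg))
    return float(auc), float(res.pvalue)


def select_model(candidates: Sequence[PCRModel], eval_expr: ExpressionMatrix,
                 eval_response: PhenotypeTable,
                 alpha: float = 0.05) -> ModelSelectionReport:
    """Evaluate every candidate on the original-cancer evaluation cohort
    and fix the final model and threshold.

    Selection rule: among candidates significant at the Mann-Whitney level
    `alpha`, the highest AUC wins, ties broken toward fewer genes
    (parsimony); if none is significant, the max-AUC candidate is chosen
    with a warning note.  The decision threshold is then fixed on this
    cohort's percentile scores by maximizing Youden's J.
    """
    if not candidates:
        raise ValueError("no candidate models")
    pheno = eval_response.subset(eval_expr.sample_ids)
    if pheno.response is None:
        raise DataError("evaluation cohort lacks a response column")
    mask = ~np.isnan(pheno.response)
    labels = pheno.response[mask]
    if labels.sum() == 0 or labels.sum() == mask.sum():
        raise DataError("degenerate evaluation response: only one class present")
    results = []
    for m in candidates:
        sc = score_cohort(m, eval_expr)
        auc, p = _auc_and_p(sc.percentile[mask], labels)
        results.append(CandidateResult(len(m.gene_ids), list(m.gene_ids), m, auc, p))
    sig = [r for r in results if r.p_value < alpha]
    note = ""
    pool = sig
    if not sig:
        note = "no candidate significant at the evaluation alpha; max-AUC fallback"
        warnings.warn(note)
        pool = results
    chosen = min(pool, key=lambda r: (-r.auc, r.n_genes))
    sc = score_cohort(chosen.model, eval_expr)
    threshold, j = _youden_threshold(sc.percentile[mask], labels)
    return ModelSelectionReport(results, chosen, threshold, j, note)
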