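"""Prospective validation statistics for a frozen predictor.

Everything here takes the model and threshold as immutable inputs: AUC with
DeLong standard error and confidence interval, positive-predictive-value
enrichment against the cohort's unselected response rate (exact one-sided
binomial test), and Kaplan-Meier / log-rank survival stratification of the
predicted-positive versus predicted-negative groups.  Each cohort is first
re-checked for co-expression suitability (its bCOXEN on the final model
genes against the original cancer's wCOXEN); an unsuitable cohort is still
scored and reported, flagged that threshold-based stratification is not
expected to transfer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

from .concordance import (CoxenCoefficients, CoxenGateResult, coxen_distribution,
                          gate_cancer_types)
from .matrix import DataError, ExpressionMatrix, PhenotypeTable
from .modeling import PCRModel, PatientScores, score_cohort


@dataclass
class RocResult:
    auc: float
    se: float
    ci95: tuple[float, float]
    p_value: float
    n_pos: int
    n_neg: int
    sidedness: str = "one-sided (AUC > 0.5)"


@dataclass
class PpvResult:
    n_predicted_positive: int
    n_true_positive_within_predicted: int
    ppv: float
    baseline_rate: float
    p_value: float
    sidedness: str = "one-sided (PPV > baseline)"


@dataclass
class KMCurve:
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray


@dataclass
class SurvivalComparison:
    groups: tuple[str, str]
    curves: dict
    statistic: float
    p_value: float
    sidedness: str = "two-sided (chi-square, 1 df)"


@dataclass
class ValidationReport:
    cohort_label: str
    suitability: Optional[CoxenGateResult]
    suitable: Optional[bool]
    scores: PatientScores
    threshold: float
    roc: Optional[RocResult] = None
    ppv: Optional[PpvResult] = None
    survival: Optional[SurvivalComparison] = None
    note: str = ""


def _delong_variance(pos: np.ndarray, neg: np.ndarray) -> tuple[float, float]:
    """DeLong AUC and its variance via placement values."""
    m, n = len(pos), len(neg)
    allv = np.r_[pos, neg]
    rank_all = stats.rankdata(allv)
    rank_pos = stats.rankdata(pos)
    rank_neg = stats.rankdata(neg)
    # placements: fraction of the other class each observation beats
    v10 = (rank_all[:m] - rank_pos) / n          # per positive
    v01 = 1.0 - (rank_all[m:] - rank_neg) / m    # per negative
    auc = v10.mean()
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(auc), float(s10 / m + s01 / n)


def roc_auc(scores: Sequence[float], labels: Sequence[float]) -> RocResult:
    """AUC (ties count 1/2) with DeLong SE and 95% CI, and a one-sided
    Mann-Whitney-Wilcoxon p-value for AUC > 0.5."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise DataError("need at least one positive and one negative label")
    auc, var = _delong_variance(pos, neg)
    se = float(np.sqrt(var))
    z = stats.norm.ppf(0.975)
    ci = (max(0.0, auc - z * se), min(1.0, auc + z * se))
    p = float(stats.mannwhitneyu(pos, neg, alternative="greater",
                                 method="asymptotic").pvalue)
    return RocResult(auc, se, ci, p, len(pos), len(neg))


def stratify(scores: PatientScores, threshold: float) -> np.ndarray:
    """Predicted positive iff percentile score >= threshold (inclusive)."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie strictly in (0, 1)")
    return scores.percentile >= threshold


def ppv_test(predicted_pos_responses: Sequence[float], baseline_rate: float) -> PpvResult:
    """Exact one-sided binomial test: is the responder fraction among
    predicted positives higher than the cohort's unselected response rate?"""
    r = np.asarray(predicted_pos_responses, dtype=float)
    if len(r) == 0:
        raise DataError("no predicted responders")
    if not (0.0 < baseline_rate < 1.0):
        raise ValueError("baseline rate must lie in (0, 1)")
    if not np.all(np.isin(r, (0.0, 1.0))):
        raise DataError("responses must be binary")
    n = len(r)
    x = int(r.sum())
    res = stats.binomtest(x, n, baseline_rate, alternative="greater")
    return PpvResult(n, x, x / n, baseline_rate, float(res.pvalue))


def km_logrank(times: Sequence[float], events: Sequence[float],
               groups: Sequence[bool]) -> SurvivalComparison:
    """Kaplan-Meier curves per predicted group and the two-group log-rank
    test (chi-square, 1 df; standard hypergeometric variance under ties)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    groups = np.asarray(groups, dtype=bool)
    if groups.all() or (~groups).all():
        raise DataError("both predicted groups must be non-empty")
    if events.sum() == 0:
        raise DataError("no events observed")
    curves = {}
    for name, mask in (("positive", groups), ("negative", ~groups)):
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask])
        sf = kmf.survival_function_
        at_risk = kmf.event_table["at_risk"].to_numpy(dtype=float)
        curves[name] = KMCurve(sf.index.to_numpy(dtype=float),
                               sf.iloc[:, 0].to_numpy(dtype=float), at_risk)
    res = logrank_test(times[groups], times[~groups],
                       event_observed_A=events[groups],
                       event_observed_B=events[~groups])
    return SurvivalComparison(("positive", "negative"), curves,
                              float(res.test_statistic), float(res.p_value))


def validate_cohort(model: PCRModel, threshold: float, cohort_expr: ExpressionMatrix,
                    phenotype: PhenotypeTable,
                    reference_wcoxen: Optional[CoxenCoefficients] = None,
                    reference_expr: Optional[ExpressionMatrix] = None,
                    gate_alpha: float = 0.025) -> ValidationReport:
    """Full prospective validation of one cohort at the frozen threshold.

    Runs the suitability re-check (bCOXEN of the final model genes between
    this cohort and the original-cancer reference, compared to the
    reference wCOXEN), scores and stratifies every patient, then computes
    whichever statistics the phenotype supports.  The model and threshold
    are never modified.
    """
    if phenotype.response is None and phenotype.time is None:
        raise DataError("phenotype has no usable outcome columns")
    suitability = None
    suitable = None
    note = ""
    if reference_wcoxen is not None and reference_expr is not None:
        bcox = coxen_distribution(model.gene_ids, reference_expr, cohort_expr)
        suitability = gate_cancer_types([reference_wcoxen], [bcox], alpha=gate_alpha)
        suitable = suitability.candidates[0].suitable
        if not suitable:
            note = ("unsuitable — co-expression concordance with the original "
                    "cancer is significantly low; threshold-based "
                    "stratification not expected to transfer")
    scores = score_cohort(model, cohort_expr)
    pheno = phenotype.subset(scores.sample_ids)
    pred = stratify(scores, threshold)
    scores.predicted_class = pred
    roc = ppv = surv = None
    if pheno.response is not None:
        mask = ~np.isnan(pheno.response)
        labels = pheno.response[mask]
        if labels.sum() > 0 and labels.sum() < mask.sum():
            roc = roc_auc(scores.percentile[mask], labels)
            if (pred & mask).sum() > 0:
                baseline = float(labels.mean())
                if 0.0 < baseline < 1.0:
                    ppv = ppv_test(pheno.response[pred & mask], baseline)
    if pheno.time is not None and pheno.event is not None:
        mask = ~np.isnan(pheno.time) & ~np.isnan(pheno.event)
        if mask.sum() >= 2 and pred[mask].any() and (~pred[mask]).any() \
                and pheno.event[mask].sum() > 0:
            surv = km_logrank(pheno.time[mask], pheno.event[mask], pred[mask])
    return ValidationReport(cohort_expr.system_label, suitability, suitable,
                            scores, threshold, roc, ppv, surv, note)
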