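"""Screen a cell-line panel for genes whose expression tracks drug activity.

Two screening routes are exposed, mirroring how such panels are analysed in
practice: a Pearson correlation test of each gene against the activity
vector, or a Welch two-sample t-test contrasting highly sensitive versus
highly resistant lines (tertile cuts by default).  Multiplicity is handled
with Benjamini-Hochberg q-values, and when several panels carry activity
data for the drug, the most informative panel (largest number of
significant genes) is kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .matrix import DataError, DrugActivity, ExpressionMatrix


@dataclass
class BiomarkerRecord:
    gene_id: str
    statistic: float
    p_value: float
    q_value: float
    direction: int          # sign of association with sensitivity
    flagged: bool = False   # constant gene: p set to 1 rather than dropped


@dataclass
class BiomarkerSet:
    """Significant genes for one (panel, drug) pair, sorted by |statistic|
    descending; `full_table` keeps every screened gene for diagnostics and
    downstream ranking."""

    records: list[BiomarkerRecord]
    panel_label: str
    drug_name: str
    method: str
    full_table: list[BiomarkerRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.method not in ("ttest", "correlation"):
            raise ValueError(f"unknown screening method {self.method!r}")
        stats_abs = [abs(r.statistic) for r in self.records]
        if any(stats_abs[i] < stats_abs[i + 1] for i in range(len(stats_abs) - 1)):
            raise ValueError("records must be sorted by |statistic| descending")
        seen = set()
        for r in self.records:
            if r.gene_id in seen:
                raise ValueError(f"duplicate gene {r.gene_id!r} in biomarker set")
            seen.add(r.gene_id)

    @property
    def gene_ids(self) -> list[str]:
        return [r.gene_id for r in self.records]

    def statistic_of(self, gene: str) -> float:
        for r in self.full_table or self.records:
            if r.gene_id == gene:
                return r.statistic
        raise KeyError(gene)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class SensitivityClassing:
    cell_line_ids: list[str]
    labels: list[str]              # "sensitive" | "intermediate" | "resistant"
    lower_frac: float
    upper_frac: float

    def ids_in(self, cls: str) -> list[str]:
        return [c for c, l in zip(self.cell_line_ids, self.labels) if l == cls]


def classify_sensitivity(act: DrugActivity, lower_frac: float = 1 / 3,
                         upper_frac: float = 2 / 3) -> SensitivityClassing:
    """Split cell lines into resistant / intermediate / sensitive by empirical
    activity quantiles.  Ties on a cut go to the extreme class (a line whose
    activity reaches the upper quantile is sensitive; one at or below the
    lower quantile and not sensitive is resistant)."""
    if not (0 < lower_frac <= upper_frac < 1):
        raise ValueError("need 0 < lower_frac <= upper_frac < 1")
    a = act.activity
    if len(a) < 3:
        raise DataError("need at least 3 cell lines to classify")
    if np.ptp(a) == 0:
        raise DataError("all drug-activity values tied; cannot classify")
    lq = np.quantile(a, lower_frac)
    uq = np.quantile(a, upper_frac)
    labels = []
    for v in a:
        if v >= uq:
            labels.append("sensitive")
        elif v <= lq:
            labels.append("resistant")
        else:
            labels.append("intermediate")
    for cls in ("sensitive", "resistant"):
        if cls not in labels:
            raise DataError(f"{cls} class empty after quantile cuts")
    return SensitivityClassing(list(act.cell_line_ids), labels, lower_frac, upper_frac)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be a vector")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def _build_set(genes, statistic, p, flagged, fdr, panel_label, drug_name, method):
    q = bh_fdr(p)
    full = [
        BiomarkerRecord(g, float(s), float(pv), float(qv),
                        int(np.sign(s)) if s != 0 else 0, bool(f))
        for g, s, pv, qv, f in zip(genes, statistic, p, q, flagged)
    ]
    sig = [r for r in full if r.q_value < fdr and not r.flagged]
    sig.sort(key=lambda r: (-abs(r.statistic), r.gene_id))
    return BiomarkerSet(sig, panel_label, drug_name, method, full_table=full)


def discover_ttest(expr: ExpressionMatrix, classing: SensitivityClassing,
                   fdr: float = 0.05, drug_name: str = "") -> BiomarkerSet:
    """Welch t-test (sensitive minus resistant) per gene, BH-corrected.

    Genes constant within both classes get p = 1 and are flagged rather than
    dropped, so gene indexing stays stable downstream.
    """
    sens = [s for s in classing.ids_in("sensitive") if s in expr.sample_ids]
    res = [s for s in classing.ids_in("resistant") if s in expr.sample_ids]
    if len(sens) < 2 or len(res) < 2:
        raise DataError("need at least 2 cell lines per extreme class")
    xs = expr.values[:, expr_sample_index(expr, sens)]
    xr = expr.values[:, expr_sample_index(expr, res)]
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(xs, xr, axis=1, equal_var=False)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    flagged = ~np.isfinite(t) | ~np.isfinite(p)
    t[flagged] = 0.0
    p[flagged] = 1.0
    return _build_set(expr.gene_ids, t, p, flagged, fdr, expr.system_label,
                      drug_name, "ttest")


def discover_correlation(expr: ExpressionMatrix, act: DrugActivity,
                         fdr: float = 0.05, method: str = "pearson") -> BiomarkerSet:
    """Per-gene correlation of expression with drug activity, with the
    t-distributed two-sided test and BH correction."""
    if set(expr.sample_ids) != set(act.cell_line_ids):
        raise DataError("expression samples and activity cell lines differ")
    act = act.reorder(expr.sample_ids)
    y = act.activity
    n = len(y)
    if n < 4:
        raise DataError("need at least 4 cell lines for correlation screening")
    x = expr.values
    if method == "spearman":
        x = stats.rankdata(x, axis=1)
        y = stats.rankdata(y)
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt((xc ** 2).sum(axis=1))
    sy = np.sqrt((yc ** 2).sum())
    flagged = sx == 0
    sx_safe = np.where(flagged, 1.0, sx)
    r = (xc @ yc) / (sx_safe * sy)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isclose(np.abs(r), 1.0)] = 0.0
    r[flagged] = 0.0
    p[flagged] = 1.0
    return _build_set(expr.gene_ids, r, p, flagged, fdr, expr.system_label,
                      act.drug_name, "correlation")


def select_panel(candidate_sets: Sequence[BiomarkerSet]) -> BiomarkerSet:
    """Keep the panel yielding the most significant genes (ties broken by
    lexicographic panel label)."""
    if not candidate_sets:
        raise ValueError("no candidate panels given")
    if all(len(s) == 0 for s in candidate_sets):
        raise DataError("no informative panel: every candidate set is empty")
    return min(candidate_sets, key=lambda s: (-len(s), s.panel_label))


def expr_sample_index(expr: ExpressionMatrix, samples: Sequence[str]) -> np.ndarray:
    pos = {s: i for i, s in enumerate(expr.sample_ids)}
    return np.array([pos[s] for s in samples], dtype=int)
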