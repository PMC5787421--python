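"""Co-expression concordance between cancer systems.

The central quantity is the co-expression extrapolation (COXEN) coefficient
rc(j): build the gene-gene Pearson correlation matrix of a biomarker set
separately within two systems (U in one, V in the other); rc(j) is then the
Pearson correlation between column j of U and column j of V.  It measures
how well gene j's pattern of co-expression with the other biomarkers is
preserved across the two systems.

Significance is calibrated by permuting gene identities in one system,
which keeps each system's internal correlation structure while destroying
the cross-system correspondence.  Candidate cancer types are gated by
comparing the distribution of between-type coefficients (bCOXEN) against
the weakest within-type distribution (wCOXEN) with a one-sided Wilcoxon
rank-sum test, and biomarkers surviving the permutation test in all three
pairs (cell panel <-> original type, cell panel <-> new type, original <->
new type) form the concordant biomarker set carried into modeling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .discovery import BiomarkerSet, bh_fdr
from .matrix import DataError, ExpressionMatrix, align_by_common_genes


@dataclass
class CorrelationMatrix:
    """Pairwise gene-gene Pearson correlations within one system."""

    gene_ids: list[str]
    values: np.ndarray
    source_label: str = ""

    def __post_init__(self) -> None:
        n = len(self.gene_ids)
        self.values = np.asarray(self.values, dtype=float)
        if n < 2:
            raise DataError("correlation matrix needs at least 2 genes")
        if self.values.shape != (n, n):
            raise DataError("correlation matrix shape mismatch")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise DataError("correlation matrix not symmetric")
        if not np.allclose(np.diag(self.values), 1.0, atol=1e-12):
            raise DataError("correlation matrix diagonal must be 1")
        if np.any(np.abs(self.values) > 1 + 1e-12):
            raise DataError("correlation entries must lie in [-1, 1]")


@dataclass
class CoxenCoefficients:
    """Per-gene rc values for one pair of systems; NaN marks a gene whose
    coefficient is undefined (zero-variance correlation column)."""

    gene_ids: list[str]
    rc: np.ndarray
    pair_label: str = ""
    diagonal_mode: str = "excluded"
    p_values: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.rc = np.asarray(self.rc, dtype=float)
        if self.rc.shape != (len(self.gene_ids),):
            raise DataError("rc length does not match gene_ids")
        finite = self.rc[np.isfinite(self.rc)]
        if np.any(np.abs(finite) > 1 + 1e-12):
            raise DataError("|rc| must not exceed 1")
        if self.diagonal_mode not in ("included", "excluded"):
            raise DataError(f"unknown diagonal mode {self.diagonal_mode!r}")

    def finite_rc(self) -> np.ndarray:
        return self.rc[np.isfinite(self.rc)]

    @property
    def median(self) -> float:
        return float(np.median(self.finite_rc()))


@dataclass
class GateCandidate:
    label: str
    median_bcoxen: float
    p_raw: float
    p_adjusted: float
    suitable: bool


@dataclass
class CoxenGateResult:
    """Outcome of the wCOXEN/bCOXEN comparison, sorted by raw p ascending."""

    reference_label: str
    reference_median: float
    alpha: float
    candidates: list[GateCandidate]

    def suitable_labels(self) -> list[str]:
        return [c.label for c in self.candidates if c.suitable]


@dataclass
class ConcordBiomarkerSet:
    """Genes surviving the permutation test in all three system pairs."""

    gene_ids: list[str]
    pair_labels: list[str]
    per_pair_q: dict                      # pair label -> {gene: q}
    per_pair_survivors: dict              # pair label -> survivor count
    initial_gene_ids: list[str]
    warning: Optional[str] = None

    def __post_init__(self) -> None:
        if not set(self.gene_ids) <= set(self.initial_gene_ids):
            raise DataError("concordant genes must be a subset of the initial set")


def gene_correlation_matrix(expr: ExpressionMatrix, genes: Sequence[str]) -> CorrelationMatrix:
    """Pearson correlation of every gene pair among `genes` within `expr`."""
    sub = expr.subset_genes(list(genes))
    if sub.n_samples < 3:
        raise DataError("need at least 3 samples for gene-gene correlations")
    sd = sub.values.std(axis=1)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        raise DataError(f"constant gene {sub.gene_ids[flat[0]]!r} in correlation matrix")
    c = np.corrcoef(sub.values)
    c = np.clip((c + c.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    return CorrelationMatrix(sub.gene_ids, c, expr.system_label)


def _rc_from_values(u: np.ndarray, v: np.ndarray, diagonal_mode: str) -> np.ndarray:
    """Columnwise correlation between two square matrices; in ``excluded``
    mode the diagonal entry of each column (the gene's self-pair) is left
    out of the sum."""
    n = u.shape[0]
    if diagonal_mode == "included":
        m = float(n)
        su, sv = u.sum(axis=0), v.sum(axis=0)
        suv = (u * v).sum(axis=0)
        suu = (u * u).sum(axis=0)
        svv = (v * v).sum(axis=0)
    else:
        m = float(n - 1)
        du, dv = np.diag(u), np.diag(v)
        su, sv = u.sum(axis=0) - du, v.sum(axis=0) - dv
        suv = (u * v).sum(axis=0) - du * dv
        suu = (u * u).sum(axis=0) - du ** 2
        svv = (v * v).sum(axis=0) - dv ** 2
    cov = suv - su * sv / m
    varu = suu - su ** 2 / m
    varv = svv - sv ** 2 / m
    # guard against catastrophic cancellation for (near-)constant columns
    tol = 1e-10 * m
    with np.errstate(divide="ignore", invalid="ignore"):
        rc = cov / np.sqrt(varu * varv)
    rc = np.where((varu <= tol) | (varv <= tol), np.nan, rc)
    return np.clip(rc, -1.0, 1.0)


def coxen_coefficients(U: CorrelationMatrix, V: CorrelationMatrix,
                       diagonal_mode: str = "excluded") -> CoxenCoefficients:
    """rc(j) = correlation between column j of U and column j of V.

    ``included`` sums over all n partners (the formula as printed, where the
    j-th entry is the constant (1, 1) self-pair); ``excluded`` (default)
    drops the self-pair, which restores the exact anti-concordance identity
    rc = -1 when V's off-diagonal is the negation of U's.
    """
    if U.gene_ids != V.gene_ids:
        raise DataError("U and V must share identical gene ids in identical order")
    if len(U.gene_ids) < 3:
        raise DataError("need at least 3 genes for rc")
    rc = _rc_from_values(U.values, V.values, diagonal_mode)
    label = f"{U.source_label}~{V.source_label}"
    return CoxenCoefficients(list(U.gene_ids), rc, label, diagonal_mode)


def coxen_distribution(biomarkers: Sequence[str], cohortA: ExpressionMatrix,
                       cohortB: ExpressionMatrix,
                       diagonal_mode: str = "excluded") -> CoxenCoefficients:
    """Align the cohorts on the biomarkers, build the two correlation
    matrices and return the rc vector for the pair."""
    a, b = align_by_common_genes(cohortA, cohortB, biomarkers)
    U = gene_correlation_matrix(a, a.gene_ids)
    V = gene_correlation_matrix(b, b.gene_ids)
    return coxen_coefficients(U, V, diagonal_mode)


@dataclass
class CoxenNullResult:
    coefficients: CoxenCoefficients       # with p_values filled in
    cutoff: float                         # percentile of pooled |null|
    percentile: float
    n_permutations: int


def coxen_null(exprA: ExpressionMatrix, exprB: ExpressionMatrix,
               genes: Sequence[str], B: int = 500, seed: int = 0,
               percentile: float = 98.0, diagonal_mode: str = "excluded",
               pooled: bool = True,
               rng: Optional[np.random.Generator] = None) -> CoxenNullResult:
    """Permutation null for rc: gene identities in system B are shuffled
    (rows and columns of V permuted jointly) B times, preserving each
    system's internal correlation structure while destroying the
    cross-system gene correspondence.

    Per-gene two-sided p-values use the pooled |null| across genes by
    default (add-one smoothed); ``pooled=False`` compares each gene only to
    its own B null draws.  The cut-off is the configured percentile of the
    pooled |null| distribution.
    """
    if B < 100:
        raise ValueError("null too coarse: need B >= 100 permutations")
    a, b = align_by_common_genes(exprA, exprB, genes)
    U = gene_correlation_matrix(a, a.gene_ids)
    V = gene_correlation_matrix(b, b.gene_ids)
    obs = coxen_coefficients(U, V, diagonal_mode)
    n = len(obs.gene_ids)
    if rng is None:
        rng = np.random.default_rng(seed)
    null = np.empty((B, n))
    v = V.values
    for bi in range(B):
        perm = rng.permutation(n)
        w = v[np.ix_(perm, perm)]
        null[bi] = _rc_from_values(U.values, w, diagonal_mode)
    abs_null = np.abs(null)
    abs_obs = np.abs(obs.rc)
    pooled_null = abs_null[np.isfinite(abs_null)]
    if pooled:
        exceed = (pooled_null[None, :] >= abs_obs[:, None]).sum(axis=1)
        p = (1.0 + exceed) / (1.0 + pooled_null.size)
    else:
        exceed = np.nansum(abs_null >= abs_obs[None, :], axis=0)
        p = (1.0 + exceed) / (1.0 + B)
    p = np.where(np.isfinite(abs_obs), p, np.nan)
    cutoff = float(np.percentile(pooled_null, percentile))
    coeffs = CoxenCoefficients(obs.gene_ids, obs.rc, obs.pair_label,
                               diagonal_mode, p_values=p)
    return CoxenNullResult(coeffs, cutoff, percentile, B)


def _rank_sum_p_less(x: np.ndarray, y: np.ndarray) -> float:
    """One-sided Wilcoxon rank-sum p for H1: x is stochastically smaller
    than y.  Exact enumeration when both groups are small and tie-free,
    tie-corrected normal approximation otherwise."""
    exact = len(x) <= 8 and len(y) <= 8 and len(np.unique(np.r_[x, y])) == len(x) + len(y)
    res = stats.mannwhitneyu(x, y, alternative="less",
                             method="exact" if exact else "asymptotic")
    return float(res.pvalue)


def gate_cancer_types(wcoxen_sets: Sequence[CoxenCoefficients],
                      bcoxen_sets: Sequence[CoxenCoefficients],
                      alpha: float = 0.025) -> CoxenGateResult:
    """Gate candidate cancer types: the reference is the within-type rc set
    with the lowest median; each candidate's rc set is tested one-sided for
    being lower, Bonferroni-adjusted over candidates, and a candidate is
    suitable iff its adjusted p exceeds alpha (i.e. not significantly worse
    than the weakest within-type concordance)."""
    if not wcoxen_sets or not bcoxen_sets:
        raise ValueError("need at least one wCOXEN and one bCOXEN set")
    for s in list(wcoxen_sets) + list(bcoxen_sets):
        if s.finite_rc().size == 0:
            raise DataError(f"empty coefficient vector for {s.pair_label!r}")
    ref = min(wcoxen_sets, key=lambda s: s.median)
    k = len(bcoxen_sets)
    cands = []
    for s in bcoxen_sets:
        p = _rank_sum_p_less(s.finite_rc(), ref.finite_rc())
        p_adj = min(1.0, p * k)
        cands.append(GateCandidate(s.pair_label, s.median, p, p_adj, p_adj > alpha))
    cands.sort(key=lambda c: c.p_raw)
    return CoxenGateResult(ref.pair_label, ref.median, alpha, cands)


def threeway_select(initial: BiomarkerSet, cell_expr: ExpressionMatrix,
                    cohortA_expr: ExpressionMatrix, cohortB_expr: ExpressionMatrix,
                    fdr: float = 0.2, B: int = 500, seed: int = 0,
                    percentile: float = 98.0, diagonal_mode: str = "excluded",
                    selection: str = "pvalue_bh") -> ConcordBiomarkerSet:
    """Intersect the three pairwise concordance analyses (cell panel vs
    original cancer, cell panel vs new cancer, original vs new) on the
    initial biomarker set; a gene survives only if significant in all three.

    ``pvalue_bh`` (default) applies BH at `fdr` to the permutation
    p-values within each pair; ``percentile_cut`` keeps genes whose |rc|
    exceeds the pooled-null percentile cut-off directly.
    """
    genes = sorted(set(initial.gene_ids) & set(cell_expr.gene_ids)
                   & set(cohortA_expr.gene_ids) & set(cohortB_expr.gene_ids))
    if len(genes) < 3:
        raise DataError("fewer than 3 initial biomarkers shared by all three systems")
    pairs = [(cell_expr, cohortA_expr), (cell_expr, cohortB_expr),
             (cohortA_expr, cohortB_expr)]
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(3)]
    per_pair_q: dict[str, dict[str, float]] = {}
    survivors_by_pair: dict[str, set[str]] = {}
    labels = []
    for (ea, eb), s in zip(pairs, child_seeds):
        res = coxen_null(ea, eb, genes, B=B, seed=s, percentile=percentile,
                         diagonal_mode=diagonal_mode)
        lab = res.coefficients.pair_label
        labels.append(lab)
        p = res.coefficients.p_values
        ok = np.isfinite(p)
        q = np.full_like(p, np.nan)
        q[ok] = bh_fdr(p[ok])
        per_pair_q[lab] = dict(zip(res.coefficients.gene_ids, q))
        if selection == "pvalue_bh":
            keep = {g for g, qq in zip(res.coefficients.gene_ids, q)
                    if np.isfinite(qq) and qq < fdr}
        elif selection == "percentile_cut":
            keep = {g for g, r in zip(res.coefficients.gene_ids, res.coefficients.rc)
                    if np.isfinite(r) and abs(r) >= res.cutoff}
        else:
            raise ValueError(f"unknown selection rule {selection!r}")
        survivors_by_pair[lab] = keep
    inter = set(genes)
    for keep in survivors_by_pair.values():
        inter &= keep
    surviving = sorted(inter)
    warning = None
    if len(surviving) < 3:
        warning = (f"only {len(surviving)} biomarkers survived all three pairwise "
                   f"concordance tests at FDR {fdr}")
    return ConcordBiomarkerSet(
        surviving, labels, per_pair_q,
        {lab: len(keep) for lab, keep in survivors_by_pair.items()},
        list(genes), warning,
    )
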