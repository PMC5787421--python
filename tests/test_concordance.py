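"""Co-expression concordance: rc against brute-force column oracles, the
permutation null, the wCOXEN/bCOXEN gate against exact rank-sum
enumeration, and three-way triage semantics."""

import itertools

import numpy as np
import pytest

from coxen import (CoxenCoefficients, DataError, coxen_coefficients,
                   coxen_distribution, coxen_null, gate_cancer_types,
                   gene_correlation_matrix, threeway_select)
from coxen.concordance import CorrelationMatrix, _rc_from_values
from conftest import make_expr


def random_corr(rng, n):
    """A valid correlation matrix from random data (so it is PSD)."""
    x = rng.standard_normal((n, n + 5))
    c = np.corrcoef(x)
    np.fill_diagonal(c, 1.0)
    return CorrelationMatrix([f"G{i}" for i in range(n)], c)


def rc_oracle(u, v, mode):
    """Materialize each column pair and call a scalar correlation."""
    n = u.shape[0]
    out = np.empty(n)
    for j in range(n):
        idx = np.arange(n) if mode == "included" else np.r_[0:j, j + 1:n]
        x, y = u[idx, j], v[idx, j]
        if x.std() == 0 or y.std() == 0:
            out[j] = np.nan
        else:
            out[j] = np.corrcoef(x, y)[0, 1]
    return out


class TestCorrelationMatrix:
    def test_identical_and_negated_rows(self, rng):
        base = rng.standard_normal(20)
        x = np.vstack([base, base, -base, rng.standard_normal(20)])
        m = gene_correlation_matrix(make_expr(x), [f"G{i}" for i in range(4)])
        assert m.values[0, 1] == pytest.approx(1.0)
        assert m.values[0, 2] == pytest.approx(-1.0)

    def test_matches_double_loop_oracle(self, rng):
        x = rng.standard_normal((6, 20))
        m = gene_correlation_matrix(make_expr(x), [f"G{i}" for i in range(6)])
        for i in range(6):
            for j in range(6):
                expect = np.corrcoef(x[i], x[j])[0, 1]
                assert m.values[i, j] == pytest.approx(expect, abs=1e-12)

    def test_constant_gene_named(self, rng):
        x = rng.standard_normal((3, 10))
        x[1] = 2.0
        with pytest.raises(DataError, match="G1"):
            gene_correlation_matrix(make_expr(x), ["G0", "G1", "G2"])


class TestCoxenCoefficients:
    @pytest.mark.parametrize("mode", ["included", "excluded"])
    def test_self_concordance_is_one(self, rng, mode):
        U = random_corr(rng, 7)
        rc = coxen_coefficients(U, U, mode).rc
        np.testing.assert_allclose(rc, 1.0, atol=1e-10)

    def test_excluded_anti_concordance_is_minus_one(self, rng):
        U = random_corr(rng, 6)
        v = -U.values.copy()
        np.fill_diagonal(v, 1.0)
        V = CorrelationMatrix(U.gene_ids, v)
        rc = coxen_coefficients(U, V, "excluded").rc
        np.testing.assert_allclose(rc, -1.0, atol=1e-10)

    @pytest.mark.parametrize("mode", ["included", "excluded"])
    def test_matches_column_oracle(self, rng, mode):
        U, V = random_corr(rng, 8), random_corr(rng, 8)
        rc = coxen_coefficients(U, V, mode).rc
        np.testing.assert_allclose(rc, rc_oracle(U.values, V.values, mode),
                                   atol=1e-12)

    def test_gene_order_mismatch_rejected(self, rng):
        U = random_corr(rng, 5)
        V = CorrelationMatrix(list(reversed(U.gene_ids)), U.values)
        with pytest.raises(DataError, match="identical gene ids"):
            coxen_coefficients(U, V)

    def test_invariant_under_joint_gene_permutation(self, rng):
        U, V = random_corr(rng, 9), random_corr(rng, 9)
        rc = coxen_coefficients(U, V).rc
        perm = rng.permutation(9)
        Up = CorrelationMatrix([U.gene_ids[i] for i in perm],
                               U.values[np.ix_(perm, perm)])
        Vp = CorrelationMatrix([V.gene_ids[i] for i in perm],
                               V.values[np.ix_(perm, perm)])
        np.testing.assert_allclose(coxen_coefficients(Up, Vp).rc, rc[perm],
                                   atol=1e-12)

    def test_zero_variance_column_flagged_nan(self):
        # a column whose off-diagonal entries are all equal has no variance
        n = 4
        u = np.full((n, n), 0.3)
        np.fill_diagonal(u, 1.0)
        rng = np.random.default_rng(3)
        V = random_corr(rng, n)
        rc = _rc_from_values(u, V.values, "excluded")
        assert np.isnan(rc).all()   # every column of u is constant off-diagonal


class TestCoxenDistribution:
    def test_identical_cohorts_give_one(self, rng):
        a = make_expr(rng.standard_normal((6, 15)), label="A")
        rc = coxen_distribution(a.gene_ids, a, a).rc
        np.testing.assert_allclose(rc, 1.0, atol=1e-10)

    def test_sample_order_irrelevant(self, rng):
        a = make_expr(rng.standard_normal((6, 15)), label="A")
        perm = rng.permutation(15)
        b = make_expr(a.values[:, perm], label="B")
        rc1 = coxen_distribution(a.gene_ids, a, b).rc
        np.testing.assert_allclose(rc1, 1.0, atol=1e-10)

    def test_shared_factor_genes_have_higher_rc(self, default_dataset):
        ds = default_dataset
        conc = ds.genes_of_class("concordant")
        null = ds.genes_of_class("null")
        rc = coxen_distribution(conc + null,
                                ds.cohorts["original_coxen"].expression,
                                ds.cohorts["new_coxen"].expression)
        vals = dict(zip(rc.gene_ids, rc.rc))
        mean_conc = np.mean([vals[g] for g in conc])
        mean_null = np.mean([vals[g] for g in null])
        assert mean_conc > mean_null + 0.3


class TestCoxenNull:
    def test_determinism(self, rng):
        a = make_expr(rng.standard_normal((10, 20)), label="A")
        b = make_expr(rng.standard_normal((10, 20)), label="B")
        r1 = coxen_null(a, b, a.gene_ids, B=100, seed=42)
        r2 = coxen_null(a, b, a.gene_ids, B=100, seed=42)
        np.testing.assert_array_equal(r1.coefficients.p_values,
                                      r2.coefficients.p_values)
        assert r1.cutoff == r2.cutoff

    def test_too_few_permutations_rejected(self, rng):
        a = make_expr(rng.standard_normal((5, 12)), label="A")
        with pytest.raises(ValueError, match="too coarse"):
            coxen_null(a, a, a.gene_ids, B=50)

    def test_null_calibration_quick(self):
        """Independent systems: ~2% of genes beyond the 98th-percentile
        cut-off (small version; the full-size check lives in the
        acceptance suite)."""
        flags = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            a = make_expr(rng.standard_normal((30, 40)), label="A")
            b = make_expr(rng.standard_normal((30, 40)), label="B")
            res = coxen_null(a, b, a.gene_ids, B=200, seed=seed)
            flags.append(np.mean(np.abs(res.coefficients.rc) > res.cutoff))
        mc_se = np.std(flags) / np.sqrt(len(flags))
        assert abs(np.mean(flags) - 0.02) <= 3 * mc_se + 0.005

    def test_planted_structure_detected(self):
        """Genes sharing a cross-system factor get smaller p than nulls."""
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            loads = np.r_[np.ones(15), np.zeros(15)] * rng.choice([-1, 1], 30)
            def system(n):
                f = rng.standard_normal(n)
                return make_expr(loads[:, None] * f + rng.standard_normal((30, n)),
                                 label=f"sys{n}")
            a, b = system(40), system(41)
            res = coxen_null(a, b, a.gene_ids, B=200, seed=seed)
            p = dict(zip(res.coefficients.gene_ids, res.coefficients.p_values))
            planted = np.median([p[f"G{i}"] for i in range(15)])
            nulls = np.median([p[f"G{i}"] for i in range(15, 30)])
            wins += planted < nulls
        assert wins >= 19


def exact_ranksum_p_less(x, y):
    """Exact one-sided rank-sum p (H1: x lower) by full enumeration of the
    U-statistic distribution over all group assignments."""
    pooled = np.r_[x, y]
    n, m = len(x), len(y)
    u_obs = sum(1 for xi in x for yj in y if xi > yj)
    count = total = 0
    for comb in itertools.combinations(range(n + m), n):
        xs = pooled[list(comb)]
        ys = pooled[[i for i in range(n + m) if i not in comb]]
        u = sum(1 for xi in xs for yj in ys if xi > yj)
        count += u <= u_obs
        total += 1
    return count / total


class TestGate:
    def _coeffs(self, vals, label):
        return CoxenCoefficients([f"G{i}" for i in range(len(vals))],
                                 np.asarray(vals, dtype=float), label)

    def test_dominating_candidate_suitable(self, rng):
        ref = self._coeffs(rng.uniform(0.2, 0.5, 12), "w")
        cand = self._coeffs(rng.uniform(0.6, 0.9, 12), "b")
        res = gate_cancer_types([ref], [cand])
        assert res.candidates[0].p_raw > 0.9
        assert res.candidates[0].suitable

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exact_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        ref_vals = rng.uniform(-1, 1, 7)
        cand_vals = rng.uniform(-0.8, 0.8, 6) - rng.uniform(0, 0.2)
        res = gate_cancer_types([self._coeffs(ref_vals, "w")],
                                [self._coeffs(cand_vals, "b")])
        expect = exact_ranksum_p_less(cand_vals, ref_vals)
        assert res.candidates[0].p_raw == pytest.approx(expect, abs=1e-12)

    def test_shifted_down_candidate_unsuitable(self, rng):
        ref = self._coeffs(rng.uniform(0.4, 0.9, 8), "w")
        cand = self._coeffs(ref.rc - 1.2, "b")
        res = gate_cancer_types([ref], [cand])
        assert not res.candidates[0].suitable
        assert res.candidates[0].p_raw < 0.001

    def test_bonferroni_arithmetic(self, rng):
        ref = self._coeffs(rng.uniform(0.4, 0.6, 20), "w")
        cands = [self._coeffs(rng.uniform(0.3, 0.6, 20), f"b{i}") for i in range(3)]
        res = gate_cancer_types([ref], cands, alpha=0.025)
        for c in res.candidates:
            assert c.p_adjusted == pytest.approx(min(1.0, 3 * c.p_raw))
            assert c.suitable == (c.p_adjusted > 0.025)

    def test_reference_is_lowest_median(self, rng):
        w1 = self._coeffs(rng.uniform(0.5, 0.9, 15), "w1")
        w2 = self._coeffs(rng.uniform(0.1, 0.4, 15), "w2")
        res = gate_cancer_types([w1, w2], [self._coeffs(rng.random(15), "b")])
        assert res.reference_label == "w2"

    def test_candidates_tested_independently(self, rng):
        """Adding a dominating candidate changes only the Bonferroni factor,
        never another candidate's raw p."""
        ref = self._coeffs(rng.uniform(0.3, 0.7, 15), "w")
        c1 = self._coeffs(rng.uniform(0.2, 0.6, 15), "b1")
        solo = gate_cancer_types([ref], [c1])
        dom = self._coeffs(np.full(15, 0.99), "b2")
        both = gate_cancer_types([ref], [c1, dom])
        p1 = {c.label: c.p_raw for c in both.candidates}["b1"]
        assert p1 == pytest.approx(solo.candidates[0].p_raw, abs=1e-14)

    def test_empty_vector_rejected(self):
        good = self._coeffs([0.5, 0.4, 0.3], "w")
        bad = CoxenCoefficients(["G0"], np.array([np.nan]), "b")
        with pytest.raises(DataError, match="empty"):
            gate_cancer_types([good], [bad])


class TestThreeway:
    def test_survivors_subset_and_bounded(self, default_dataset):
        ds = default_dataset
        from coxen import discover_correlation
        bm = discover_correlation(ds.cell_expression, ds.drug_activity, 0.05)
        tw = threeway_select(bm, ds.cell_expression,
                             ds.cohorts["original_coxen"].expression,
                             ds.cohorts["new_coxen"].expression, seed=5)
        assert set(tw.gene_ids) <= set(bm.gene_ids)
        assert len(tw.gene_ids) <= min(tw.per_pair_survivors.values())
        assert len(tw.pair_labels) == 3

    def test_planted_genes_retained_pairwise_dropped(self, default_dataset):
        ds = default_dataset
        from coxen import discover_correlation
        bm = discover_correlation(ds.cell_expression, ds.drug_activity, 0.05)
        tw = threeway_select(bm, ds.cell_expression,
                             ds.cohorts["original_coxen"].expression,
                             ds.cohorts["new_coxen"].expression, seed=5)
        got = set(tw.gene_ids)
        conc = set(ds.genes_of_class("concordant")) & set(bm.gene_ids)
        pair = set(ds.genes_of_class("pairwise_only")) & set(bm.gene_ids)
        assert len(got & conc) / len(conc) >= 0.8
        assert len(got & pair) / len(pair) <= 0.35

    def test_intersection_semantics(self, default_dataset):
        """A gene passing only two pairs is dropped."""
        ds = default_dataset
        from coxen import discover_correlation
        bm = discover_correlation(ds.cell_expression, ds.drug_activity, 0.05)
        tw = threeway_select(bm, ds.cell_expression,
                             ds.cohorts["original_coxen"].expression,
                             ds.cohorts["new_coxen"].expression, seed=5,
                             fdr=0.2)
        survivors = {lab: set() for lab in tw.pair_labels}
        for lab in tw.pair_labels:
            survivors[lab] = {g for g, q in tw.per_pair_q[lab].items()
                              if np.isfinite(q) and q < 0.2}
        expect = set(tw.initial_gene_ids)
        for s in survivors.values():
            expect &= s
        assert set(tw.gene_ids) == expect

    def test_warning_when_few_survive(self, rng):
        from coxen import discover_correlation, DrugActivity
        x = rng.standard_normal((12, 30))
        expr = make_expr(x, label="cell")
        act = DrugActivity(expr.sample_ids, rng.standard_normal(30))
        bm = discover_correlation(expr, act, fdr=1.1)
        full = sorted(bm.full_table, key=lambda r: (-abs(r.statistic), r.gene_id))
        from coxen.discovery import BiomarkerSet
        allset = BiomarkerSet(full, "cell", "d", "correlation", full_table=full)
        a = make_expr(rng.standard_normal((12, 25)), label="A")
        b = make_expr(rng.standard_normal((12, 25)), label="B")
        tw = threeway_select(allset, expr, a, b, seed=1, B=150)
        if len(tw.gene_ids) < 3:
            assert tw.warning is not None
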