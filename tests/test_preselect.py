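"""Screening statistics: size factors, NB Wald test, BH, rank tests, chi-square."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gutpheno.cohort import QualVar, QuantVar, generate_cohort
from gutpheno.preselect import (
    bh_adjust,
    chi_square_test,
    kruskal_wallis,
    mann_whitney_u,
    nb_wald_da,
    posthoc_vs_control,
    select_candidates,
    shapiro_normality,
    size_factors,
)

from conftest import make_counts, small_spec


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        counts = make_counts([[5, 3, 9], [5, 3, 9]])
        sf = size_factors(counts)
        np.testing.assert_allclose(sf.to_numpy(), [1.0, 1.0])

    def test_doubled_sample_has_double_factor(self):
        a = np.array([4, 10, 6, 2])
        counts = make_counts([a, 2 * a])
        sf = size_factors(counts)
        assert sf.iloc[1] / sf.iloc[0] == pytest.approx(2.0)
        assert np.exp(np.mean(np.log(sf))) == pytest.approx(1.0)

    def test_matches_brute_force_median_of_ratios(self):
        x = np.array([[3, 7, 2, 11], [6, 2, 9, 4], [1, 5, 8, 12]], dtype=float)
        counts = make_counts(x)
        # independent oracle: literal median-of-ratios over all-positive taxa
        geo = np.exp(np.log(x).mean(axis=0))
        raw = np.array([np.median(x[j] / geo) for j in range(3)])
        expected = raw / np.exp(np.mean(np.log(raw)))
        np.testing.assert_allclose(size_factors(counts).to_numpy(), expected)

    def test_fallback_when_no_taxon_is_everywhere_nonzero(self):
        counts = make_counts([[0, 8, 4], [6, 0, 4], [6, 8, 0]])
        sf = size_factors(counts)
        assert (sf > 0).all()

    def test_all_zero_table_errors(self):
        with pytest.raises(ValueError):
            size_factors(make_counts(np.zeros((3, 4), dtype=int)))


class TestBHAdjust:
    def test_single_p_is_identity(self):
        np.testing.assert_allclose(bh_adjust([0.03]), [0.03])

    def test_hand_step_up_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
    def test_equals_brute_force_min_over_suffix(self, pvals):
        p = np.asarray(pvals)
        m = p.size
        order = np.argsort(p, kind="mergesort")
        # oracle: q_(i) = min over j >= i of (m/j) p_(j), straight from the definition
        expected = np.empty(m)
        for rank_i, idx in enumerate(order, start=1):
            candidates = [
                m / rank_j * p[order[rank_j - 1]] for rank_j in range(rank_i, m + 1)
            ]
            expected[idx] = min(1.0, min(candidates))
        np.testing.assert_allclose(bh_adjust(p), expected, atol=1e-12)
        assert (bh_adjust(p) >= p - 1e-15).all()


class TestNBWald:
    def test_identical_groups_give_zero_lfc_and_p_one(self):
        block = np.array([[10, 4, 7], [3, 9, 5], [8, 2, 6], [5, 5, 5]])
        counts = make_counts(np.vstack([block, block]))
        labels = pd.Series(["case"] * 4 + ["ctrl"] * 4, index=counts.index)
        res = nb_wald_da(counts, labels, "case", "ctrl", min_prevalence=0.0)
        np.testing.assert_allclose(res.table["log2_fc"], 0.0, atol=1e-12)
        np.testing.assert_allclose(res.table["pvalue"], 1.0, atol=1e-12)

    def test_all_zero_group_yields_sentinel_excluded_from_bh(self):
        case = np.array([[50, 0, 10], [40, 0, 12], [60, 0, 9]])
        ctrl = np.array([[45, 30, 11], [55, 25, 10], [50, 28, 12]])
        counts = make_counts(np.vstack([case, ctrl]))
        labels = pd.Series(["case"] * 3 + ["ctrl"] * 3, index=counts.index)
        res = nb_wald_da(counts, labels, "case", "ctrl", min_prevalence=0.0)
        row = res.table.loc["t1"]
        assert row["log2_fc"] == -np.inf
        assert np.isnan(row["pvalue"]) and np.isnan(row["padj"])
        assert res.table["padj"].notna().sum() == 2

    def test_null_type_one_error_is_calibrated(self):
        # 20 replicate null cohorts, 50+50 samples, 100 taxa: pooled fraction
        # of raw p < 0.05 should sit near the nominal level
        fractions = []
        for rep in range(20):
            spec = small_spec(seed=300 + rep, n_taxa=100,
                              group_sizes={"CT": 50, "DZ": 50})
            cohort = generate_cohort(spec)
            res = nb_wald_da(cohort.counts, cohort.labels, "DZ", "CT")
            p = res.table["pvalue"].dropna()
            fractions.append(float((p < 0.05).mean()))
        assert 0.02 <= np.mean(fractions) <= 0.09

    def test_strongly_planted_taxon_wins_smallest_padj(self):
        hits = 0
        for rep in range(20):
            spec = small_spec(seed=500 + rep, n_taxa=100,
                              planted={"DZ": [(5, 3.0)]},
                              group_sizes={"CT": 40, "DZ": 40},
                              depth=(5000, 5000))
            cohort = generate_cohort(spec)
            res = nb_wald_da(cohort.counts, cohort.labels, "DZ", "CT")
            hits += res.table["padj"].idxmin() == cohort.counts.columns[5]
        assert hits >= 18

    def test_requires_two_samples_per_group(self):
        counts = make_counts([[1, 2], [3, 4], [5, 6]])
        labels = pd.Series(["a", "b", "b"], index=counts.index)
        with pytest.raises(ValueError):
            nb_wald_da(counts, labels, "a", "b")


class TestMannWhitney:
    def test_complete_separation_gives_zero_u(self):
        u, _ = mann_whitney_u([1, 2], [3, 4])
        assert u == 0

    def test_identical_samples_symmetric(self):
        u, p = mann_whitney_u([1, 2, 3, 4], [1, 2, 3, 4])
        assert u == pytest.approx(16 / 2)
        assert p > 0.9

    def test_matches_exhaustive_relabeling_oracle(self):
        x, y = (1, 3, 5), (2, 4, 6)
        u_obs, p_obs = mann_whitney_u(x, y)
        pooled = x + y
        # oracle: U and exact two-sided p by enumerating all C(6,3) relabelings
        def u_stat(xs, ys):
            return sum(1 for a in xs for b in ys if a > b)

        assert u_obs == u_stat(x, y)
        u_null = [
            u_stat([pooled[i] for i in combo],
                   [pooled[i] for i in range(6) if i not in combo])
            for combo in itertools.combinations(range(6), 3)
        ]
        mean_u = np.mean(u_null)
        extreme = sum(1 for u in u_null if abs(u - mean_u) >= abs(u_obs - mean_u))
        assert p_obs == pytest.approx(extreme / len(u_null))

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestKruskalWallis:
    def test_identical_groups_give_no_signal(self):
        vals = np.tile([1.0, 2.0, 3.0, 4.0], 3)
        groups = np.repeat(["a", "b", "c"], 4)
        h, p = kruskal_wallis(vals, groups)
        assert h == pytest.approx(0.0, abs=1e-9)
        assert p > 0.99

    def test_matches_textbook_formula(self):
        vals = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9], dtype=float)
        groups = np.repeat(["a", "b", "c"], 3)
        # oracle: H = 12/(N(N+1)) * sum n_i (Rbar_i - Rbar)^2, no ties
        ranks = vals.argsort().argsort() + 1
        n = 9
        h_expected = 12 / (n * (n + 1)) * sum(
            3 * (ranks[groups == g].mean() - (n + 1) / 2) ** 2
            for g in ["a", "b", "c"]
        )
        h, _ = kruskal_wallis(vals, groups)
        assert h == pytest.approx(h_expected, abs=1e-9)

    def test_null_rejection_rate_calibrated(self, rng):
        rejections = 0
        reps = 1000
        for _ in range(reps):
            vals = rng.normal(size=15)
            groups = np.repeat(["a", "b", "c"], 5)
            _, p = kruskal_wallis(vals, groups)
            rejections += p < 0.05
        assert 0.03 <= rejections / reps <= 0.07

    def test_two_groups_directed_to_mann_whitney(self):
        with pytest.raises(ValueError, match="mann_whitney"):
            kruskal_wallis([1, 2, 3, 4], ["a", "a", "b", "b"])


class TestPosthocVsControl:
    def test_identical_groups_give_p_near_one(self, rng):
        vals = rng.normal(size=40)
        groups = np.repeat(["CT", "d1", "d2", "d3"], 10)
        padj = posthoc_vs_control(vals, groups, control="CT")
        assert (padj > 0.2).all()

    def test_only_shifted_group_is_detected(self, rng):
        hits = 0
        for rep in range(20):
            r = np.random.default_rng(900 + rep)
            vals = np.concatenate([
                r.normal(0, 1, 15), r.normal(5, 1, 15), r.normal(0, 1, 15)
            ])
            groups = np.repeat(["CT", "shifted", "nullg"], 15)
            padj = posthoc_vs_control(vals, groups, control="CT")
            hits += (padj["shifted"] < 0.05) and (padj["nullg"] >= 0.05)
        assert hits >= 18

    def test_adjusted_dominates_unadjusted(self, rng):
        vals = rng.normal(size=40)
        groups = np.repeat(["CT", "d1", "d2", "d3"], 10)
        padj = posthoc_vs_control(vals, groups, control="CT")
        for d in ["d1", "d2", "d3"]:
            _, raw = mann_whitney_u(vals[groups == d], vals[groups == "CT"])
            assert padj[d] >= raw - 1e-12

    def test_missing_control_errors(self):
        with pytest.raises(ValueError):
            posthoc_vs_control([1, 2, 3, 4], ["a", "a", "b", "b"], control="CT")


class TestChiSquare:
    def test_perfect_independence(self):
        chi2, dof, p = chi_square_test([[10, 10], [10, 10]])
        assert chi2 == pytest.approx(0.0)
        assert dof == 1
        assert p == pytest.approx(1.0)

    def test_diagonal_table_hand_computation(self):
        chi2, dof, _ = chi_square_test([[20, 0], [0, 20]])
        assert chi2 == pytest.approx(40.0)
        assert dof == 1

    def test_invariant_under_permutation(self, rng):
        t = rng.integers(1, 30, size=(3, 4))
        chi2, _, _ = chi_square_test(t)
        chi2_perm, _, _ = chi_square_test(t[::-1][:, ::-1])
        assert chi2_perm == pytest.approx(chi2)

    def test_empty_margin_errors(self):
        with pytest.raises(ValueError):
            chi_square_test([[0, 0], [5, 5]])


class TestShapiro:
    def test_calibrated_on_normal_draws(self):
        ok = sum(
            shapiro_normality(np.random.default_rng(i).normal(size=500)) > 0.01
            for i in range(40)
        )
        assert ok >= 38  # >= 95%

    def test_detects_exponential(self):
        detected = sum(
            shapiro_normality(np.random.default_rng(i).exponential(size=500)) < 0.01
            for i in range(40)
        )
        assert detected >= 38

    def test_constant_vector_errors(self):
        with pytest.raises(ValueError):
            shapiro_normality(np.ones(10))

    def test_out_of_range_n_errors(self):
        with pytest.raises(ValueError):
            shapiro_normality([1.0, 2.0])


class TestSelectCandidates:
    def test_planted_taxa_recovered(self):
        # effects planted on scattered abundance ranks: median-of-ratios
        # normalization assumes most of the composition is unchanged
        planted_idx = [3, 11, 19, 27, 35]
        hits = 0
        for rep in range(20):
            spec = small_spec(
                seed=700 + rep, n_taxa=40,
                planted={"DZ": [(i, 2.5) for i in planted_idx]},
                group_sizes={"CT": 40, "DZ": 40},
                depth=(4000, 6000),
            )
            cohort = generate_cohort(spec)
            cs = select_candidates(cohort.counts, cohort.phenotypes,
                                   cohort.labels, "DZ")
            planted_names = [cohort.counts.columns[i] for i in planted_idx]
            hits += all(t in cs.taxa for t in planted_names)
        assert hits >= 18

    def test_null_phenotype_candidate_rate_matches_alpha(self):
        # expected false-candidate count for phenotype blocks is about
        # alpha * m; pooled over 20 replicate null cohorts, a binomial
        # tolerance brackets the mean rate
        m_quant = 6
        alpha = 0.05
        total = 0
        reps = 20
        for rep in range(reps):
            spec = small_spec(
                seed=800 + rep,
                quant=[QuantVar(f"q{i}", 50, 10) for i in range(m_quant)],
                qual=[QualVar("c0", ("a", "b"), (0.5, 0.5))],
            )
            cohort = generate_cohort(spec)
            cs = select_candidates(cohort.counts, cohort.phenotypes,
                                   cohort.labels, "DZ", alpha=alpha)
            total += len(cs.quantitative) + len(cs.qualitative)
        n_tests = reps * (m_quant + 1)
        rate = total / n_tests
        se = np.sqrt(alpha * (1 - alpha) / n_tests)
        assert rate <= alpha + 4 * se

    def test_alpha_zero_empties_every_block(self, signal_cohort):
        cs = select_candidates(signal_cohort.counts, signal_cohort.phenotypes,
                               signal_cohort.labels, "DZ", alpha=0.0)
        assert cs.taxa == [] and cs.quantitative == [] and cs.qualitative == []

    def test_selection_invariant_to_sample_order(self, signal_cohort):
        c = signal_cohort
        cs1 = select_candidates(c.counts, c.phenotypes, c.labels, "DZ")
        perm = np.random.default_rng(0).permutation(len(c.labels))
        idx = c.counts.index[perm]
        cs2 = select_candidates(c.counts.loc[idx], c.phenotypes.loc[idx],
                                c.labels.loc[idx], "DZ")
        assert cs1.to_dict() == cs2.to_dict()

    def test_missing_group_errors(self, signal_cohort):
        with pytest.raises(ValueError):
            select_candidates(signal_cohort.counts, signal_cohort.phenotypes,
                              signal_cohort.labels, "NOPE")
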