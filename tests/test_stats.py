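"""Statistical pipeline vs brute-force oracles and textbook invariants."""

import subprocess
import sys
import textwrap

import numpy as np
import pandas as pd
import pytest

import _oracles
from renal_ivim.cohort import CohortConfig, generate_cohort
from renal_ivim.stats import (
    anova_posthoc,
    bonferroni,
    build_study_report,
    chi_square_counts,
    icc_two_reader,
    kruskal_wallis_posthoc,
    mann_whitney,
    normality_screen,
    roc_analysis,
    spearman_bonferroni,
)


class TestNormalityScreen:
    def test_normal_null(self):
        x = np.random.default_rng(0).normal(size=5000)
        assert normality_screen(x).classification == "normal"

    def test_gross_violation(self):
        x = np.exp(np.random.default_rng(1).normal(0, 1, size=5000))
        assert normality_screen(x).classification == "non_normal"

    def test_constant_vector_documented(self):
        res = normality_screen(np.ones(10))
        assert res.classification == "non_normal"
        assert "degenerate" in res.flags

    def test_too_small(self):
        with pytest.raises(ValueError):
            normality_screen([1.0, 2.0])


class TestMannWhitney:
    def test_complete_separation(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.u == 0.0

    def test_identical_samples_tied_u(self):
        x = list(range(10))
        res = mann_whitney(x, x)
        assert res.u == pytest.approx(100 / 2)  # n^2 / 2 with full ties
        assert res.p > 0.99

    def test_exact_p_vs_permutation_enumeration(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            n1 = int(rng.integers(2, 5))
            n2 = int(rng.integers(2, 5))
            a = rng.normal(size=n1)
            b = rng.normal(size=n2) + rng.normal()
            res = mann_whitney(a, b)
            assert res.method == "exact"
            assert res.u == pytest.approx(_oracles.mann_whitney_u(a, b))
            assert res.p == pytest.approx(_oracles.mann_whitney_exact_p(a, b),
                                          abs=1e-12)

    def test_small_two_vs_one(self):
        res = mann_whitney([1.0, 2.0], [3.0])
        assert res.u == 0.0
        assert res.p == pytest.approx(_oracles.mann_whitney_exact_p([1, 2], [3]))

    def test_empty_group(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestKruskalWallis:
    def test_h_against_direct_rank_formula(self):
        groups = [[1, 2], [3, 4], [5, 6]]
        res = kruskal_wallis_posthoc(groups)
        assert res.h == pytest.approx(_oracles.kruskal_h(groups), rel=1e-12)

    def test_random_instances_vs_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            groups = [rng.integers(0, 6, size=rng.integers(2, 8)).astype(float)
                      for _ in range(3)]
            if all(np.ptp(np.concatenate(groups)) == 0 for _ in [0]):
                continue
            res = kruskal_wallis_posthoc(groups)
            assert res.h == pytest.approx(_oracles.kruskal_h(groups), rel=1e-10)

    def test_identical_groups_adjusted_p_capped_at_one(self):
        x = np.arange(40, dtype=float)
        res = kruskal_wallis_posthoc([x, x, x])
        assert res.p > 0.05
        for pair in res.pairwise.values():
            assert pair.p_adj == 1.0

    def test_requires_three_groups(self):
        with pytest.raises(ValueError):
            kruskal_wallis_posthoc([[1, 2], [3, 4]])

    def test_anova_branch_pairwise_adjustment(self):
        rng = np.random.default_rng(4)
        groups = [rng.normal(m, 1, 30) for m in (0, 0, 2)]
        res = anova_posthoc(groups)
        assert res.p < 0.01
        assert res.pairwise[(0, 1)].p_adj == pytest.approx(
            min(1.0, 3 * res.pairwise[(0, 1)].p_raw))


class TestSpearman:
    def test_perfect_monotone(self):
        [res] = spearman_bonferroni({"x": [1, 2, 3, 5]}, {"y": [2, 4, 9, 11]})
        assert res.rho == pytest.approx(1.0)

    def test_reversed_monotone(self):
        [res] = spearman_bonferroni({"x": [1, 2, 3, 5]}, {"y": [11, 9, 4, 2]})
        assert res.rho == pytest.approx(-1.0)

    def test_hand_rank_oracle_case(self):
        [res] = spearman_bonferroni({"x": [1, 2, 3, 4]}, {"y": [1, 3, 2, 4]})
        assert res.rho == pytest.approx(0.8)

    def test_random_instances_with_ties_vs_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            n = int(rng.integers(4, 9))
            x = rng.integers(0, 4, n).astype(float)
            y = rng.integers(0, 4, n).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            [res] = spearman_bonferroni({"x": x}, {"y": y})
            assert res.rho == pytest.approx(_oracles.spearman_rho(x, y), abs=1e-12)

    def test_bonferroni_family(self):
        results = spearman_bonferroni(
            {"a": [1, 2, 3, 4, 5], "b": [2, 1, 4, 3, 5]},
            {"t": [1, 3, 2, 5, 4]}, family_size=6)
        for r in results:
            assert r.p_adj == pytest.approx(min(1.0, 6 * r.p_raw))
            assert r.family_size == 6

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            spearman_bonferroni({"x": [1, 2, 3]}, {"y": [1, 2]})


class TestBonferroni:
    def test_capped_and_monotone(self):
        assert bonferroni(0.5, 6) == 1.0
        assert bonferroni(0.001, 6) == pytest.approx(0.006)
        ps = np.linspace(0, 1, 50)
        adj = [bonferroni(p, 5) for p in ps]
        assert all(b >= a for a, b in zip(adj, adj[1:]))
        assert max(adj) <= 1.0


class TestICC:
    def test_duplicated_column_is_unity(self):
        x = np.random.default_rng(6).normal(size=20)
        res = icc_two_reader(np.c_[x, x])
        assert res.icc == pytest.approx(1.0, abs=1e-9)

    def test_independent_columns_near_zero(self):
        # null simulation: mean ICC over replicates of n=200 independent readers
        rng = np.random.default_rng(7)
        iccs = [icc_two_reader(rng.normal(size=(200, 2))).icc for _ in range(10)]
        assert abs(np.mean(iccs)) <= 0.1

    def test_ci_contains_estimate(self):
        rng = np.random.default_rng(8)
        subj = rng.normal(0, 2, 50)
        m = np.c_[subj + rng.normal(0, 0.5, 50), subj + rng.normal(0, 0.5, 50)]
        res = icc_two_reader(m)
        assert res.ci_low <= res.icc <= res.ci_high

    def test_missing_cells_rejected(self):
        m = np.random.default_rng(9).normal(size=(10, 2))
        m[3, 1] = np.nan
        with pytest.raises(ValueError):
            icc_two_reader(m)
        with pytest.raises(ValueError):
            icc_two_reader(m[:4])


class TestRoc:
    def test_perfect_separation(self):
        res = roc_analysis([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert res.auc == 1.0
        assert res.youden == pytest.approx(1.0)
        assert res.sensitivity == 1.0 and res.specificity == 1.0

    def test_null_marker(self):
        rng = np.random.default_rng(10)
        res = roc_analysis(rng.normal(size=2000), rng.integers(0, 2, 2000))
        assert res.auc == pytest.approx(0.5, abs=0.05)

    def test_auc_equals_u_over_n1n2(self):
        """Empirical AUC == U/(n1*n2) on random small instances, exactly."""
        rng = np.random.default_rng(11)
        for _ in range(200):
            n1 = int(rng.integers(2, 10))
            n0 = int(rng.integers(2, 10))
            marker = np.concatenate([rng.integers(0, 6, n1),
                                     rng.integers(0, 6, n0)]).astype(float)
            labels = np.r_[np.ones(n1), np.zeros(n0)].astype(bool)
            res = roc_analysis(marker, labels, direction=">")
            oracle = _oracles.pairwise_auc(marker[labels], marker[~labels])
            assert res.auc == pytest.approx(oracle, abs=1e-12)

    def test_youden_consistency(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            marker = rng.normal(size=60)
            labels = rng.integers(0, 2, 60).astype(bool)
            if labels.all() or not labels.any():
                continue
            res = roc_analysis(marker, labels)
            assert res.youden == pytest.approx(
                res.sensitivity + res.specificity - 1.0, abs=1e-12)

    def test_direction_for_disease_lowered_marker(self):
        rng = np.random.default_rng(13)
        marker = np.r_[rng.normal(5, 1, 30), rng.normal(2, 1, 30)]
        labels = np.r_[np.zeros(30), np.ones(30)].astype(bool)
        res = roc_analysis(marker, labels)
        assert res.direction == "<="
        assert res.auc > 0.9
        # the rule classifies by marker <= threshold
        pred = marker <= res.threshold
        sens = (pred & labels).sum() / labels.sum()
        assert sens == pytest.approx(res.sensitivity, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_analysis([1.0, 2.0], [1, 1])

    def test_delong_ci_matches_r_proc(self):
        """DeLong 95% CI cross-checked against R's pROC on a fixed instance."""
        rng = np.random.default_rng(14)
        marker = np.round(np.r_[rng.normal(2, 1, 25), rng.normal(3.2, 1, 20)], 4)
        labels = np.r_[np.zeros(25, int), np.ones(20, int)]
        res = roc_analysis(marker, labels, direction=">")
        rscript = textwrap.dedent(f"""
            suppressMessages(library(pROC))
            marker <- c({", ".join(map(str, marker))})
            labels <- c({", ".join(map(str, labels))})
            r <- roc(labels, marker, direction="<", quiet=TRUE)
            ci <- ci.auc(r, method="delong")
            cat(sprintf("%.10f %.10f %.10f", ci[1], ci[2], ci[3]))
        """)
        out = subprocess.run(["Rscript", "-e", rscript], capture_output=True,
                             text=True, check=True)
        lo, auc, hi = map(float, out.stdout.split())
        assert res.auc == pytest.approx(auc, abs=1e-9)
        assert res.ci95[0] == pytest.approx(lo, abs=1e-6)
        assert res.ci95[1] == pytest.approx(hi, abs=1e-6)


class TestChiSquare:
    def test_proportional_table_is_zero(self):
        stat, p, dof = chi_square_counts([[10, 20, 30], [1, 2, 3]])
        assert stat == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_two_by_two(self):
        stat, _, dof = chi_square_counts([[10, 0], [0, 10]])
        assert stat == pytest.approx(20.0)
        assert dof == 1

    def test_study_gender_counts_nonsignificant(self):
        # male/female counts per group in the emulated study design
        stat, p, _ = chi_square_counts([[7, 17, 20], [12, 16, 8]])
        assert p > 0.05

    def test_oracle_random_tables(self):
        rng = np.random.default_rng(15)
        for _ in range(20):
            t = rng.integers(1, 20, size=(2, 3))
            stat, _, _ = chi_square_counts(t)
            assert stat == pytest.approx(_oracles.chi_square_stat(t), rel=1e-12)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            chi_square_counts([[0, 0], [1, 2]])


class TestRankInvariance:
    def test_monotone_transform_leaves_rank_statistics_unchanged(self):
        rng = np.random.default_rng(16)
        a, b, c = rng.normal(size=20), rng.normal(1, 1, 25), rng.normal(2, 1, 15)
        f = np.exp  # strictly monotone
        assert mann_whitney(a, b).p == pytest.approx(mann_whitney(f(a), f(b)).p)
        assert kruskal_wallis_posthoc([a, b, c]).h == pytest.approx(
            kruskal_wallis_posthoc([f(a), f(b), f(c)]).h)
        [r1] = spearman_bonferroni({"x": a}, {"y": b[:20]})
        [r2] = spearman_bonferroni({"x": f(a)}, {"y": f(b[:20])})
        assert r1.rho == pytest.approx(r2.rho)
        labels = np.r_[np.zeros(20), np.ones(25)].astype(bool)
        m = np.r_[a, b]
        assert roc_analysis(m, labels, direction=">").auc == pytest.approx(
            roc_analysis(f(m), labels, direction=">").auc)


@pytest.fixture(scope="module")
def small_cohort():
    return generate_cohort(CohortConfig(seed=2))


class TestStudyReport:
    def _values(self, cohort):
        from renal_ivim.cohort import PARAM_NAMES
        df = cohort.params_df[["subject_id"] +
                              [f"{p}_true" for p in PARAM_NAMES]]
        return df.rename(columns={f"{p}_true": p for p in PARAM_NAMES})

    def test_all_tables_produced(self, small_cohort):
        res = build_study_report(
            small_cohort.subjects_df, self._values(small_cohort),
            reader_pairs=small_cohort.params_df,
            pathology_df=small_cohort.pathology_df)
        assert len(res.parameters) == 6
        assert set(res.roc["contrast"]) == {"control_vs_ckd", "control_vs_high"}
        assert len(res.icc) == 6
        assert len(res.pathology) == 4
        assert not res.correlations.empty
        # decreasing medians across groups for the bi-/stretched parameters
        med = small_cohort.params_df.groupby("group")[
            ["adc_fast_true", "f_true", "alpha_true"]].median()
        for col in med:
            assert med.loc["control", col] > med.loc["high_egfr", col] \
                > med.loc["low_egfr", col]

    def test_permuted_labels_kill_group_signal(self, small_cohort):
        """Omnibus p under label permutation is null on average."""
        rng = np.random.default_rng(20)
        df = small_cohort.params_df
        ps = []
        for _ in range(20):
            perm = rng.permutation(df["group"].to_numpy())
            groups = [df.loc[perm == g, "adc_fast_true"].to_numpy()
                      for g in ("control", "high_egfr", "low_egfr")]
            ps.append(kruskal_wallis_posthoc(groups).p)
        assert np.mean(ps) > 0.05
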