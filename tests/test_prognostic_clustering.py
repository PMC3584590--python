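"""Hierarchical clustering, Kaplan-Meier, log-rank, Cox, Fisher exact."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from tmaprog import prognostic_clustering as pc
from tmaprog import synthetic_data as sd


def logrank_oracle(times, events, groups):
    """Risk-table log-rank chi-square from the observed-minus-expected
    definition; independent of the package implementation."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    groups = np.asarray(groups)
    labs = np.unique(groups)
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        n = at_risk.sum()
        d = (events & (times == t)).sum()
        n1 = (at_risk & (groups == labs[0])).sum()
        d1 = (events & (times == t) & (groups == labs[0])).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestHierarchicalCluster:
    def test_brute_force_1d_partition(self):
        """1D values {0,1,10}: complete linkage splits {0,1} from {10}."""
        m = pd.DataFrame({"f": [0.0, 1.0, 10.0]}, index=["a", "b", "c"])
        out = pc.hierarchical_cluster(m, k=2)
        assert out.labels["a"] == out.labels["b"] != out.labels["c"]

    def test_planted_groups_fully_recovered(self):
        m, truth = sd.generate_cohort_matrix(
            n_patients=40, n_features=30, n_planted=15, effect=3.0,
            group_sizes=(15, 25), missing_rate=0.0, seed=2,
        )
        out = pc.hierarchical_cluster(m, k=2)
        assert adjusted_rand_score(truth.group_assignment, out.labels) == 1.0

    def test_order_invariant_up_to_label_swap(self):
        rng = np.random.default_rng(5)
        m = pd.DataFrame(rng.normal(size=(12, 4)), index=[f"p{i}" for i in range(12)])
        a = pc.hierarchical_cluster(m, k=2).labels
        perm = rng.permutation(12)
        b = pc.hierarchical_cluster(m.iloc[perm], k=2).labels
        assert adjusted_rand_score(a.loc[b.index], b) == 1.0

    def test_identical_rows_deterministic(self):
        """All-identical patients collapse to one flat cluster, always the
        same labeling under the first-occurrence tie-break."""
        m = pd.DataFrame(np.ones((4, 3)), index=list("abcd"))
        out = pc.hierarchical_cluster(m, k=2)
        assert out.labels.nunique() == 1
        again = pc.hierarchical_cluster(m, k=2)
        pd.testing.assert_series_equal(out.labels, again.labels)

    def test_too_few_patients_rejected(self):
        m = pd.DataFrame(np.ones((1, 3)))
        with pytest.raises(ValueError):
            pc.hierarchical_cluster(m, k=2)

    def test_incomplete_matrix_rejected(self):
        m = pd.DataFrame([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError, match="complete"):
            pc.hierarchical_cluster(m, k=2)


class TestKaplanMeier:
    def test_product_limit_no_censoring(self):
        curve, median = pc.km_estimate([1, 2, 3, 4], [1, 1, 1, 1])
        steps = curve.set_index("time")["survival"]
        assert steps.loc[[1.0, 2.0, 3.0, 4.0]].tolist() == pytest.approx(
            [0.75, 0.5, 0.25, 0.0]
        )
        assert median == pytest.approx(2.0)

    def test_all_censored_flat_curve(self):
        curve, median = pc.km_estimate([5, 6, 7], [0, 0, 0])
        assert np.isnan(median)
        assert (curve["survival"] == 1.0).all()

    def test_single_patient(self):
        curve, median = pc.km_estimate([5.0], [1])
        assert median == pytest.approx(5.0)
        assert curve["survival"].iloc[-1] == pytest.approx(0.0)

    def test_curve_starts_at_one_nonincreasing(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(10, 30)
        e = rng.random(30) < 0.7
        curve, _ = pc.km_estimate(t, e)
        s = curve["survival"].to_numpy()
        assert s[0] == 1.0
        assert np.all(np.diff(s) <= 1e-12)

    def test_matches_empirical_survival_without_censoring(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(12, 25)
        curve, _ = pc.km_estimate(t, np.ones(25, bool))
        for time, surv in zip(curve["time"], curve["survival"]):
            assert surv == pytest.approx(np.mean(t > time))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pc.km_estimate([], [])


class TestLogrank:
    def test_identical_groups_null(self):
        t = [1, 2, 3, 4, 1, 2, 3, 4]
        e = [1] * 8
        g = [0] * 4 + [1] * 4
        chi2, p = pc.logrank_test(t, e, g)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_risk_table_oracle(self):
        t = [1, 2, 3, 10, 20, 30]
        e = [1] * 6
        g = ["A"] * 3 + ["B"] * 3
        chi2, _ = pc.logrank_test(t, e, g)
        assert chi2 == pytest.approx(logrank_oracle(t, e, g))

    def test_one_group_rejected(self):
        with pytest.raises(ValueError, match="two"):
            pc.logrank_test([1, 2], [1, 1], ["A", "A"])

    def test_agrees_with_permutation_p_small_n(self):
        """Chi-square p matches a label-permutation p within MC error."""
        rng = np.random.default_rng(7)
        t = rng.exponential(10, 16)
        e = rng.random(16) < 0.8
        g = np.array([0] * 8 + [1] * 8)
        chi2_obs, p_chi2 = pc.logrank_test(t, e, g)
        n_perm = 2000
        count = 0
        for _ in range(n_perm):
            gp = rng.permutation(g)
            if logrank_oracle(t, e, gp) >= chi2_obs - 1e-12:
                count += 1
        p_perm = count / n_perm
        assert abs(p_perm - p_chi2) < 4 * np.sqrt(p_perm * (1 - p_perm) / n_perm) + 0.02


class TestCox:
    def test_binary_covariate_hr_recovery_single_run(self):
        rng = np.random.default_rng(0)
        n = 200
        x = rng.integers(0, 2, n)
        lam = 0.05 * np.exp(np.log(3.0) * x)
        t = rng.exponential(1 / lam)
        clinical = pd.DataFrame(
            {
                "time_months": t,
                "event": np.ones(n, bool),
                "age": rng.normal(55, 10, n),
            },
            index=[f"P{i}" for i in range(n)],
        )
        labels = pd.Series(np.where(x == 1, 2, 1), index=clinical.index)
        out = pc.cox_multivariate(clinical, labels)
        assert 2.0 < out.loc["cluster2", "hazard_ratio"] < 4.5
        assert out.loc["cluster2", "ci_low"] < 3.0 < out.loc["cluster2", "ci_high"]

    def test_constant_covariate_dropped_with_warning(self):
        rng = np.random.default_rng(1)
        n = 60
        clinical = pd.DataFrame(
            {
                "time_months": rng.exponential(10, n),
                "event": np.ones(n, bool),
                "age": np.full(n, 50.0),  # dichotomized -> constant
            },
            index=[f"P{i}" for i in range(n)],
        )
        labels = pd.Series(rng.integers(1, 3, n), index=clinical.index)
        with pytest.warns(UserWarning, match="constant"):
            out = pc.cox_multivariate(clinical, labels)
        assert "age_ge_cut" not in out.index

    def test_null_covariate_p_calibrated(self):
        """A covariate unrelated to survival has roughly uniform p."""
        rng = np.random.default_rng(2)
        ps = []
        for rep in range(30):
            n = 80
            clinical = pd.DataFrame(
                {
                    "time_months": rng.exponential(10, n),
                    "event": np.ones(n, bool),
                    "age": rng.normal(55, 10, n),
                },
                index=[f"P{i}" for i in range(n)],
            )
            labels = pd.Series(rng.integers(1, 3, n), index=clinical.index)
            out = pc.cox_multivariate(clinical, labels)
            ps.append(out.loc["cluster2", "p"])
        _, ks_p = stats.kstest(ps, "uniform")
        assert ks_p > 0.01


class TestFisherExact:
    def test_balanced_table(self):
        assert pc.fisher_exact_2x2([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_small_diagonal_table_enumeration(self):
        """[[2,0],[0,2]]: of the C(4,2)=6 equal-margin tables, the two
        diagonal ones have probability 1/6 each -> two-sided p = 1/3."""
        assert pc.fisher_exact_2x2([[2, 0], [0, 2]]) == pytest.approx(1.0 / 3.0)

    def test_large_diagonal_tiny_p(self):
        assert pc.fisher_exact_2x2([[20, 0], [0, 20]]) < 1e-9

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            pc.fisher_exact_2x2([[1, -1], [0, 2]])


class TestPrognosisLabels:
    def _assignment(self, labels):
        s = pd.Series(labels, index=[f"P{i}" for i in range(len(labels))])
        return pc.ClusterAssignment(s, np.zeros((0, 4)))

    def test_planted_hazard_ratio_sets_poor_label(self):
        m, truth = sd.generate_cohort_matrix(
            n_patients=60, n_features=5, n_planted=0, effect=0.0,
            group_sizes=(30, 30), missing_rate=0.0, seed=3,
            hazards=(0.18, 0.06), censor_rate=0.1,
        )
        recs = sd.generate_survival(truth, seed=3)
        clin = sd.clinical_to_frame(recs)
        labels = truth.group_assignment
        a = pc.ClusterAssignment(labels.rename("cluster"), np.zeros((0, 4)))
        out = pc.assign_prognosis_labels(a, clin["time_months"], clin["event"])
        assert out.poor_prognosis_label == 1

    def test_symmetric_survival_tie_error(self):
        a = self._assignment([1, 1, 2, 2])
        with pytest.raises(ValueError, match="manual"):
            pc.assign_prognosis_labels(a, [5, 10, 5, 10], [1, 1, 1, 1])

    def test_all_censored_cluster_is_good_prognosis(self):
        a = self._assignment([1, 1, 2, 2])
        out = pc.assign_prognosis_labels(a, [5, 10, 8, 9], [1, 1, 0, 0])
        assert out.poor_prognosis_label == 1


class TestKmPlot:
    def test_writes_png(self, tmp_path):
        comp = pc.compare_group_survival(
            [1, 2, 3, 4, 5, 6], [1] * 6, [1, 1, 1, 2, 2, 2]
        )
        path = tmp_path / "km.png"
        pc.plot_km_curves(comp, path)
        assert path.stat().st_size > 0


class TestTumorNormalSeparation:
    def test_separated_tissues_small_fisher_p(self):
        rng = np.random.default_rng(4)
        tumor = pd.DataFrame(rng.normal(200, 10, (20, 8)),
                             index=[f"T{i}" for i in range(20)])
        normal = pd.DataFrame(rng.normal(50, 10, (10, 8)),
                              index=[f"N{i}" for i in range(10)])
        combined = pd.concat([tumor, normal])
        tissue = pd.Series(["tumor"] * 20 + ["normal"] * 10, index=combined.index)
        p, tab = pc.tumor_normal_separation(combined, tissue)
        assert p < 1e-6
        assert tab.to_numpy().sum() == 30
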