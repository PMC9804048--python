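import numpy as np
import pytest
from scipy import stats as sps

from dfnc import (
    chi_square_counts,
    compare_between,
    compare_within,
    fdr_adjust,
    normality_test,
    partial_spearman,
    run_full_comparison,
)
from dfnc.metrics import metrics_table
from dfnc.stats import mannwhitney_exact, wilcoxon_exact


class TestNormality:
    def test_tiny_sample_rejected(self):
        with pytest.raises(ValueError):
            normality_test([1.0, 2.0])

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            normality_test([1.0] * 10)

    def test_gaussian_samples_pass(self):
        hits = 0
        for seed in range(10):
            x = np.random.default_rng(seed).standard_normal(500)
            _, p = normality_test(x)
            hits += p > 0.05
        assert hits >= 9

    def test_exponential_samples_fail(self):
        x = np.random.default_rng(3).exponential(size=500)
        _, p = normality_test(x)
        assert p < 0.01


class TestMannWhitney:
    def test_fully_separated_small_arms(self):
        res = compare_between([1, 2, 3], [4, 5, 6], force_test="mannwhitney")
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1)

    def test_identical_arms_give_p_one(self):
        res = compare_between([1, 2, 3], [1, 2, 3], force_test="mannwhitney")
        assert res.p_value == pytest.approx(1.0)

    def test_exact_path_matches_scipy_enumeration(self, rng):
        """On tie-free data the enumeration must agree with scipy's exact
        Mann-Whitney null for every small dataset."""
        for _ in range(25):
            n_a, n_b = rng.integers(2, 5, size=2)
            a = rng.standard_normal(n_a)
            b = rng.standard_normal(n_b)
            u, p = mannwhitney_exact(a, b)
            ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert u == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_normality_gate_picks_t_for_gaussians(self, rng):
        a = rng.standard_normal(60)
        b = rng.standard_normal(60) + 0.2
        assert compare_between(a, b).test == "t"
        assert compare_between(rng.exponential(size=60), b).test == "mannwhitney"

    def test_empty_arm_rejected(self):
        with pytest.raises(ValueError):
            compare_between([], [1.0])


class TestWilcoxon:
    def test_three_positive_differences(self):
        res = compare_within([0, 0, 0], [1, 2, 3])
        assert res.p_value == pytest.approx(0.25)

    def test_no_change_is_degenerate(self):
        res = compare_within([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.degenerate and res.p_value == 1.0

    def test_exact_null_matches_scipy(self, rng):
        for _ in range(25):
            d = rng.standard_normal(rng.integers(4, 11))
            w, p = wilcoxon_exact(d)
            ref = sps.wilcoxon(d, alternative="two-sided", method="exact")
            assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_exact_null_distribution_is_proper(self, rng):
        """Over all 2^n sign patterns the exact p at the most extreme
        observable statistic is 2/2^n and at the center it is 1."""
        d = np.abs(rng.standard_normal(8)) + 0.1  # all positive
        _, p = wilcoxon_exact(d)
        assert p == pytest.approx(2 / 2**8)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compare_within([1, 2], [1, 2, 3])


class TestChiSquare:
    def test_gender_table_worked_example(self):
        stat, p = chi_square_counts([[22, 19], [21, 13]])
        assert p == pytest.approx(0.49, abs=0.02)

    def test_homogeneous_table(self):
        stat, p = chi_square_counts([[10, 10], [10, 10]])
        assert stat == 0.0 and p == 1.0

    def test_perfect_association(self):
        stat, p = chi_square_counts([[20, 0], [0, 20]])
        assert stat == pytest.approx(40.0)
        assert p < 1e-8

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square_counts([[0, 0], [5, 5]])


class TestPartialSpearman:
    def test_monotone_transform_gives_unit_rho(self, rng):
        x = rng.standard_normal(30)
        res = partial_spearman(x, x**3)
        assert res.rho == pytest.approx(1.0)

    def test_covariate_equal_to_x_is_degenerate(self, rng):
        x = rng.standard_normal(30)
        res = partial_spearman(x, rng.standard_normal(30), covariates=x[:, None])
        assert res.degenerate and res.rho == 0.0

    def test_no_covariates_equals_plain_spearman(self, rng):
        x, y = rng.standard_normal((2, 50))
        res = partial_spearman(x, y)
        rho_ref, p_ref = sps.spearmanr(x, y)
        assert res.rho == pytest.approx(rho_ref, abs=1e-12)
        assert res.p_value == pytest.approx(p_ref, rel=1e-6)

    def test_matches_pingouin_partial_correlation(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        n = 60
        z = rng.standard_normal((n, 2))
        x = z @ [0.5, -0.3] + rng.standard_normal(n)
        y = 0.4 * x + z @ [0.2, 0.6] + rng.standard_normal(n)
        df = pd.DataFrame({"x": x, "y": y, "c1": z[:, 0], "c2": z[:, 1]})
        ref = pingouin.partial_corr(df, x="x", y="y", covar=["c1", "c2"],
                                    method="spearman")
        res = partial_spearman(x, y, covariates=z)
        assert res.rho == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert res.p_value == pytest.approx(float(ref["p_val"].iloc[0]), rel=1e-6)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            partial_spearman([1, 1, 1, 1, 1], [1, 2, 3, 4, 5])


class TestFDR:
    def test_stepup_boundary_family(self):
        p_adj, flags = fdr_adjust([0.01, 0.02, 0.03, 0.04, 0.05])
        np.testing.assert_allclose(p_adj, 0.05)
        assert flags.all()

    def test_single_p_unchanged(self):
        p_adj, flags = fdr_adjust([0.03])
        assert p_adj[0] == pytest.approx(0.03)
        assert flags[0]

    def test_all_null_none_significant(self):
        _, flags = fdr_adjust([1.0, 1.0, 1.0])
        assert not flags.any()

    def test_flags_match_bruteforce_definition(self, rng):
        """BH flags equal max{i: p_(i) <= i alpha / m} from first principles,
        and adjusted p-values are monotone in raw-p order."""
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 12))
            alpha = 0.05
            p_adj, flags = fdr_adjust(p, alpha)
            order = np.argsort(p)
            m = len(p)
            thresh = [i for i in range(1, m + 1)
                      if p[order][i - 1] <= i * alpha / m]
            expected = np.zeros(m, dtype=bool)
            if thresh:
                expected[order[: max(thresh)]] = True
            np.testing.assert_array_equal(flags, expected)
            assert np.all(np.diff(p_adj[order]) >= -1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.2])


class TestFullComparison:
    @staticmethod
    def _toy_tables(rng, n_per_group=8, k=3, drop_on_for=None):
        rows = {}
        subjects = []
        for g, n in (("LID", n_per_group), ("NoLID", n_per_group)):
            for i in range(n):
                sid = f"{g}{i}"
                subjects.append(
                    {"subject": sid, "group": g,
                     "age_at_onset": 50 + rng.standard_normal(),
                     "ledd": 700 + 10 * rng.standard_normal(),
                     "disease_duration": 7 + rng.standard_normal(),
                     "aims": float(rng.uniform(0, 20)) if g == "LID" else np.nan}
                )
                for phase in ("OFF", "ON"):
                    if drop_on_for == sid and phase == "ON":
                        continue
                    rows[(sid, phase)] = rng.integers(1, k + 1, size=40)
        import pandas as pd

        return metrics_table(rows, k), pd.DataFrame(subjects)

    def test_contrast_families_complete(self, rng):
        metrics, subjects = self._toy_tables(rng)
        out = run_full_comparison(metrics, subjects)
        comp = out["comparisons"]
        assert set(comp["contrast"]) == {
            "LIDvsNoLID@OFF", "LIDvsNoLID@ON", "OFFvsON@LID", "OFFvsON@NoLID"
        }
        # per state-metric: 3 states x 4 contrasts x 2 metrics + 4 transition rows
        assert len(comp) == 3 * 4 * 2 + 4
        corr = out["correlations"]
        assert len(corr) == 3 * 2 + 1
        assert out["n_dropped"] == 0

    def test_subject_missing_phase_dropped_with_warning(self, rng):
        metrics, subjects = self._toy_tables(rng, drop_on_for="LID0")
        with pytest.warns(UserWarning, match="without both phases"):
            out = run_full_comparison(metrics, subjects)
        assert out["n_dropped"] == 1


def _cohort_metrics(cfg):
    """Ground-truth window-state metrics table + subject table (cheap:
    no time-course synthesis)."""
    from dfnc import WindowSpec, simulate_cohort, window_majority_labels
    from dfnc.simulate import subject_table

    cohort = simulate_cohort(cfg, include_timecourses=False)
    seqs = {
        key: window_majority_labels(path, WindowSpec())
        for key, path in cohort.ground_truth["paths"].items()
    }
    return metrics_table(seqs, cfg.n_states), subject_table(cohort)


class TestBatteryCalibrationAndPower:
    def test_null_scenario_false_positive_rate(self):
        """With no planted group or phase differences, at most ~10% of
        contrasts reach p < 0.05 before FDR."""
        from dfnc import ScenarioConfig

        n_sig = n_tot = 0
        for seed in (1, 2, 3):
            null_dwell = {
                (g, p): np.full(5, 60.0)
                for g in ("LID", "NoLID") for p in ("OFF", "ON")
            }
            null_logits = {
                (g, p): np.zeros(5)
                for g in ("LID", "NoLID") for p in ("OFF", "ON")
            }
            cfg = ScenarioConfig(dwell_mean_windows=null_dwell,
                                 occupancy_logits=null_logits, seed=seed)
            metrics, subjects = _cohort_metrics(cfg)
            comp = run_full_comparison(metrics, subjects)["comparisons"]
            n_sig += int((comp["p_value"] < 0.05).sum())
            n_tot += len(comp)
        assert n_sig / n_tot <= 0.10

    def test_planted_on_phase_elevation_detected(self):
        """The default scenario's ON-phase occupancy elevation of state 1
        in the LID group is detected both between groups (Mann-Whitney)
        and within the LID group (paired Wilcoxon) in >= 80% of seeds."""
        from dfnc import ScenarioConfig, simulate_cohort

        between_hits = paired_hits = 0
        n_seeds = 10
        for seed in range(1, n_seeds + 1):
            cohort = simulate_cohort(ScenarioConfig(seed=seed),
                                     include_timecourses=False)
            occ = cohort.ground_truth["occupancy"]
            lid = [s.id for s in cohort.subjects if s.group == "LID"]
            nolid = [s.id for s in cohort.subjects if s.group == "NoLID"]
            a = [occ[(i, "ON")][0] for i in lid]
            b = [occ[(i, "ON")][0] for i in nolid]
            res = compare_between(a, b, force_test="mannwhitney")
            between_hits += res.p_value < 0.05 and np.median(a) > np.median(b)
            off = [occ[(i, "OFF")][0] for i in lid]
            paired_hits += compare_within(off, a).p_value < 0.05
        assert between_hits >= 0.8 * n_seeds
        assert paired_hits >= 0.8 * n_seeds
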