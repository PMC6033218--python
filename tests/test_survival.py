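import numpy as np
import pandas as pd
import pytest
from scipy import stats

from s3score import (
    cox_fit,
    find_cutoff,
    harrell_c,
    km_estimate,
    logrank_test,
    lr_test,
    recode_covariates,
)
from s3score.survival import SurvivalError, validate_survival
from conftest import make_survival_frame


class TestKaplanMeier:
    def test_hand_product_limit(self):
        # {1e, 2c, 3e, 4e, 5c}: S = 0.8 after t=1, 0.5333 after t=3, 0.2667 after t=4
        rec = make_survival_frame([1, 2, 3, 4, 5], [1, 0, 1, 1, 0])
        km = km_estimate(rec)
        assert km.survival_at(1.5) == pytest.approx(0.8)
        assert km.survival_at(3.5) == pytest.approx(0.5333, abs=1e-4)
        assert km.survival_at(4.5) == pytest.approx(0.2667, abs=1e-4)

    def test_all_censored_stays_at_one(self):
        rec = make_survival_frame([1, 2, 3], [0, 0, 0])
        km = km_estimate(rec)
        assert np.allclose(km.survival, 1.0)

    def test_duplication_invariance_and_shape(self):
        rec = make_survival_frame([1, 2, 3, 4, 5], [1, 0, 1, 1, 0])
        both = pd.concat(
            [rec, rec.set_index(rec.index + "_copy")]
        )
        km1, km2 = km_estimate(rec), km_estimate(both)
        for t in (0.5, 1.5, 3.5, 4.5):
            assert km1.survival_at(t) == pytest.approx(km2.survival_at(t))
        # non-increasing, starts at 1 before first event
        assert (np.diff(km1.survival) <= 1e-12).all()
        assert km1.survival_at(0.0) == 1.0

    def test_empty_input_is_error(self):
        with pytest.raises(SurvivalError):
            km_estimate(make_survival_frame([], []))


class TestLogrank:
    def test_hand_risk_set_enumeration(self):
        # A = {1e, 3e, 5c}, B = {2e, 4c, 6e}: O_A=2, E_A=1.4, V=0.74
        rec = make_survival_frame([1, 3, 5, 2, 4, 6], [1, 1, 0, 1, 0, 1])
        groups = ["A", "A", "A", "B", "B", "B"]
        res = logrank_test(rec, groups)
        assert res.statistic == pytest.approx(0.6**2 / 0.74, abs=1e-3)
        assert res.statistic == pytest.approx(0.4865, abs=1e-3)
        assert res.df == 1

    def test_identical_groups_give_zero(self):
        times, events = [1, 2, 3, 4], [1, 0, 1, 1]
        rec = make_survival_frame(times + times, events + events)
        res = logrank_test(rec, ["A"] * 4 + ["B"] * 4)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_invariant_to_monotone_time_transform(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(1, 40) + 0.01
        e = rng.integers(0, 2, 40)
        g = rng.integers(0, 2, 40)
        r1 = logrank_test(make_survival_frame(t, e), g)
        r2 = logrank_test(make_survival_frame(np.exp(t), e), g)
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-12)

    def test_empty_group_is_error(self):
        rec = make_survival_frame([1, 2], [1, 1])
        with pytest.raises(SurvivalError):
            logrank_test(rec, ["A", "A"])


def _efron_partial_loglik(beta, x, time, event):
    """Independent oracle: direct Efron partial log-likelihood."""
    ll = 0.0
    for t in np.unique(time[event == 1]):
        D = np.flatnonzero((time == t) & (event == 1))
        R = np.flatnonzero(time >= t)
        d = len(D)
        sum_d = np.exp(beta * x[D]).sum()
        sum_r = np.exp(beta * x[R]).sum()
        ll += beta * x[D].sum()
        for l in range(d):
            ll -= np.log(sum_r - (l / d) * sum_d)
    return ll


class TestCox:
    def test_coefficient_matches_grid_search_of_partial_likelihood(self):
        # x=1: {1e, 4e}; x=0: {2e, 3c, 5e}
        rec = make_survival_frame([1, 4, 2, 3, 5], [1, 1, 1, 0, 1])
        x = np.array([1.0, 1.0, 0.0, 0.0, 0.0])
        fit = cox_fit(rec, pd.DataFrame({"x": x}, index=rec.index))
        grid = np.arange(-5, 5, 1e-4)
        ll = [
            _efron_partial_loglik(b, x, rec["time"].to_numpy(), rec["event"].to_numpy())
            for b in grid
        ]
        beta_grid = grid[int(np.argmax(ll))]
        assert fit.table.loc["x", "coef"] == pytest.approx(beta_grid, abs=1e-3)
        # oracle also validates the reported log-likelihood
        assert fit.log_likelihood == pytest.approx(max(ll), abs=1e-4)

    def test_breslow_matches_its_own_grid_search(self):
        rec = make_survival_frame([1, 4, 2, 3, 5], [1, 1, 1, 0, 1])
        x = np.array([1.0, 1.0, 0.0, 0.0, 0.0])
        fit = cox_fit(rec, pd.DataFrame({"x": x}, index=rec.index), ties="breslow")

        def breslow_ll(beta):
            t, e = rec["time"].to_numpy(), rec["event"].to_numpy()
            ll = 0.0
            for i in np.flatnonzero(e == 1):
                R = t >= t[i]
                ll += beta * x[i] - np.log(np.exp(beta * x[R]).sum())
            return ll

        grid = np.arange(-5, 5, 1e-4)
        ll = [breslow_ll(b) for b in grid]
        assert fit.table.loc["x", "coef"] == pytest.approx(
            grid[int(np.argmax(ll))], abs=1e-3
        )

    def test_hr_and_ci_consistency(self):
        rng = np.random.default_rng(7)
        n = 120
        x = rng.normal(size=n)
        t = rng.exponential(np.exp(-0.8 * x))
        rec = make_survival_frame(t + 1e-9, np.ones(n))
        fit = cox_fit(rec, pd.DataFrame({"x": x}, index=rec.index))
        row = fit.table.loc["x"]
        assert row["hr"] == pytest.approx(np.exp(row["coef"]))
        assert row["ci_lower"] < row["hr"] < row["ci_upper"]

    def test_constant_covariate_is_error(self):
        rec = make_survival_frame([1, 2, 3, 4], [1, 1, 0, 1])
        with pytest.raises(SurvivalError, match="constant"):
            cox_fit(rec, pd.DataFrame({"x": [1.0] * 4}, index=rec.index))

    @pytest.mark.parametrize("ties", ["efron", "breslow"])
    def test_dataset_duplication_scales_se_not_coef(self, ties):
        """Doubling every record: coefficient unchanged, SE shrinks ~1/sqrt(2).

        Exact for Breslow (the partial likelihood literally doubles);
        Efron's tie correction perturbs the duplicated risk sets slightly,
        so its check is to ~1%.
        """
        rng = np.random.default_rng(11)
        n = 80
        x = rng.normal(size=n)
        t = rng.exponential(np.exp(-x))
        c = rng.uniform(0, 2, n)
        rec = make_survival_frame(np.minimum(t, c) + 1e-9, (t <= c).astype(int))
        X = pd.DataFrame({"x": x}, index=rec.index)
        fit1 = cox_fit(rec, X, ties=ties)
        rec2 = pd.concat([rec, rec.set_index(rec.index + "d")])
        X2 = pd.concat([X, X.set_index(X.index + "d")])
        fit2 = cox_fit(rec2, X2, ties=ties)
        tol = 1e-6 if ties == "breslow" else 1e-2
        assert fit2.table.loc["x", "coef"] == pytest.approx(
            fit1.table.loc["x", "coef"], abs=tol
        )
        assert fit2.table.loc["x", "se"] == pytest.approx(
            fit1.table.loc["x", "se"] / np.sqrt(2), rel=2e-2
        )

    @pytest.mark.parametrize("ties", ["efron", "breslow"])
    def test_stratified_fit_runs_and_respects_strata(self, ties):
        rng = np.random.default_rng(13)
        n = 100
        x = rng.normal(size=n)
        stratum = rng.integers(0, 2, n)
        # stratum 1 has a much higher baseline hazard
        t = rng.exponential(np.exp(-x) / np.where(stratum == 1, 5.0, 1.0))
        rec = make_survival_frame(t + 1e-9, np.ones(n))
        X = pd.DataFrame({"x": x}, index=rec.index)
        fit = cox_fit(rec, X, strata=pd.Series(stratum, index=rec.index), ties=ties)
        assert fit.strata == ["0", "1"]
        assert np.isfinite(fit.table.loc["x", "coef"])

    def test_efron_and_breslow_agree_without_ties(self):
        rng = np.random.default_rng(17)
        n = 60
        x = rng.normal(size=n)
        t = rng.exponential(np.exp(-0.5 * x))  # continuous: no ties
        rec = make_survival_frame(t + 1e-9, np.ones(n))
        X = pd.DataFrame({"x": x}, index=rec.index)
        fe = cox_fit(rec, X, ties="efron")
        fb = cox_fit(rec, X, ties="breslow")
        assert fe.table.loc["x", "coef"] == pytest.approx(
            fb.table.loc["x", "coef"], abs=1e-5
        )
        assert fe.log_likelihood == pytest.approx(fb.log_likelihood, abs=1e-5)


class TestHarrellC:
    def test_perfect_anti_ordering(self):
        rec = make_survival_frame([1, 2, 3, 4], [1, 1, 1, 1])
        risk = np.array([4.0, 3.0, 2.0, 1.0])  # highest risk fails first
        assert harrell_c(rec, risk) == pytest.approx(1.0)

    def test_all_tied_scores_give_half(self):
        rec = make_survival_frame([1, 2, 3, 4], [1, 1, 1, 1])
        assert harrell_c(rec, np.ones(4)) == pytest.approx(0.5)

    def test_matches_all_pairs_double_loop(self):
        rng = np.random.default_rng(23)
        n = 30
        t = rng.exponential(1, n) + 0.01
        e = rng.integers(0, 2, n)
        risk = rng.normal(size=n)
        rec = make_survival_frame(t, e)
        conc = comp = 0.0
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                # pair comparable iff the earlier time is an event
                if t[i] < t[j] and e[i] == 1:
                    comp += 1
                    if risk[i] > risk[j]:
                        conc += 1
                    elif risk[i] == risk[j]:
                        conc += 0.5
        assert harrell_c(rec, risk) == pytest.approx(conc / comp, abs=1e-12)


class TestLRT:
    def _fits(self, seed=0, beta2=0.0, n=150):
        rng = np.random.default_rng(seed)
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        t = rng.exponential(np.exp(-0.5 * x1 - beta2 * x2))
        c = rng.uniform(0, 3, n)
        rec = make_survival_frame(np.minimum(t, c) + 1e-9, (t <= c).astype(int))
        red = cox_fit(rec, pd.DataFrame({"x1": x1}, index=rec.index))
        full = cox_fit(rec, pd.DataFrame({"x1": x1, "x2": x2}, index=rec.index))
        return red, full

    def test_identical_models_give_zero(self):
        red, _ = self._fits()
        res = lr_test(red, red)
        assert res.chi2 == pytest.approx(0.0)
        assert res.p_value == 1.0

    def test_chi2_equals_twice_loglik_gain(self):
        red, full = self._fits(seed=5, beta2=0.8)
        res = lr_test(red, full)
        assert res.chi2 == pytest.approx(
            2 * (full.log_likelihood - red.log_likelihood)
        )
        assert res.df == 1
        assert res.p_value == pytest.approx(stats.chi2.sf(res.chi2, 1))

    def test_true_effect_detected_with_high_power(self):
        rejections = sum(
            lr_test(*self._fits(seed=100 + i, beta2=1.0, n=200)).p_value < 0.05
            for i in range(40)
        )
        assert rejections >= 36  # >= 0.9 power

    def test_non_nested_is_error(self):
        red, full = self._fits()
        with pytest.raises(SurvivalError, match="nested"):
            lr_test(full, red)


class TestFindCutoff:
    def test_planted_gap_recovered(self):
        rng = np.random.default_rng(41)
        n = 100
        low = rng.uniform(0.0, 0.4, n // 2)   # hazard 2.0 (worse)
        high = rng.uniform(0.6, 1.0, n // 2)  # hazard 0.4 (better)
        scores = np.concatenate([low, high])
        rate = np.where(scores < 0.5, 2.0, 0.4)
        t = rng.exponential(1 / rate)
        c = rng.uniform(0, 5, n)
        rec = make_survival_frame(np.minimum(t, c) + 1e-9, (t <= c).astype(int))
        s = pd.Series(scores, index=rec.index)
        model = find_cutoff(s, rec, n_permutations=200, seed=1)
        assert 0.4 < model.threshold < 0.6
        assert model.p_adjusted < 0.05

    def test_maximum_attained_over_exhaustive_scan(self):
        """The selected cutpoint attains the max statistic among all
        admissible candidates, verified with per-candidate lifelines tests."""
        rng = np.random.default_rng(43)
        n = 60
        scores = rng.normal(size=n)
        t = rng.exponential(np.exp(-0.5 * scores))
        rec = make_survival_frame(t + 1e-9, np.ones(n))
        s = pd.Series(scores, index=rec.index)
        model = find_cutoff(s, rec, min_group_size=5, n_permutations=50, seed=2)
        lo, hi = np.quantile(scores, (0.10, 0.90))
        best_stat, best_c = -np.inf, None
        for c in np.unique(scores[(scores >= lo) & (scores <= hi)]):
            gh = scores > c
            if gh.sum() < 5 or (~gh).sum() < 5:
                continue
            res = logrank_test(rec, gh.astype(int))
            z = np.sqrt(res.statistic)
            if z > best_stat:
                best_stat, best_c = z, c
        # the reported threshold is the gap midpoint above the best observed
        # candidate: it must induce the same split and attain the same max
        assert ((scores > model.threshold) == (scores > best_c)).all()
        assert model.max_statistic == pytest.approx(best_stat, abs=1e-8)

    def test_min_group_size_respected(self):
        rng = np.random.default_rng(47)
        n = 50
        s = pd.Series(rng.normal(size=n), index=[f"s{i}" for i in range(n)])
        rec = make_survival_frame(rng.exponential(1, n) + 0.01, np.ones(n))
        model = find_cutoff(s, rec, min_group_size=15, n_permutations=20, seed=0)
        n_high = (s > model.threshold).sum()
        assert n_high >= 15 and n - n_high >= 15

    def test_constant_scores_error(self):
        rec = make_survival_frame(np.arange(1, 41, dtype=float), np.ones(40))
        s = pd.Series(np.ones(40), index=rec.index)
        with pytest.raises(SurvivalError, match="constant"):
            find_cutoff(s, rec)


class TestRecodeCovariates:
    @pytest.fixture
    def clinical(self):
        rows = [
            # sid,  T,    N,   M,   G,     necrosis, size
            ("p1", "1", "0", "0", "1", "absent", 4.0),   # reference row
            ("p2", "2", "1", "0", "2", "present", 6.0),
            ("p3", "3", "0", "1", "2-3", "absent", 11.0),  # G2-3 -> G3
            ("p4", "3", "2", "0", "4", "present", 9.0),    # G4 -> G3
            ("p5", "1", "0", "X", "2", "absent", 5.0),     # MX -> excluded
            ("p6", "4", "0", "0", "X", "absent", 3.0),     # GX -> excluded
            ("p7", "1", "0", "0", None, "absent", 2.0),    # missing grade
            ("p8", "3", "1", "1", "3", "present", 12.0),
            ("p9", "2", "0", "0", "G2", "absent", 7.0),    # prefixed token
            ("p10", "1", "0", "1", "1", "present", 8.0),
        ]
        return pd.DataFrame(
            rows, columns=["sample_id", "T", "N", "M", "G", "necrosis", "size_cm"]
        ).set_index("sample_id")

    def test_footnote_rules_on_constructed_table(self, clinical):
        out, report = recode_covariates(clinical)
        # exclusions: MX and missing/X grade
        assert set(report["sample_id"]) == {"p5", "p6", "p7"}
        assert report.set_index("sample_id").loc["p5", "reason"] == "MX"
        assert report.set_index("sample_id").loc["p6", "reason"] == "missing_grade"
        # grade folding: G2-3 and G4 -> G3 indicator
        assert out.loc["p3", "G3"] == 1 and out.loc["p3", "G2"] == 0
        assert out.loc["p4", "G3"] == 1
        # reference row has all indicators zero
        ref_cols = ["T2", "T3", "T4", "N1", "N2", "M1", "G2", "G3"]
        assert (out.loc["p1", ref_cols] == 0).all()
        # spot checks
        assert out.loc["p2", ["T2", "N1", "G2"]].tolist() == [1, 1, 1]
        assert out.loc["p8", ["T3", "N1", "M1", "G3"]].tolist() == [1, 1, 1, 1]
        assert out.loc["p9", "G2"] == 1
        assert out.loc["p10", "M1"] == 1
        assert out.loc["p2", "necrosis"] == 1 and out.loc["p1", "necrosis"] == 0

    def test_no_errors_only_reported_exclusions(self, clinical):
        out, report = recode_covariates(clinical)
        assert len(out) + len(report) == len(clinical)
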