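import math

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter
from lifelines.statistics import multivariate_logrank_test

from pairedprog import survival
from pairedprog.synthetic_data import (
    SimulationConfig,
    generate_cohort,
    generate_validation_cohort,
)


def make_stats(p, effect, genes=None):
    genes = genes or [f"g{i}" for i in range(len(p))]
    return pd.DataFrame({"p": p, "mean_paired_diff": effect}, index=genes)


class TestDeriveSignature:
    def test_alpha_one_assigns_all_nonzero_genes_by_sign(self):
        stats = make_stats([0.5, 0.9, 0.2, 0.7], [1.0, -2.0, 0.0, 0.5])
        sig = survival.derive_signature(stats, alpha=1.0)
        assert sig.up_genes == {"g0", "g3"}
        assert sig.down_genes == {"g1"}
        # zero-effect gene excluded from both sides
        assert "g2" not in sig.genes

    def test_reproduces_fifteen_up_fiftythree_down_split(self):
        # stats constructed so exactly 15 up and 53 down pass p < 0.001
        n_up, n_down, n_null = 15, 53, 500
        p = [1e-5] * (n_up + n_down) + [0.5] * n_null
        eff = [1.0] * n_up + [-1.0] * n_down + [0.1] * n_null
        sig = survival.derive_signature(make_stats(p, eff), alpha=0.001)
        assert (len(sig.up_genes), len(sig.down_genes)) == (15, 53)
        assert len(sig) == 68

    def test_empty_signature_rejected_with_advice(self):
        stats = make_stats([0.5, 0.6], [1.0, -1.0])
        with pytest.raises(ValueError, match="alpha"):
            survival.derive_signature(stats, alpha=0.001)


class TestMedianCenter:
    def test_row_arithmetic(self):
        m = pd.DataFrame({"a": [1.0], "b": [2.0], "c": [9.0]}, index=["g"])
        out = survival.median_center(m)
        assert list(out.loc["g"]) == [-1.0, 0.0, 7.0]

    def test_single_sample_becomes_zero(self):
        m = pd.DataFrame({"only": [3.0, -2.0]})
        assert (survival.median_center(m) == 0).all().all()

    def test_idempotent(self, rng):
        m = pd.DataFrame(rng.normal(size=(20, 7)))
        once = survival.median_center(m)
        assert np.allclose(once, survival.median_center(once))


class TestTScore:
    @pytest.fixture()
    def sig(self):
        return survival.Signature(
            frozenset({"u1", "u2", "u3"}), frozenset({"d1", "d2", "d3"}), 0.001
        )

    def test_equal_up_and_down_values_give_zero(self, sig):
        profile = pd.Series(1.0, index=["u1", "u2", "u3", "d1", "d2", "d3"])
        assert survival.t_score(profile, sig) == pytest.approx(0.0)

    def test_degenerate_zero_variance_gets_floor_not_inf(self, sig):
        profile = pd.Series(
            [1.0, 1.0, 1.0, -1.0, -1.0, -1.0],
            index=["u1", "u2", "u3", "d1", "d2", "d3"],
        )
        score = survival.t_score(profile, sig)
        assert math.isfinite(score)
        assert score > 1e3  # large sentinel via variance floor

    def test_hand_computed_pooled_formula(self, sig):
        up = np.array([2.0, 1.0, 0.0])
        down = np.array([-1.0, 0.0, -2.0])
        profile = pd.Series(
            np.concatenate([up, down]), index=["u1", "u2", "u3", "d1", "d2", "d3"]
        )
        s2 = (up.var(ddof=1) * 2 + down.var(ddof=1) * 2) / 4
        expected = (up.mean() - down.mean()) / math.sqrt(s2 * (2 / 3))
        assert survival.t_score(profile, sig) == pytest.approx(expected)

    def test_invariant_to_constant_profile_shift(self, sig, rng):
        profile = pd.Series(
            rng.normal(size=6), index=["u1", "u2", "u3", "d1", "d2", "d3"]
        )
        a = survival.t_score(profile, sig)
        b = survival.t_score(profile + 7.5, sig)
        assert a == pytest.approx(b)

    def test_insufficient_overlap_gives_nan(self, sig):
        profile = pd.Series([1.0, 2.0], index=["u1", "d1"])
        assert math.isnan(survival.t_score(profile, sig))


class TestScoreCohort:
    def test_signature_like_samples_occupy_top_tertile(self):
        sig = survival.Signature(
            frozenset({"u1", "u2"}), frozenset({"d1", "d2"}), 0.001
        )
        pattern = pd.Series([1.0, 1.2, -1.0, -0.8], index=["u1", "u2", "d1", "d2"])
        cols = {f"plus{i}": pattern + np.random.default_rng(i).normal(0, 0.1, 4)
                for i in range(3)}
        cols |= {f"minus{i}": -pattern + np.random.default_rng(10 + i).normal(0, 0.1, 4)
                 for i in range(3)}
        m = pd.DataFrame(cols)
        scored = survival.score_cohort(m, sig)
        assert set(scored.index[scored["tertile"] == "high"]) <= {
            "plus0", "plus1", "plus2"
        }

    def test_sample_order_permutation_leaves_scores_unchanged(self, rng):
        sig = survival.Signature(
            frozenset({"g0", "g1", "g2"}), frozenset({"g3", "g4", "g5"}), 0.01
        )
        m = pd.DataFrame(rng.normal(size=(6, 9)), index=[f"g{i}" for i in range(6)])
        a = survival.score_cohort(m, sig)["t_score"]
        b = survival.score_cohort(m[list(m.columns[::-1])], sig)["t_score"]
        assert np.allclose(a.sort_index(), b.sort_index())

    def test_tertile_sizes_differ_by_at_most_one(self, rng):
        sig = survival.Signature(
            frozenset({"g0", "g1"}), frozenset({"g2", "g3"}), 0.01
        )
        for n in (7, 8, 9):
            m = pd.DataFrame(rng.normal(size=(4, n)), index=[f"g{i}" for i in range(4)])
            counts = survival.score_cohort(m, sig)["tertile"].value_counts()
            assert counts.max() - counts.min() <= 1


class TestKaplanMeier:
    def test_no_events_curve_stays_at_one(self):
        out = survival.km_estimate([5.0, 6.0, 7.0], [0, 0, 0])
        assert (out["survival"] == 1.0).all()

    def test_three_events_product_limit(self):
        out = survival.km_estimate([1.0, 2.0, 3.0], [1, 1, 1])
        assert np.allclose(out["survival"], [2 / 3, 1 / 3, 0.0])

    def test_censoring_handled_after_events(self):
        out = survival.km_estimate([1.0, 5.0, 5.0, 5.0], [1, 0, 0, 0])
        assert out.loc[out["time"] == 1.0, "survival"].iloc[0] == pytest.approx(0.75)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            survival.km_estimate([], [])


class TestLogrank:
    def test_identical_groups_give_null_result(self):
        t = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        e = [1, 1, 0, 1, 1, 0]
        g = ["a", "a", "a", "b", "b", "b"]
        res = survival.logrank_test(t, e, g)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_hand_computed_two_group_example(self):
        # group A events at 1, 2, 3; group B censored at 4, 4, 4
        t = np.array([1.0, 2.0, 3.0, 4.0, 4.0, 4.0])
        e = np.array([1, 1, 1, 0, 0, 0])
        g = np.array(["A", "A", "A", "B", "B", "B"])
        # by hand: event times 1, 2, 3 with O_A = 3,
        # E_A = 3/6 + 2/5 + 1/4 = 1.15, V = sum of hypergeometric variances
        v = (1 * (3 / 6) * (3 / 6) * (6 - 1) / (6 - 1)) + (
            1 * (2 / 5) * (3 / 5) * (5 - 1) / (5 - 1)
        ) + (1 * (1 / 4) * (3 / 4) * (4 - 1) / (4 - 1))
        chi2 = (3 - 1.15) ** 2 / v
        res = survival.logrank_test(t, e, g)
        assert res.chi2 == pytest.approx(chi2, rel=1e-12)

    def test_agrees_with_lifelines_multigroup(self, rng):
        n = 60
        t = rng.exponential(10, n)
        e = (rng.random(n) < 0.7).astype(int)
        g = rng.choice(["a", "b", "c"], n)
        mine = survival.logrank_test(t, e, g)
        theirs = multivariate_logrank_test(t, g, e)
        assert mine.chi2 == pytest.approx(theirs.test_statistic, rel=1e-9)
        assert mine.p == pytest.approx(theirs.p_value, rel=1e-9)

    def test_stratified_one_stratum_equals_unstratified(self, rng):
        n = 40
        t = rng.exponential(5, n)
        e = (rng.random(n) < 0.6).astype(int)
        g = rng.choice(["x", "y"], n)
        plain = survival.logrank_test(t, e, g)
        strat = survival.logrank_test(t, e, g, strata=np.zeros(n))
        assert plain.chi2 == pytest.approx(strat.chi2)

    def test_strata_equal_to_group_rejected(self):
        t = [1.0, 2.0, 3.0, 4.0]
        e = [1, 1, 1, 1]
        g = ["a", "a", "b", "b"]
        with pytest.raises(ValueError):
            survival.logrank_test(t, e, g, strata=g)

    def test_no_events_warns_p_one(self):
        res = survival.logrank_test([1.0, 2.0], [0, 0], ["a", "b"])
        assert res.p == 1.0

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            survival.logrank_test([1.0, 2.0], [1, 1], ["a", "a"])


class TestCox:
    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError):
            survival.cox_fit([1.0, 1.0, 1.0], [1.0, 2.0, 3.0], [1, 1, 1])

    def test_score_test_equals_logrank_for_binary_covariate(self, rng):
        n = 80
        x = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(1.0 / np.exp(0.7 * x)) + rng.uniform(0, 1e-9, n)
        e = (rng.random(n) < 0.8).astype(int)
        fit = survival.cox_fit(x, t, e)
        lr = survival.logrank_test(t, e, x)
        assert abs(fit.score_chi2 - lr.chi2) < 1e-6

    def test_beta_matches_lifelines_on_untied_data(self, rng):
        n = 100
        x = rng.normal(size=n)
        t = rng.exponential(1.0 / np.exp(0.5 * x))
        e = (rng.random(n) < 0.75).astype(int)
        fit = survival.cox_fit(x, t, e)
        ref = CoxPHFitter().fit(
            pd.DataFrame({"t": t, "e": e, "x": x}), "t", "e"
        )
        assert fit.beta == pytest.approx(ref.params_["x"], abs=1e-5)
        assert fit.se == pytest.approx(ref.standard_errors_["x"], abs=1e-5)

    def test_stratified_fit_matches_lifelines_strata(self, rng):
        n = 120
        x = rng.normal(size=n)
        strata = rng.choice(["s1", "s2", "s3"], n)
        base = np.where(strata == "s1", 1.0, np.where(strata == "s2", 3.0, 0.5))
        t = rng.exponential(base / np.exp(0.6 * x))
        e = (rng.random(n) < 0.8).astype(int)
        fit = survival.cox_fit(x, t, e, strata=strata)
        df = pd.DataFrame({"t": t, "e": e, "x": x, "s": strata})
        ref = CoxPHFitter().fit(df, "t", "e", strata=["s"])
        assert fit.beta == pytest.approx(ref.params_["x"], abs=1e-4)

    def test_efron_and_breslow_agree_without_ties(self, rng):
        n = 50
        x = rng.normal(size=n)
        t = rng.exponential(1.0, n)
        e = np.ones(n, dtype=int)
        b = survival.cox_fit(x, t, e, ties="breslow")
        f = survival.cox_fit(x, t, e, ties="efron")
        assert b.beta == pytest.approx(f.beta, abs=1e-9)

    def test_perfect_separation_flagged(self):
        # covariate perfectly orders the event times: monotone likelihood
        t = np.arange(1.0, 21.0)
        e = np.ones(20, dtype=int)
        x = -t
        with pytest.raises(FloatingPointError):
            survival.cox_fit(x, t, e)


class TestValidationRecovery:
    def test_hazard_ratio_recovered_from_latent_score(self):
        cfg = SimulationConfig(seed=0, n_validation_patients=300)
        cohort = generate_cohort(cfg)
        expr, clin, truth = generate_validation_cohort(cfg, cohort.truth)
        z = np.array([truth.true_scores[s] for s in clin["sample_id"]])
        fit = survival.cox_fit(
            z, clin["os_time"].to_numpy(float), clin["os_event"].to_numpy(int)
        )
        assert 1.5 <= fit.hr <= 2.7
        assert fit.p_wald < 0.05

    def test_cox_beta_sign_matches_logrank_direction(self, rng):
        n = 100
        x = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(1.0 / np.exp(0.8 * x))
        e = np.ones(n, dtype=int)
        fit = survival.cox_fit(x, t, e)
        res = survival.logrank_test(t, e, x)
        # group 1 has more events than expected iff beta > 0
        excess = res.observed["1.0"] - res.expected["1.0"]
        assert math.copysign(1, fit.beta) == math.copysign(1, excess)


class TestPerGeneScan:
    def test_latent_hazard_gene_has_smallest_p(self):
        cfg = SimulationConfig(seed=2, n_validation_patients=200)
        cohort = generate_cohort(cfg)
        expr, clin, truth = generate_validation_cohort(cfg, cohort.truth)
        z = pd.Series(truth.true_scores)
        m = expr.copy()
        m.loc["latent"] = z[m.columns].to_numpy()
        genes = ["latent"] + list(cohort.truth.planted_up[:5]) + ["G01500"]
        scan = survival.per_gene_outcome_scan(
            m, clin.set_index("sample_id"), genes, strata_col="histology"
        )
        assert scan["p"].idxmin() == "latent"

    def test_empty_gene_list_gives_empty_table(self):
        clin = pd.DataFrame(
            {"os_time": [1.0], "os_event": [1], "histology": ["x"]}, index=["s"]
        )
        m = pd.DataFrame({"s": [0.0]}, index=["g"])
        out = survival.per_gene_outcome_scan(m, clin, [], strata_col="histology")
        assert out.empty

    def test_null_gene_calibration_roughly_five_percent(self, rng):
        n = 150
        t = rng.exponential(10, n)
        e = (rng.random(n) < 0.7).astype(int)
        clin = pd.DataFrame(
            {"os_time": t, "os_event": e, "histology": ["h"] * n},
            index=[f"s{i}" for i in range(n)],
        )
        m = pd.DataFrame(
            rng.normal(size=(60, n)),
            index=[f"g{i}" for i in range(60)],
            columns=clin.index,
        )
        scan = survival.per_gene_outcome_scan(m, clin, list(m.index), None)
        assert (scan["p"] < 0.05).mean() <= 0.15
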