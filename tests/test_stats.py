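"""Tests of the cohort statistics: mixed models, repeatability, GLMs, effect sizes."""

import warnings

import numpy as np
import pytest
import scipy.stats

from torporlab import (
    BatRecord,
    Bout,
    SimulationConfig,
    cohens_d,
    fit_count_glm,
    fit_drink_proportion_glm,
    fit_duration_mixed_model,
    fit_mass_loss_glm,
    repeatability,
    simulate_cohort,
    welch_t,
)


def records(counts_by_treatment, masses=None, drinks=None, with_drink=None):
    out = []
    i = 0
    for tr, counts in counts_by_treatment.items():
        for j, c in enumerate(counts):
            out.append(
                BatRecord(
                    bat_id=f"{tr}{j}",
                    treatment=tr,
                    initial_mass=(masses or {}).get(tr, [25.0] * len(counts))[j],
                    final_mass=20.0,
                    n_arousals=c,
                    n_drinks=(drinks or {}).get(tr, [0] * len(counts))[j],
                    n_arousals_with_drink=(with_drink or {}).get(tr, [0] * len(counts))[j],
                    n_arousals_without_drink=c
                    - (with_drink or {}).get(tr, [0] * len(counts))[j],
                )
            )
            i += 1
    return out


class TestRepeatability:
    def test_balanced_hand_case_anova(self):
        res = repeatability([("A", 1), ("A", 3), ("B", 5), ("B", 7)], method="anova")
        assert res.v_individual == pytest.approx(7.0)
        assert res.v_residual == pytest.approx(2.0)
        assert res.r == pytest.approx(7 / 9)

    def test_reml_matches_anova_on_balanced_data(self):
        data = [("A", 1), ("A", 3), ("B", 5), ("B", 7)]
        reml = repeatability(data, method="reml")
        assert reml.v_individual == pytest.approx(7.0, rel=1e-4)
        assert reml.r == pytest.approx(7 / 9, rel=1e-4)

    def test_identical_within_bat_gives_r_one(self):
        res = repeatability(
            [("A", 2), ("A", 2), ("B", 5), ("B", 5), ("C", 9), ("C", 9)],
            method="anova",
        )
        assert res.r == pytest.approx(1.0)
        assert res.v_residual == 0.0

    def test_single_observations_rejected(self):
        with pytest.raises(ValueError):
            repeatability([("A", 1), ("B", 2), ("C", 3)])

    def test_variance_recovery_large_sample(self):
        """V_I = V_Res = 1 on 200 bats × 10 obs: r̂ near 0.5."""
        rng = np.random.default_rng(13)
        data = []
        for i in range(200):
            u = rng.normal()
            data += [(f"b{i}", u + rng.normal()) for _ in range(10)]
        res = repeatability(data)
        assert res.r == pytest.approx(0.5, abs=0.05)
        assert res.lrt_p < 1e-6

    def test_r_monotone_in_individual_variance(self):
        from torporlab import RepeatabilityResult

        rs = [
            RepeatabilityResult(v, 1.0, 0.0, 1.0).r for v in (0.0, 0.5, 1.0, 4.0)
        ]
        assert rs[0] == 0.0
        assert all(a < b for a, b in zip(rs[:-1], rs[1:]))
        assert RepeatabilityResult(1.0, 0.0, 0.0, 1.0).r == 1.0


def duration_bouts(rng, n_bats_per_tr=12, bouts_per_bat=8, delta=0.3, sd_bat=0.2):
    """Arousal bouts whose sqrt(hours) follow 3 + delta·[dry] + bat + noise."""
    bouts, bats = [], []
    for tr, shift in (("humid", 0.0), ("dry", delta)):
        for i in range(n_bats_per_tr):
            bat = f"{tr}{i}"
            bats.append(
                BatRecord(bat_id=bat, treatment=tr, initial_mass=25.0 + rng.normal(),
                          final_mass=20.0)
            )
            b_i = rng.normal(0, sd_bat)
            t = 0.0
            for _ in range(bouts_per_bat):
                sqrt_h = 3.0 + shift + b_i + rng.normal(0, 0.3)
                dur_min = (sqrt_h**2) * 60.0
                bouts.append(Bout(bat, "arousal", "behaviour", t, t + dur_min))
                t += dur_min + 1000
    return bouts, bats


class TestMixedModel:
    def test_treatment_effect_recovered_within_3_se(self):
        rng = np.random.default_rng(21)
        bouts, bats = duration_bouts(rng, delta=0.3)
        fit = fit_duration_mixed_model(bouts, bats, "arousal_h")
        term = "C(treatment)[T.humid]"  # humid vs dry baseline: -delta
        est = fit.coef(term)
        se = float(fit.table.loc[term, "se"])
        assert abs(est - (-0.3)) < 3 * se

    def test_null_rejection_rate_bounded(self):
        """Permuted labels: the treatment effect is spurious ≤ α-ish often."""
        rng = np.random.default_rng(22)
        n_rej = 0
        reps = 30
        for _ in range(reps):
            bouts, bats = duration_bouts(rng, n_bats_per_tr=8, bouts_per_bat=6,
                                         delta=0.0)
            fit = fit_duration_mixed_model(bouts, bats, "arousal_h")
            n_rej += fit.pvalue("C(treatment)[T.humid]") < 0.05
        assert n_rej <= scipy.stats.binom.ppf(0.999, reps, 0.05) + 1

    def test_constant_durations_degenerate(self):
        bats = [
            BatRecord(bat_id=f"b{i}", treatment=tr, initial_mass=25.0 + i,
                      final_mass=20.0)
            for i, tr in enumerate(["humid"] * 3 + ["dry"] * 3)
        ]
        bouts = [
            Bout(b.bat_id, "arousal", "behaviour", k * 200.0, k * 200.0 + 120.0)
            for b in bats
            for k in range(4)
        ]
        fit = fit_duration_mixed_model(bouts, bats, "arousal_h")
        assert fit.coef("C(treatment)[T.humid]") == pytest.approx(0.0, abs=1e-8)
        assert fit.extras["v_individual"] == pytest.approx(0.0, abs=1e-6)
        assert fit.extras["singular"]

    def test_censored_bouts_excluded(self):
        rng = np.random.default_rng(23)
        bats = [
            BatRecord(bat_id=f"b{i}", treatment=tr, initial_mass=24.0 + i,
                      final_mass=20.0)
            for i, tr in enumerate(["humid", "humid", "dry", "dry"])
        ]
        bouts = []
        for b in bats:
            bouts.append(Bout(b.bat_id, "arousal", "behaviour", 0, 120,
                              left_censored=True))
            bouts += [
                Bout(b.bat_id, "arousal", "behaviour", 1000 * (k + 1),
                     1000 * (k + 1) + 120 + float(rng.uniform(0, 30)))
                for k in range(3)
            ]
        fit = fit_duration_mixed_model(bouts, bats, "arousal_h")
        assert fit.extras["n_bouts"] == 12  # 3 per bat, censored dropped


class TestCountGlm:
    def test_identical_groups_rate_ratio_one(self):
        recs = records({"humid": [5, 7, 9], "dry": [5, 7, 9]})
        fit = fit_count_glm(recs, "arousals")
        assert fit.extras["rate_ratio"] == pytest.approx(1.0, abs=1e-8)
        assert fit.pvalue("C(treatment)[T.humid]") > 0.9

    def test_treatment_only_matches_closed_form_mean_ratio(self):
        recs = records({"humid": [4, 6, 8, 10], "dry": [6, 9, 12, 21]})
        fit = fit_count_glm(recs, "arousals", include_mass=False)
        assert fit.extras["rate_ratio"] == pytest.approx(7.0 / 12.0, rel=1e-8)

    def test_rate_ratio_recovery_within_3_se(self):
        rng = np.random.default_rng(31)
        lam_h, lam_d = 10.0, 15.2
        recs = records(
            {
                "humid": list(rng.poisson(lam_h, 50)),
                "dry": list(rng.poisson(lam_d, 50)),
            },
            masses={"humid": list(rng.uniform(22, 30, 50)),
                    "dry": list(rng.uniform(22, 30, 50))},
        )
        fit = fit_count_glm(recs, "arousals")
        term = "C(treatment)[T.humid]"
        est, se = fit.coef(term), float(fit.table.loc[term, "se"])
        assert abs(est - np.log(lam_h / lam_d)) < 3 * se

    def test_single_bat_group_refused(self):
        recs = records({"humid": [5], "dry": [5, 6]})
        with pytest.raises(ValueError):
            fit_count_glm(recs, "arousals")


class TestProportionGlm:
    def test_even_proportions_odds_ratio_one(self):
        recs = records(
            {"humid": [10, 10], "dry": [10, 10]},
            with_drink={"humid": [5, 5], "dry": [5, 5]},
        )
        fit = fit_drink_proportion_glm(recs, include_mass=False)
        assert fit.extras["odds_ratio"] == pytest.approx(1.0, abs=1e-8)

    def test_treatment_only_matches_pooled_odds_ratio(self):
        recs = records(
            {"humid": [10, 10], "dry": [10, 10]},
            with_drink={"humid": [3, 5], "dry": [7, 8]},
        )
        fit = fit_drink_proportion_glm(recs, include_mass=False)
        # pooled tables: humid 8/12, dry 15/5
        expected = (15.0 / 5.0) / (8.0 / 12.0)
        term = "C(treatment)[T.humid]"
        assert np.exp(-fit.coef(term)) == pytest.approx(expected, rel=1e-8)

    def test_log_odds_recovery_within_3_se(self):
        rng = np.random.default_rng(32)
        n = 40
        recs = records(
            {"humid": [12] * n, "dry": [12] * n},
            with_drink={
                "humid": list(rng.binomial(12, 0.5, n)),
                "dry": list(rng.binomial(12, scipy.special.expit(1.0), n)),
            },
            masses={"humid": list(rng.uniform(22, 30, n)),
                    "dry": list(rng.uniform(22, 30, n))},
        )
        fit = fit_drink_proportion_glm(recs)
        term = "C(treatment)[T.humid]"
        est, se = fit.coef(term), float(fit.table.loc[term, "se"])
        assert abs(est - (-1.0)) < 3 * se

    def test_zero_arousal_bats_excluded_with_warning(self):
        recs = records(
            {"humid": [10, 0, 10], "dry": [10, 10]},
            with_drink={"humid": [5, 0, 5], "dry": [5, 5]},
        )
        with pytest.warns(UserWarning, match="zero arousals"):
            fit_drink_proportion_glm(recs)


class TestMassLossGlm:
    def test_initial_mass_slope_sign_recovered_across_seeds(self):
        """Generator regime (n=19): heavier animals lose more mass."""
        n_pos = 0
        for seed in range(8):
            bundle = simulate_cohort(SimulationConfig(seed=seed))
            fit = fit_mass_loss_glm(bundle.bat_records)
            n_pos += fit.coef("initial_mass") > 0
        assert n_pos >= 7

    def test_constant_loss_gives_null_slopes(self):
        recs = records(
            {"humid": [5, 6, 7], "dry": [5, 6, 7]},
            masses={"humid": [23.0, 25.0, 27.0], "dry": [23.0, 25.0, 27.0]},
        )
        for r in recs:
            r.final_mass = r.initial_mass - 5.0
        fit = fit_mass_loss_glm(recs)
        for term in fit.table.index:
            if term != "Intercept":
                assert fit.coef(term) == pytest.approx(0.0, abs=1e-6)

    def test_nonpositive_loss_excluded(self):
        recs = records(
            {"humid": [5, 6, 7, 8], "dry": [5, 6, 7, 8]},
            masses={"humid": [23.0, 24.0, 25.0, 26.0],
                    "dry": [23.0, 24.0, 25.0, 26.0]},
        )
        for r in recs:
            r.final_mass = r.initial_mass - 5.0 - 0.1 * r.n_arousals
        recs[0].final_mass = recs[0].initial_mass + 1.0  # gained mass
        with pytest.warns(UserWarning, match="non-positive"):
            fit_mass_loss_glm(recs)


class TestEffectSizes:
    def test_hand_case(self):
        es = cohens_d([0, 2], [2, 4])
        assert es.d == pytest.approx(-np.sqrt(2))
        assert es.magnitude == "large"

    def test_identical_groups_undefined(self):
        with pytest.raises(ValueError):
            cohens_d([1, 1, 1], [1, 1, 1])

    def test_antisymmetry_and_affine_invariance(self):
        rng = np.random.default_rng(33)
        a, b = rng.normal(0, 1, 30), rng.normal(1, 2, 30)
        d = cohens_d(a, b).d
        assert cohens_d(b, a).d == pytest.approx(-d)
        assert cohens_d(3 * a + 7, 3 * b + 7).d == pytest.approx(d)

    def test_monte_carlo_unit_shift(self):
        rng = np.random.default_rng(34)
        a = rng.normal(0, 1, 10_000)
        b = rng.normal(1, 1, 10_000)
        assert cohens_d(a, b).d == pytest.approx(-1.0, abs=0.05)

    def test_magnitude_labels(self):
        from torporlab import EffectSize

        assert EffectSize(0.1).magnitude == "negligible"
        assert EffectSize(-0.3).magnitude == "small"
        assert EffectSize(0.6).magnitude == "medium"
        assert EffectSize(-0.9).magnitude == "large"


class TestWelch:
    def test_hand_case(self):
        res = welch_t([1, 2, 3], [2, 3, 4])
        assert res["t"] == pytest.approx(-1.2247, abs=1e-4)
        assert res["df"] == pytest.approx(4.0)

    def test_identical_groups(self):
        res = welch_t([1, 2, 3], [1, 2, 3])
        assert res["t"] == 0.0

    def test_matches_scipy(self):
        rng = np.random.default_rng(35)
        a, b = rng.normal(0, 1, 15), rng.normal(0.5, 2, 25)
        res = welch_t(a, b)
        ref = scipy.stats.ttest_ind(a, b, equal_var=False)
        assert res["t"] == pytest.approx(ref.statistic)
        assert res["p"] == pytest.approx(ref.pvalue)

    def test_null_rejection_rate(self):
        rng = np.random.default_rng(36)
        rej = sum(
            welch_t(rng.normal(0, 1, 10), rng.normal(0, 3, 14))["p"] < 0.05
            for _ in range(400)
        )
        assert rej / 400 == pytest.approx(0.05, abs=0.03)
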