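import numpy as np
import pandas as pd
import pytest
from scipy import stats

from voicetest import irt, simulate
from voicetest.irt import (
    AbilityEstimate,
    FitResult,
    ResponseMatrix,
    dif_test,
    eap_abilities,
    empirical_icc,
    empirical_reliability,
    fit_2pl,
    fit_rasch,
    item_fit,
    lr_test,
    rasch_icc,
)
from voicetest.irt import test_information as information_curve


def dense_marginal_loglik(fit, responses, grid=None):
    """Independent brute-force marginal likelihood by dense trapezoid
    integration over the continuous latent prior."""
    if grid is None:
        grid = np.linspace(-9, 9, 10001)
    dens = stats.norm.pdf(grid, float(fit.latent_mean[0]), fit.latent_sd)
    total = 0.0
    for p in range(responses.n_persons):
        like = np.ones_like(grid)
        for j in range(responses.n_items):
            x = responses.correct[p, j]
            if not np.isfinite(x):
                continue
            Pj = 1.0 / (1.0 + np.exp(-fit.discrimination[j] * (grid - fit.difficulty[j])))
            like = like * (Pj if x == 1.0 else 1.0 - Pj)
        total += np.log(np.trapezoid(like * dens, grid))
    return total


def dense_posterior_mean(fit, responses, person, grid=None):
    if grid is None:
        grid = np.linspace(-9, 9, 10001)
    dens = stats.norm.pdf(grid, float(fit.latent_mean[0]), fit.latent_sd)
    like = np.ones_like(grid)
    for j in range(responses.n_items):
        x = responses.correct[person, j]
        if not np.isfinite(x):
            continue
        Pj = 1.0 / (1.0 + np.exp(-fit.discrimination[j] * (grid - fit.difficulty[j])))
        like = like * (Pj if x == 1.0 else 1.0 - Pj)
    post = like * dens
    return np.trapezoid(grid * post, grid) / np.trapezoid(post, grid)


def make_fit(b, a=None, sd=1.0, model="rasch", loglik=-100.0, k=None, n=100):
    b = np.asarray(b, float)
    a = np.ones_like(b) if a is None else np.asarray(a, float)
    return FitResult(
        model=model,
        item_ids=tuple(f"i{j}" for j in range(len(b))),
        difficulty=b,
        discrimination=a,
        latent_mean=np.zeros(1),
        latent_sd=sd,
        loglik=loglik,
        n_free_params=k if k is not None else len(b) + 1,
        n_persons=n,
        converged=True,
        n_iter=1,
    )


class TestICC:
    def test_half_probability_when_ability_equals_difficulty(self):
        for theta in (-2.0, 0.0, 1.7):
            assert rasch_icc(theta, theta) == pytest.approx(0.5, abs=1e-15)

    def test_saturation(self):
        assert rasch_icc(20.0, 0.0) >= 1 - 1e-8
        assert rasch_icc(-20.0, 0.0) <= 1e-8

    def test_logistic_value(self):
        assert rasch_icc(1.0, 0.0) == pytest.approx(0.7310585786300049, abs=1e-12)

    def test_discrimination_scales_slope(self):
        assert rasch_icc(0.5, 0.0, a=2.0) == pytest.approx(rasch_icc(1.0, 0.0))


class TestResponseMatrix:
    def test_rejects_non_binary(self):
        with pytest.raises(ValueError, match="0, 1, or missing"):
            ResponseMatrix(("p1",), ("i1", "i2"), np.array([[0.5, 1.0]]))

    def test_omission_boundary_inclusive(self):
        rm = ResponseMatrix(
            ("p1",),
            ("i1", "i2", "i3"),
            np.array([[1.0, 1.0, 0.0]]),
            rt_ms=np.array([[3999.0, 4000.0, 4001.0]]),
        )
        out = rm.with_omissions_excluded()
        assert np.isfinite(out.correct[0, 0])
        assert np.isnan(out.correct[0, 1]) and np.isnan(out.correct[0, 2])

    def test_long_wide_roundtrip(self):
        rng = np.random.default_rng(0)
        correct = rng.integers(0, 2, size=(5, 4)).astype(float)
        correct[0, 1] = np.nan
        rm = ResponseMatrix(
            tuple(f"p{i}" for i in range(5)),
            tuple(f"i{j}" for j in range(4)),
            correct,
            rt_ms=np.full((5, 4), 1500.0),
            groups={"gender": np.array(["f", "m", "f", "m", "f"])},
        )
        back = ResponseMatrix.from_long(rm.to_long(), group_cols=("gender",))
        assert back.person_ids == rm.person_ids
        np.testing.assert_array_equal(np.isnan(back.correct), np.isnan(rm.correct))
        np.testing.assert_array_equal(
            np.nan_to_num(back.correct), np.nan_to_num(rm.correct)
        )
        np.testing.assert_array_equal(back.groups["gender"], rm.groups["gender"])


class TestFitRasch:
    def test_loglik_matches_dense_integration_oracle(self):
        model = simulate.RespondentModel(difficulty=np.array([-1.0, 0.0, 1.0]))
        rm = simulate.simulate_responses(model, 60, seed=7)
        fit = fit_rasch(rm, compute_se=False)
        assert fit.loglik == pytest.approx(dense_marginal_loglik(fit, rm), abs=1e-4)

    def test_recovers_generating_difficulties(self, rasch_responses):
        b_true, rm = rasch_responses
        fit = fit_rasch(rm, compute_se=False)
        b_hat = fit.difficulty - fit.difficulty.mean() + b_true.mean()
        assert np.sqrt(np.mean((b_hat - b_true) ** 2)) < 0.25
        assert fit.converged
        assert 0.7 < fit.latent_sd < 1.3

    def test_deterministic(self, rasch_responses):
        _, rm = rasch_responses
        f1 = fit_rasch(rm, compute_se=False)
        f2 = fit_rasch(rm, compute_se=False)
        np.testing.assert_array_equal(f1.difficulty, f2.difficulty)
        assert f1.loglik == f2.loglik

    def test_all_correct_item_flagged_inestimable(self):
        rng = np.random.default_rng(1)
        correct = rng.integers(0, 2, size=(50, 4)).astype(float)
        correct[:, 2] = 1.0
        rm = ResponseMatrix(
            tuple(f"p{i}" for i in range(50)), ("i1", "i2", "i3", "i4"), correct
        )
        with pytest.warns(UserWarning, match="inestimable"):
            fit = fit_rasch(rm, compute_se=False)
        assert fit.inestimable_items == ("i3",)
        assert np.isnan(fit.difficulty[2])
        assert np.isfinite(fit.difficulty[[0, 1, 3]]).all()

    def test_bic_definition(self, rasch_responses):
        _, rm = rasch_responses
        fit = fit_rasch(rm, compute_se=False)
        assert fit.n_free_params == rm.n_items + 1
        assert fit.bic == pytest.approx(
            -2 * fit.loglik + fit.n_free_params * np.log(rm.n_persons)
        )

    def test_standard_errors_positive_and_plausible(self, rasch_responses):
        _, rm = rasch_responses
        fit = fit_rasch(rm)
        assert np.all(fit.se_difficulty > 0)
        # with n=300 persons, difficulty SEs should be on the 0.1-0.3 scale
        assert np.all(fit.se_difficulty < 0.5)


class TestFit2PL:
    def test_recovers_discrimination_ordering(self):
        rng = np.random.default_rng(2)
        J = 10
        a = np.where(np.arange(J) < 5, 0.5, 2.0)
        b = rng.uniform(-1, 1, J)
        model = simulate.RespondentModel(difficulty=b, discrimination=a)
        rm = simulate.simulate_responses(model, 600, seed=3)
        fit = fit_2pl(rm, compute_se=False)
        assert fit.discrimination[5:].mean() > fit.discrimination[:5].mean()
        assert fit.n_free_params == 2 * J

    def test_single_item_rejected(self):
        rm = ResponseMatrix(("p1", "p2"), ("i1",), np.array([[1.0], [0.0]]))
        with pytest.raises(ValueError):
            fit_2pl(rm)


class TestLRTest:
    def test_identical_fits_give_zero(self):
        nested = make_fit([0.0, 1.0], loglik=-50.0, k=3)
        full = make_fit([0.0, 1.0], loglik=-50.0, k=5, model="2pl")
        res = lr_test(nested, full)
        assert res.chi2 == 0.0 and res.p == 1.0

    def test_chisquare_survival_value(self):
        nested = make_fit([0.0], loglik=-100.0, k=2)
        full = make_fit([0.0], loglik=-97.5, k=7, model="2pl")
        res = lr_test(nested, full)
        assert res.chi2 == pytest.approx(5.0)
        assert res.df == 5
        assert res.p == pytest.approx(0.4159, abs=2e-4)

    def test_inconsistent_logliks_rejected(self):
        nested = make_fit([0.0], loglik=-90.0, k=2)
        full = make_fit([0.0], loglik=-95.0, k=4, model="2pl")
        with pytest.raises(ValueError, match="below nested"):
            lr_test(nested, full)


class TestEAP:
    def test_prior_fallback_for_unscored_person(self):
        fit = make_fit([0.0, 0.5], sd=1.3)
        rm = ResponseMatrix(
            ("p1", "p2"), ("i0", "i1"), np.array([[np.nan, np.nan], [1.0, 0.0]])
        )
        ab = eap_abilities(fit, rm)
        assert ab.theta[0] == pytest.approx(0.0, abs=1e-10)
        assert ab.se[0] == pytest.approx(1.3, abs=2e-3)  # prior SD on the grid

    def test_sum_score_sufficiency_under_rasch(self, rasch_responses):
        _, rm = rasch_responses
        fit = fit_rasch(rm, compute_se=False)
        ab = eap_abilities(fit, rm)
        mask = rm.scored_mask()
        complete = np.where(mask.all(axis=1))[0]
        sums = np.nansum(rm.correct[complete], axis=1)
        for s in np.unique(sums):
            thetas = ab.theta[complete[sums == s]]
            assert np.ptp(thetas) < 1e-8

    def test_matches_dense_posterior_integration(self):
        model = simulate.RespondentModel(difficulty=np.array([-0.5, 0.3, 1.1]))
        rm = simulate.simulate_responses(model, 20, seed=9)
        fit = make_fit([-0.5, 0.3, 1.1], sd=1.0)  # known parameters, unit prior
        ab = eap_abilities(fit, rm)
        for p in (0, 7, 13):
            assert ab.theta[p] == pytest.approx(
                dense_posterior_mean(fit, rm, p), abs=1e-6
            )


class TestReliability:
    def test_direct_arithmetic(self):
        theta = np.array([0.0, 1.0952, -1.0952, 0.5, -0.5])  # var ~ 0.75
        theta = theta / theta.std(ddof=1) * np.sqrt(0.3)
        se = np.full(5, np.sqrt(0.15))
        rel = empirical_reliability(AbilityEstimate(("a", "b", "c", "d", "e"), theta, se))
        assert rel == pytest.approx(0.3 / 0.45, abs=1e-9)

    def test_zero_error_limit(self):
        ab = AbilityEstimate(("a", "b"), np.array([0.0, 1.0]), np.zeros(2))
        assert empirical_reliability(ab) == 1.0

    def test_zero_variance_rejected(self):
        ab = AbilityEstimate(("a", "b"), np.zeros(2), np.ones(2))
        with pytest.raises(ValueError):
            empirical_reliability(ab)


class TestInformation:
    def test_single_item_maximum_quarter(self):
        fit = make_fit([0.7, 0.7])
        theta, info, se = information_curve(fit, theta=np.array([0.7]))
        assert info[0] == pytest.approx(2 * 0.25)  # two identical items
        assert se[0] == pytest.approx(1 / np.sqrt(0.5))

    def test_symmetry_about_difficulty(self):
        fit = make_fit([0.5, 0.5])
        _, lo, _ = information_curve(fit, theta=np.array([0.5 - 1.2]))
        _, hi, _ = information_curve(fit, theta=np.array([0.5 + 1.2]))
        assert lo[0] == pytest.approx(hi[0], rel=1e-12)

    def test_peak_near_mean_difficulty(self, rasch_responses):
        _, rm = rasch_responses
        fit = fit_rasch(rm, compute_se=False)
        theta, info, _ = information_curve(fit)
        center = info[np.argmin(np.abs(theta - np.mean(fit.difficulty)))]
        assert center > info[0] and center > info[-1]


class TestItemFit:
    def test_well_fitting_items_near_one(self):
        # 20 items keep the point-estimate shrinkage bias of infit small
        rng = np.random.default_rng(21)
        model = simulate.RespondentModel(difficulty=rng.uniform(-1, 1, 20))
        rm = simulate.simulate_responses(model, 500, seed=22)
        fit = fit_rasch(rm, compute_se=False)
        table = item_fit(fit, rm)
        assert table["infit"].between(0.8, 1.2).all()
        assert table["infit"].mean() == pytest.approx(1.0, abs=0.1)
        assert not table["flagged"].any()

    def test_guessing_item_worst_fitting(self):
        # an item with a 1/3 guessing floor and shallow slope should rank as
        # the worst-fitting item in most replicates
        top = 0
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            J = 12
            b = rng.uniform(-1, 1, J)
            c = np.zeros(J)
            c[0] = 1 / 3
            a = np.ones(J)
            a[0] = 0.4
            model = simulate.RespondentModel(difficulty=b, discrimination=a, guessing=c)
            rm = simulate.simulate_responses(model, 500, seed=200 + seed)
            fit = fit_rasch(rm, compute_se=False)
            table = item_fit(fit, rm).set_index("item_id")
            top += int(table["infit"].idxmax() == "i01")
        assert top >= 4

    def test_binned_chi2_reported(self, rasch_responses):
        _, rm = rasch_responses
        fit = fit_rasch(rm, compute_se=False)
        table = item_fit(fit, rm)
        assert (table["chi2"] >= 0).all()
        assert (table["chi2_df"] >= 1).all()


class TestEmpiricalICC:
    def test_all_correct_item_flat_at_one(self):
        correct = np.ones((30, 2))
        correct[:15, 1] = 0.0
        rm = ResponseMatrix(tuple(f"p{i}" for i in range(30)), ("i1", "i2"), correct)
        ab = AbilityEstimate(rm.person_ids, np.linspace(-2, 2, 30), np.ones(30))
        table = empirical_icc(rm, ab, n_bins=3)
        flat = table[table["item_id"] == "i1"]
        assert (flat["observed"] == 1.0).all()

    def test_monotone_for_simulated_item(self):
        model = simulate.RespondentModel(difficulty=np.zeros(6))
        rm = simulate.simulate_responses(model, 2000, seed=5)
        fit = fit_rasch(rm, compute_se=False)
        ab = eap_abilities(fit, rm)
        table = empirical_icc(rm, ab, n_bins=5, fit=fit)
        one = table[table["item_id"] == "i01"].sort_values("bin_mean_theta")
        diffs = np.diff(one["observed"].to_numpy())
        assert (diffs > -0.06).all()  # non-decreasing up to sampling noise

    def test_bin_merging_conserves_counts(self):
        model = simulate.RespondentModel(difficulty=np.zeros(3))
        rm = simulate.simulate_responses(model, 40, seed=6)
        fit = fit_rasch(rm, compute_se=False)
        ab = eap_abilities(fit, rm)
        table = empirical_icc(rm, ab, n_bins=8, min_per_bin=5)
        for item, sub in table.groupby("item_id"):
            j = rm.item_ids.index(item)
            assert sub["n"].sum() == np.isfinite(rm.correct[:, j]).sum()
            assert (sub["n"] >= 5).all()


class TestDIF:
    def test_duplicated_groups_show_no_dif(self):
        model = simulate.RespondentModel(difficulty=np.linspace(-1, 1, 6))
        rm0 = simulate.simulate_responses(model, 120, seed=8)
        correct = np.vstack([rm0.correct, rm0.correct])
        rm = ResponseMatrix(
            tuple(f"p{i}" for i in range(240)),
            rm0.item_ids,
            correct,
            groups={"half": np.array(["a"] * 120 + ["b"] * 120)},
        )
        res = dif_test(rm, "half")
        assert res.chi2 == pytest.approx(0.0, abs=1e-3)
        assert res.p > 0.99
        np.testing.assert_allclose(res.item_table["delta_b"], 0.0, atol=1e-6)

    def test_injected_shift_flagged(self):
        rng = np.random.default_rng(3)
        b = rng.uniform(-1, 1, 15)
        model = simulate.RespondentModel(
            difficulty=b,
            group_proportions={"a": 0.5, "b": 0.5},
            dif_shifts={(4, "b"): 1.2},
        )
        rm = simulate.simulate_responses(model, 600, seed=4)
        res = dif_test(rm, "group")
        table = res.item_table.set_index("item_id")
        assert bool(table.loc["i05", "flagged"])
        assert abs(table.loc["i05", "delta_b"]) > 0.5

    def test_omnibus_only_mode(self):
        model = simulate.RespondentModel(
            difficulty=np.linspace(-1, 1, 6), group_proportions={"a": 0.5, "b": 0.5}
        )
        rm = simulate.simulate_responses(model, 200, seed=5)
        res = dif_test(rm, "group", per_item=False)
        assert res.item_table.empty and res.df == 5

    def test_single_group_rejected(self):
        model = simulate.RespondentModel(difficulty=np.zeros(4))
        rm = simulate.simulate_responses(model, 100, seed=6)
        with pytest.raises(ValueError, match="group"):
            dif_test(rm, "gender")

    def test_small_groups_rejected(self):
        model = simulate.RespondentModel(
            difficulty=np.zeros(4), group_proportions={"a": 0.95, "b": 0.05}
        )
        rm = simulate.simulate_responses(model, 60, seed=7)
        with pytest.raises(ValueError, match="below minimum"):
            dif_test(rm, "group")
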