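"""One-sample MR estimators: oracles, invariances, sex-difference test."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from helpers import simulate_ready

from mrsuite import (
    EstimateRecord,
    SimConfig,
    fit_first_stage,
    fit_observational,
    run_subgroups,
    sex_difference_z,
    tsls_continuous,
    two_stage_logistic,
)
from mrsuite.errors import DegenerateInputError, EstimationError, WeakInstrumentWarning


@pytest.fixture(scope="module")
def cohort():
    _, _, c = simulate_ready(SimConfig(n_individuals=20_000, seed=30))
    return c


class TestEstimateRecord:
    def test_wald_ci_identity(self):
        rec = EstimateRecord.from_beta_se("y", "tsls", "per-SD beta", 0.1, 0.02, 100)
        assert rec.ci_low == pytest.approx(rec.beta - 1.96 * rec.se, abs=1e-12)
        assert rec.ci_high == pytest.approx(rec.beta + 1.96 * rec.se, abs=1e-12)
        assert 0 < rec.p <= 1

    def test_invalid_se_rejected(self):
        with pytest.raises(EstimationError):
            EstimateRecord.from_beta_se("y", "tsls", "per-SD beta", 0.1, 0.0, 100)


class TestObservational:
    def test_identity_outcome_slope_one(self, cohort):
        c = cohort.assign(same=cohort.x)
        rec = fit_observational(c, "same", "x")
        assert rec.beta == pytest.approx(1.0, abs=1e-10)
        assert rec.p < 1e-100

    def test_confounded_slope_matches_ovb_oracle(self, cohort):
        # y = 0.1 x + 0.3 U + e with cov(x, U) = 0.3 -> slope ~ 0.19
        rec = fit_observational(cohort, "y", "x")
        assert rec.beta == pytest.approx(0.19, abs=0.02)

    def test_logistic_gives_log_odds_scale(self, cohort):
        rec = fit_observational(cohort, "cohabit", "x", family="logistic")
        assert rec.scale == "per-SD log-OR"
        assert rec.beta > 0  # positive linear predictor by construction

    def test_type_one_error_calibrated_on_null_outcome(self):
        rng = np.random.default_rng(31)
        rejections = 0
        reps = 400
        for _ in range(reps):
            c = pd.DataFrame({"x": rng.normal(size=300), "y": rng.normal(size=300)})
            rejections += fit_observational(c, "y", "x").p < 0.05
        assert rejections / reps == pytest.approx(0.05, abs=0.03)

    def test_binary_outcome_required_for_logistic(self, cohort):
        with pytest.raises(EstimationError):
            fit_observational(cohort, "y", "x", family="logistic")


class TestFirstStage:
    def test_recovers_coefficient(self):
        rng = np.random.default_rng(32)
        g = rng.normal(size=5000)
        c = pd.DataFrame({"g": g, "x": 2.0 * g + rng.normal(size=5000)})
        fs = fit_first_stage(c, "g", "x")
        assert fs.coef == pytest.approx(2.0, abs=0.05)
        assert fs.partial_f > 1000

    def test_orthogonal_score_warns_weak(self):
        rng = np.random.default_rng(33)
        c = pd.DataFrame({"g": rng.normal(size=2000), "x": rng.normal(size=2000)})
        with pytest.warns(WeakInstrumentWarning):
            fs = fit_first_stage(c, "g", "x")
        assert fs.partial_f < 6

    def test_constant_score_rejected(self):
        c = pd.DataFrame({"g": np.ones(100), "x": np.arange(100.0)})
        with pytest.raises(DegenerateInputError):
            fit_first_stage(c, "g", "x")


class TestTsls:
    def test_single_instrument_equals_wald_ratio(self, cohort):
        rec = tsls_continuous(cohort, "y", "x", "grs")
        g, x, y = (cohort[c].to_numpy() for c in ("grs", "x", "y"))
        wald = np.cov(g, y)[0, 1] / np.cov(g, x)[0, 1]
        assert rec.beta == pytest.approx(wald, abs=1e-8)

    def test_instrument_rescaling_invariance(self, cohort):
        a = tsls_continuous(cohort, "y", "x", "grs")
        b = tsls_continuous(cohort, "y", "x", "weighted")
        assert a.beta == pytest.approx(b.beta, abs=1e-8)
        assert a.se == pytest.approx(b.se, abs=1e-8)

    def test_matches_statsmodels_iv2sls_oracle(self, cohort):
        from statsmodels.sandbox.regression.gmm import IV2SLS

        sub = cohort.head(5000)
        Z = np.column_stack([np.ones(len(sub)), sub.grs, sub.age])
        X = np.column_stack([np.ones(len(sub)), sub.x, sub.age])
        oracle = IV2SLS(sub.y.to_numpy(), X, instrument=Z).fit()
        rec = tsls_continuous(sub, "y", "x", "grs", covariates=["age"])
        assert rec.beta == pytest.approx(oracle.params[1], abs=1e-8)

    def test_nulls_out_confounding(self):
        cfg = SimConfig(n_individuals=50_000, seed=34, causal_params={"slope": 0.0})
        _, _, c = simulate_ready(cfg)
        rec = tsls_continuous(c, "y", "x", "grs")
        assert abs(rec.beta) < 2 * rec.se

    def test_controlling_the_confounder_reconciles_estimators(self):
        cfg = SimConfig(n_individuals=50_000, seed=35)
        _, _, c = simulate_ready(cfg)
        obs = fit_observational(c, "y", "x", covariates=["confounder_true"])
        iv = tsls_continuous(c, "y", "x", "grs", covariates=["confounder_true"])
        assert abs(obs.beta - iv.beta) < 2 * iv.se

    def test_robust_close_to_conventional_under_homoskedasticity(self, cohort):
        robust = tsls_continuous(cohort, "y", "x", "grs", robust="HC1")
        plain = tsls_continuous(cohort, "y", "x", "grs", robust="none")
        assert robust.se == pytest.approx(plain.se, rel=0.05)


class TestTwoStageLogistic:
    def test_null_causal_effect_with_confounding(self):
        cfg = SimConfig(n_individuals=50_000, seed=36, causal_params={"slope": 0.0})
        _, _, c = simulate_ready(cfg)
        rec = two_stage_logistic(c, "cohabit", "x", "grs")
        assert abs(rec.beta) < 2 * rec.se

    def test_recovers_sex_specific_log_odds(self):
        # female-only log-OR of -0.19 (OR 0.83) with null effect in men
        cfg = SimConfig(
            n_individuals=100_000,
            seed=37,
            causal_params={"male": {"slope": 0.0}, "female": {"slope": np.log(0.83)}},
            confounder_effect_on_outcome=0.0,
        )
        _, _, c = simulate_ready(cfg)
        women = c[c.sex == "female"].reset_index(drop=True)
        rec = two_stage_logistic(women, "cohabit", "x", "grs", subgroup="women")
        assert np.exp(rec.beta) == pytest.approx(0.83, abs=0.05)

    def test_degenerate_outcome_rejected(self, cohort):
        c = cohort.assign(allzero=0)
        with pytest.raises(EstimationError):
            two_stage_logistic(c, "allzero", "x", "grs")


class TestSexDifference:
    def _rec(self, beta, se, scale="per-SD log-OR"):
        return EstimateRecord.from_beta_se("y", "tsls", scale, beta, se, 100)

    def test_identical_records_z_zero(self):
        r = self._rec(0.1, 0.05)
        z, p = sex_difference_z(r, r)
        assert z == 0.0
        assert p == 1.0

    def test_antisymmetry(self):
        a, b = self._rec(0.2, 0.05), self._rec(0.1, 0.04)
        z1, p1 = sex_difference_z(a, b)
        z2, p2 = sex_difference_z(b, a)
        assert z1 == -z2
        assert p1 == p2

    def test_cohabitation_or_difference_hand_computation(self):
        # log-ORs and SEs reconstructed from printed CIs: z ~ 3.72
        sm = (np.log(1.17) - np.log(0.97)) / 3.92
        sf = (np.log(0.92) - np.log(0.76)) / 3.92
        z, p = sex_difference_z(
            self._rec(np.log(1.07), sm), self._rec(np.log(0.83), sf)
        )
        assert z == pytest.approx(3.72, abs=0.01)
        assert p < 0.001

    def test_mismatched_scales_rejected(self):
        with pytest.raises(DegenerateInputError):
            sex_difference_z(self._rec(0.1, 0.05), self._rec(0.1, 0.05, "per-SD beta"))


class TestRunSubgroups:
    def test_cells_filled_and_sexes_partition(self, cohort):
        res = run_subgroups(
            cohort,
            outcomes=[("y", "linear"), ("cohabit", "logistic")],
            exposure="x",
            score="grs",
            subgroups={"men": "sex == 'male'", "women": "sex == 'female'"},
        )
        assert len(res) == 2 * 3 * 2  # outcomes x subgroups x methods
        assert (res.status == "ok").all()
        ysub = res[(res.outcome == "y") & (res.method == "tsls")].set_index("subgroup")
        assert ysub.loc["men", "n"] + ysub.loc["women", "n"] == ysub.loc["all", "n"]

    def test_empty_subgroup_flagged_not_crashed(self, cohort):
        res = run_subgroups(
            cohort.head(100),
            outcomes=[("y", "linear")],
            exposure="x",
            score="grs",
            subgroups={"none": "age > 1000"},
        )
        flagged = res[res.subgroup == "none"]
        assert (flagged.status == "empty subgroup").all()

    def test_median_age_split_balanced(self, cohort):
        med = cohort.age.median()
        res = run_subgroups(
            cohort,
            outcomes=[("y", "linear")],
            exposure="x",
            score="grs",
            methods=("observational",),
            subgroups={"young": f"age < {med}", "old": f"age >= {med}"},
        )
        counts = res[res.subgroup != "all"].set_index("subgroup").n
        assert counts.sum() == len(cohort)
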