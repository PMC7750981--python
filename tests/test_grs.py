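"""Score construction: alignment, weighting, rescaling, instrument strength."""

import numpy as np
import pandas as pd
import pytest

from helpers import simulate_ready

from mrsuite import (
    SimConfig,
    align_dosages,
    exclude_variants,
    instrument_strength,
    rescale_score,
    weighted_score,
)
from mrsuite.errors import AlignmentError, DegenerateInputError, EstimationError


@pytest.fixture
def two_variant_weights():
    return pd.DataFrame(
        {
            "variant_id": ["rs1", "rs2"],
            "effect_allele": ["A", "C"],
            "other_allele": ["G", "T"],
            "beta": [0.1, 0.2],
            "freq": [0.3, 0.5],
        }
    )


@pytest.fixture
def two_variant_dosages():
    return pd.DataFrame(
        {"rs1": [2.0, 0.0, 1.0], "rs2": [1.0, 0.0, 1.0]},
        index=pd.Index(["i1", "i2", "i3"], name="individual_id"),
    )


class TestAlign:
    def test_matching_alleles_identity(self, two_variant_weights, two_variant_dosages):
        meta = two_variant_weights[["variant_id", "effect_allele", "other_allele"]]
        out = align_dosages(two_variant_dosages, two_variant_weights, meta)
        pd.testing.assert_frame_equal(out, two_variant_dosages)

    def test_swapped_alleles_flip_dosage(self, two_variant_weights, two_variant_dosages):
        meta = pd.DataFrame(
            {
                "variant_id": ["rs1", "rs2"],
                "effect_allele": ["G", "C"],  # rs1 counted on the other allele
                "other_allele": ["A", "T"],
            }
        )
        out = align_dosages(two_variant_dosages, two_variant_weights, meta)
        assert out["rs1"].tolist() == [0.0, 2.0, 1.0]
        assert out["rs2"].tolist() == [1.0, 0.0, 1.0]

    def test_ambiguous_swap_rejected(self, two_variant_dosages):
        weights = pd.DataFrame(
            {
                "variant_id": ["rs1", "rs2"],
                "effect_allele": ["A", "C"],
                "other_allele": ["T", "G"],  # both strand-ambiguous pairs
                "beta": [0.1, 0.2],
                "freq": [0.3, 0.5],
            }
        )
        meta = pd.DataFrame(
            {
                "variant_id": ["rs1", "rs2"],
                "effect_allele": ["T", "C"],
                "other_allele": ["A", "G"],
            }
        )
        with pytest.raises(AlignmentError, match="ambiguous"):
            align_dosages(two_variant_dosages, weights, meta)

    def test_missing_variant_listed_in_error(self, two_variant_weights):
        lone = pd.DataFrame({"rs1": [1.0]}, index=pd.Index(["i1"], name="individual_id"))
        with pytest.raises(AlignmentError, match="rs2"):
            align_dosages(lone, two_variant_weights)


class TestWeightedScore:
    def test_dot_product_arithmetic(self, two_variant_weights, two_variant_dosages):
        s = weighted_score(two_variant_dosages, two_variant_weights)
        assert s.tolist() == pytest.approx([0.4, 0.0, 0.3])

    def test_all_ones_give_beta_sum(self, two_variant_weights):
        ones = pd.DataFrame(
            {"rs1": [1.0], "rs2": [1.0]}, index=pd.Index(["i"], name="individual_id")
        )
        assert weighted_score(ones, two_variant_weights).iloc[0] == pytest.approx(0.3)

    def test_missing_dosage_errors_unless_imputed(self, two_variant_weights):
        g = pd.DataFrame(
            {"rs1": [1.0, np.nan], "rs2": [1.0, 1.0]},
            index=pd.Index(["i1", "i2"], name="individual_id"),
        )
        with pytest.raises(DegenerateInputError):
            weighted_score(g, two_variant_weights)
        s = weighted_score(g, two_variant_weights, missing="mean")
        assert s.iloc[1] == pytest.approx(0.1 * 1.0 + 0.2)  # mean dosage 1.0 imputed

    def test_subset_additivity(self, two_variant_weights, two_variant_dosages):
        full = weighted_score(two_variant_dosages, two_variant_weights)
        parts = sum(
            weighted_score(two_variant_dosages, two_variant_weights.iloc[[i]])
            for i in range(2)
        )
        pd.testing.assert_series_equal(full, parts)


class TestRescale:
    def test_eq2_arithmetic(self, two_variant_weights):
        out = rescale_score(pd.Series([0.4]), two_variant_weights)
        assert round(float(out.iloc[0]), 3) == 2.667  # 0.4 * 2 / 0.3

    def test_all_heterozygous_gives_n_snps(self, two_variant_weights):
        w = pd.Series([0.3])  # all dosages 1 -> weighted = sum(beta)
        assert float(rescale_score(w, two_variant_weights).iloc[0]) == pytest.approx(2.0)

    def test_upper_bound_all_effect_alleles(self):
        cfg = SimConfig(seed=21)
        from mrsuite import simulate_variant_panel

        weights = simulate_variant_panel(cfg)
        top = pd.Series([2.0 * weights.beta.sum()])
        assert float(rescale_score(top, weights).iloc[0]) == pytest.approx(146.0)

    def test_linearity(self, two_variant_weights):
        w = pd.Series([0.1, 0.4])
        a = rescale_score(3.0 * w, two_variant_weights)
        b = 3.0 * rescale_score(w, two_variant_weights)
        pd.testing.assert_series_equal(a, b)

    def test_zero_beta_sum_rejected(self):
        weights = pd.DataFrame(
            {
                "variant_id": ["rs1", "rs2"],
                "effect_allele": ["A", "C"],
                "other_allele": ["G", "T"],
                "beta": [0.1, -0.1],
                "freq": [0.5, 0.5],
            }
        )
        with pytest.raises(DegenerateInputError):
            rescale_score(pd.Series([0.0]), weights)


class TestExclude:
    def test_pleiotropic_exclusion_76_to_73(self):
        # three variants with known pleiotropic effects are dropped by id
        ids = [f"rs{i}" for i in range(73)] + ["rs11030104", "rs13107325", "rs3888190"]
        weights = pd.DataFrame(
            {
                "variant_id": ids,
                "effect_allele": "A",
                "other_allele": "G",
                "beta": 0.01,
                "freq": 0.5,
            }
        )
        kept = exclude_variants(weights, ["rs11030104", "rs13107325", "rs3888190"])
        assert len(kept) == 73

    def test_empty_exclusion_is_identity(self, two_variant_weights):
        pd.testing.assert_frame_equal(
            exclude_variants(two_variant_weights, []), two_variant_weights
        )

    def test_unknown_id_warns(self, two_variant_weights):
        with pytest.warns(UserWarning, match="rs999"):
            exclude_variants(two_variant_weights, ["rs999"])

    def test_all_excluded_warns_and_empties(self, two_variant_weights):
        with pytest.warns(UserWarning):
            kept = exclude_variants(two_variant_weights, ["rs1", "rs2"])
        assert kept.empty


class TestInstrumentStrength:
    def test_identity_exposure_r2_one(self):
        rng = np.random.default_rng(0)
        s = rng.normal(size=500)
        r2, f = instrument_strength(s, s)
        assert r2 == pytest.approx(1.0)

    def test_independent_score_null(self):
        rng = np.random.default_rng(1)
        r2, f = instrument_strength(rng.normal(size=20_000), rng.normal(size=20_000))
        assert r2 < 0.001
        assert f < 6.0

    def test_incremental_beyond_covariates(self):
        rng = np.random.default_rng(2)
        cov = rng.normal(size=5000)
        s = rng.normal(size=5000)
        x = 0.5 * cov + 0.1 * s + rng.normal(size=5000)
        r2_incr, _ = instrument_strength(s, x, covariates=cov)
        marginal = instrument_strength(s, x)[0]
        # incremental R2 is relative to the covariate-reduced model
        assert r2_incr > 0.001
        assert abs(r2_incr - marginal) < 0.005

    def test_collinear_covariates_rejected(self):
        rng = np.random.default_rng(3)
        c = rng.normal(size=100)
        with pytest.raises(EstimationError):
            instrument_strength(
                rng.normal(size=100), rng.normal(size=100),
                covariates=np.column_stack([c, 2 * c]),
            )

    def test_simulated_score_explains_configured_variance(self):
        cfg = SimConfig(n_individuals=30_000, seed=22)
        _, _, cohort = simulate_ready(cfg)
        r2, f = instrument_strength(cohort.grs, cohort.x)
        assert r2 == pytest.approx(0.017, abs=0.004)
        assert f > 100
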