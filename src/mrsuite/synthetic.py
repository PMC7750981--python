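"""Synthetic cohort generator with known causal ground truth.

Emulates the statistical structure a one-sample Mendelian-randomization
study of BMI and social/socio-economic outcomes assumes: a panel of
independent biallelic variants in Hardy-Weinberg proportions whose weighted
score explains a small, configurable fraction of exposure variance
(default 1.7%); a single standard-normal individual-level confounder acting
on both exposure and outcomes; and, for family designs, sibships produced
by Mendelian transmission from simulated parents, with optional dynastic
effects (mid-parental score entering the offspring outcome) and assortative
mating (rank-coupled parental scores).

The exposure is built on a latent standardized (SD) scale and reported in
natural units (default: BMI-like, mean 27.4, SD 4.8 kg/m^2).  The
continuous outcome is likewise reported in natural units (default:
deprivation-index-like, mean -1.48, SD 2.99); the binary outcome shares
the same linear predictor through a logit link.

Causal shapes
-------------
``linear``     f(x) = slope * x
``quadratic``  f(x) = a * (x - center)^2 + slope * x    (U-shape)
``piecewise``  f(x) = slope_low * min(x, knot) + slope_high * max(x - knot, 0)

``causal_params`` may be a single parameter dict or ``{"male": {...},
"female": {...}}`` for sex-specific effects.  All shapes act on the
standardized exposure and return outcome SD units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .errors import InvalidConfigError

_BASES = np.array(list("ACGT"))

# rng stream ids so each operation draws from an independent child stream
_STREAM_PANEL = 11
_STREAM_UNRELATED = 23
_STREAM_SIBS = 37


@dataclass
class SimConfig:
    """Parameters of the data-generating process.

    Identical configs (including ``seed``) produce bit-identical tables.
    """

    n_individuals: int = 10_000
    n_families: int = 5_000
    sibs_per_family: int = 2
    n_variants: int = 73
    allele_freq_range: tuple[float, float] = (0.05, 0.95)
    target_r2: float = 0.017
    confounder_effect_on_exposure: float = 0.3
    confounder_effect_on_outcome: float = 0.3
    confounder_family_share: float = 0.0
    dynastic_effect: float = 0.0
    assortative_mating_corr: float = 0.0
    causal_shape: str = "linear"
    causal_params: dict = field(default_factory=lambda: {"slope": 0.1})
    binary_baseline_logodds: float = 1.0
    exposure_mean: float = 27.4
    exposure_sd: float = 4.8
    outcome_mean: float = -1.48
    outcome_sd: float = 2.99
    n_pcs: int = 5
    n_centres: int = 22
    male_fraction: float = 0.461
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.target_r2 < 1.0):
            raise InvalidConfigError(
                f"target_r2 must be in (0, 1), got {self.target_r2}"
            )
        if self.n_variants < 1:
            raise InvalidConfigError("n_variants must be >= 1")
        if self.sibs_per_family < 2:
            raise InvalidConfigError("sibs_per_family must be >= 2")
        lo, hi = self.allele_freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise InvalidConfigError("allele_freq_range must satisfy 0 < lo <= hi < 1")
        if not (0.0 <= self.assortative_mating_corr < 1.0):
            raise InvalidConfigError("assortative_mating_corr must be in [0, 1)")
        if not (0.0 <= self.confounder_family_share <= 1.0):
            raise InvalidConfigError("confounder_family_share must be in [0, 1]")
        if self.causal_shape not in ("linear", "quadratic", "piecewise"):
            raise InvalidConfigError(f"unknown causal_shape {self.causal_shape!r}")
        resid = 1.0 - self.target_r2 - self.confounder_effect_on_exposure**2
        if resid <= 0:
            raise InvalidConfigError(
                "target_r2 + confounder_effect_on_exposure^2 must be < 1 so the "
                "standardized exposure has positive residual variance"
            )
        if self.exposure_sd <= 0 or self.outcome_sd <= 0:
            raise InvalidConfigError("exposure_sd and outcome_sd must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def simulate_variant_panel(config: SimConfig) -> pd.DataFrame:
    """Draw a panel of independent biallelic variants with per-allele weights.

    Allele frequencies are uniform on ``allele_freq_range``.  Raw positive
    weights are rescaled analytically so the HWE variance of the weighted
    score, sum_i 2 p_i (1-p_i) beta_i^2, equals ``target_r2`` — hence the
    score explains exactly that fraction of a unit-variance exposure in
    expectation.

    Returns a VariantWeights table with columns
    ``variant_id, effect_allele, other_allele, beta, freq``.
    """
    rng = _rng(config, _STREAM_PANEL)
    m = config.n_variants
    lo, hi = config.allele_freq_range
    freq = rng.uniform(lo, hi, size=m)
    beta = np.abs(rng.normal(0.0, 1.0, size=m))  # effect allele = raising allele
    hwe_var = float(np.sum(2.0 * freq * (1.0 - freq) * beta**2))
    beta *= np.sqrt(config.target_r2 / hwe_var)

    effect = rng.integers(0, 4, size=m)
    shift = rng.integers(1, 4, size=m)  # ensures other != effect
    other = (effect + shift) % 4
    return pd.DataFrame(
        {
            "variant_id": [f"rs{1_000_000 + i}" for i in range(m)],
            "effect_allele": _BASES[effect],
            "other_allele": _BASES[other],
            "beta": beta,
            "freq": freq,
        }
    )


def _score(dosages: np.ndarray, weights: pd.DataFrame) -> np.ndarray:
    """Centered weighted score (expectation 2*sum(p_i beta_i) removed)."""
    beta = weights["beta"].to_numpy()
    freq = weights["freq"].to_numpy()
    return dosages @ beta - 2.0 * float(freq @ beta)


def _causal_sd_units(
    x_std: np.ndarray, male: np.ndarray, config: SimConfig
) -> np.ndarray:
    """Evaluate the causal shape, honouring per-sex parameter sets."""
    params = config.causal_params
    if "male" in params or "female" in params:
        out = np.empty_like(x_std)
        out[male] = _eval_shape(x_std[male], config.causal_shape, params["male"])
        out[~male] = _eval_shape(x_std[~male], config.causal_shape, params["female"])
        return out
    return _eval_shape(x_std, config.causal_shape, params)


def _eval_shape(x: np.ndarray, shape: str, p: dict) -> np.ndarray:
    if shape == "linear":
        return p.get("slope", 0.0) * x
    if shape == "quadratic":
        a = p.get("a", 0.0)
        c = p.get("center", 0.0)
        return a * (x - c) ** 2 + p.get("slope", 0.0) * x
    # piecewise: continuous hinge at the knot
    k = p.get("knot", 0.0)
    return p.get("slope_low", 0.0) * np.minimum(x, k) + p.get(
        "slope_high", 0.0
    ) * np.maximum(x - k, 0.0)


def _covariates(rng: np.random.Generator, n: int, config: SimConfig) -> dict:
    male = rng.random(n) < config.male_fraction
    age = np.clip(rng.normal(57.2, 8.0, size=n), 37.0, 73.0)
    centre = rng.integers(0, config.n_centres, size=n)
    cols = {
        "sex": np.where(male, "male", "female"),
        "age": np.round(age, 1),
        "centre": centre,
    }
    for j in range(config.n_pcs):
        cols[f"pc{j + 1}"] = rng.normal(0.0, 1.0, size=n)
    return cols


def _assemble_cohort(
    rng: np.random.Generator,
    config: SimConfig,
    ids: list[str],
    score: np.ndarray,
    u: np.ndarray,
    extra_outcome_shift: Optional[np.ndarray] = None,
    family_id: Optional[list[str]] = None,
) -> pd.DataFrame:
    """Build exposure and outcomes on the shared latent SD scale.

    exposure_std = centered score + a*U + e,  var(e) = 1 - r2 - a^2 so the
    standardized exposure has unit variance in expectation (under random
    mating; assortative mating inflates score variance slightly).
    """
    n = len(ids)
    a = config.confounder_effect_on_exposure
    b = config.confounder_effect_on_outcome
    resid_sd = np.sqrt(1.0 - config.target_r2 - a**2)
    x_std = score + a * u + rng.normal(0.0, resid_sd, size=n)

    cols = _covariates(rng, n, config)
    male = cols["sex"] == "male"
    fx = _causal_sd_units(x_std, male, config)

    shift = 0.0 if extra_outcome_shift is None else extra_outcome_shift
    linpred = fx + b * u + shift
    y_std = linpred + rng.normal(0.0, 1.0, size=n)
    logit = config.binary_baseline_logodds + linpred
    y_bin = (rng.random(n) < 1.0 / (1.0 + np.exp(-logit))).astype(int)

    frame = {
        "individual_id": ids,
        "family_id": family_id if family_id is not None else [None] * n,
        **cols,
        "bmi": config.exposure_mean + config.exposure_sd * x_std,
        "deprivation": config.outcome_mean + config.outcome_sd * y_std,
        "cohabit": y_bin,
        "confounder_true": u,
        "exposure_true_effect": fx,
    }
    return pd.DataFrame(frame)


def simulate_unrelated(
    config: SimConfig, weights: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate an unrelated cohort: HWE genotypes, confounded exposure, outcomes.

    Returns ``(genotypes, cohort)``: a dosage matrix (individuals x variants,
    values in {0,1,2}) indexed by individual id, and a CohortTable.
    """
    rng = _rng(config, _STREAM_UNRELATED)
    n, m = config.n_individuals, config.n_variants
    freq = weights["freq"].to_numpy()
    dosages = rng.binomial(2, freq, size=(n, m)).astype(float)
    ids = [f"U{i:07d}" for i in range(n)]
    u = rng.normal(0.0, 1.0, size=n)
    cohort = _assemble_cohort(rng, config, ids, _score(dosages, weights), u)
    genotypes = pd.DataFrame(
        dosages, index=pd.Index(ids, name="individual_id"),
        columns=weights["variant_id"].tolist(),
    )
    return genotypes, cohort


def _transmit(
    rng: np.random.Generator, parent_dosage: np.ndarray
) -> np.ndarray:
    """One allele per variant from a parent: 0 if dosage 0, 1 if 2, coin-flip if 1."""
    het = parent_dosage == 1.0
    allele = (parent_dosage == 2.0).astype(float)
    allele[het] = rng.integers(0, 2, size=int(het.sum())).astype(float)
    return allele


def simulate_sibships(
    config: SimConfig, weights: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate sibships by Mendelian transmission from simulated parents.

    Two parents per family are drawn in HWE; under ``assortative_mating_corr``
    rho > 0 couples are formed by a Gaussian-copula rank coupling of the two
    parental weighted scores.  Each sibling inherits one allele per variant
    from each parent independently, giving the canonical 0.5 sib-sib score
    correlation under random mating.  With ``dynastic_effect`` delta != 0,
    delta times the standardized mid-parental score is added to every
    offspring outcome's linear predictor — a family-level IV violation that
    within-family centring removes.

    The confounder of sib i is sqrt(s)*U_family + sqrt(1-s)*U_individual
    with s = ``confounder_family_share``.
    """
    rng = _rng(config, _STREAM_SIBS)
    n_fam, s_per, m = config.n_families, config.sibs_per_family, config.n_variants
    if n_fam < 1:
        raise InvalidConfigError("n_families must be >= 1")
    freq = weights["freq"].to_numpy()

    father = rng.binomial(2, freq, size=(n_fam, m)).astype(float)
    mother = rng.binomial(2, freq, size=(n_fam, m)).astype(float)

    rho = config.assortative_mating_corr
    if rho > 0.0:
        z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n_fam)
        sf, sm = _score(father, weights), _score(mother, weights)
        # couple the father at score-rank r1(i) with the mother at rank r2(i)
        father = father[np.argsort(sf)][np.argsort(np.argsort(z[:, 0]))]
        mother = mother[np.argsort(sm)][np.argsort(np.argsort(z[:, 1]))]

    mid_parent = (_score(father, weights) + _score(mother, weights)) / 2.0
    # analytic SD of the mid-parental score under HWE + assortative mating
    mid_sd = np.sqrt(config.target_r2 * (1.0 + rho) / 2.0)
    dynastic = config.dynastic_effect * mid_parent / mid_sd

    share = config.confounder_family_share
    u_fam = rng.normal(0.0, 1.0, size=n_fam)

    sib_dosages, ids, fam_ids, u_all, dyn_all = [], [], [], [], []
    for s in range(s_per):
        child = _transmit(rng, father) + _transmit(rng, mother)
        sib_dosages.append(child)
        ids.extend(f"S{f:06d}_{s}" for f in range(n_fam))
        fam_ids.extend(f"F{f:06d}" for f in range(n_fam))
        u_ind = rng.normal(0.0, 1.0, size=n_fam)
        u_all.append(np.sqrt(share) * u_fam + np.sqrt(1.0 - share) * u_ind)
        dyn_all.append(dynastic)

    dosages = np.vstack(sib_dosages)
    cohort = _assemble_cohort(
        rng,
        config,
        ids,
        _score(dosages, weights),
        np.concatenate(u_all),
        extra_outcome_shift=np.concatenate(dyn_all),
        family_id=fam_ids,
    )
    genotypes = pd.DataFrame(
        dosages, index=pd.Index(ids, name="individual_id"),
        columns=weights["variant_id"].tolist(),
    )
    return genotypes, cohort
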