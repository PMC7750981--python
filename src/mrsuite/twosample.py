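"""Summary-statistic MR sensitivity estimators: IVW, MR-Egger, weighted median.

Each estimator consumes per-variant effect pairs (variant->exposure
``beta_gx`` with ``se_gx``, variant->outcome ``beta_gy`` with ``se_gy``)
harmonized so every ``beta_gx`` is non-negative (oriented to the
exposure-raising allele).

* IVW: zero-intercept weighted regression of beta_gy on beta_gx with
  weights 1/se_gy^2; consistent only if all variants are valid instruments.
* MR-Egger: the same regression with a free intercept; a non-zero intercept
  estimates the average directional pleiotropic effect and the slope stays
  consistent under the InSIDE assumption.
* Weighted median: the 1/var-weighted median of per-variant Wald ratios;
  consistent while valid instruments carry >50% of the weight.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError
from .estimators import EstimateRecord, build_design, _with_const

_COLS = ["variant_id", "beta_gx", "se_gx", "beta_gy", "se_gy"]


@dataclass
class SummaryStats:
    """Per-variant summary statistics for two-sample MR."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _COLS if c not in self.table.columns]
        if missing:
            raise InsufficientDataError(f"summary table lacks columns {missing}")
        if (self.table[["se_gx", "se_gy"]] <= 0).any().any():
            raise InsufficientDataError("all summary SEs must be > 0")

    def __len__(self) -> int:
        return len(self.table)


def harmonize(summary: SummaryStats) -> SummaryStats:
    """Orient every variant to its exposure-raising allele.

    Variants with ``beta_gx < 0`` have both betas negated (SEs unchanged);
    Wald ratios are invariant to this.
    """
    t = summary.table.copy()
    flip = t["beta_gx"] < 0
    t.loc[flip, ["beta_gx", "beta_gy"]] *= -1.0
    return SummaryStats(t)


def ivw(summary: SummaryStats, random_effects: bool = False) -> EstimateRecord:
    """Inverse-variance-weighted estimate (fixed-effect SE by default).

    ``random_effects=True`` applies the multiplicative random-effects
    inflation max(1, sqrt(Q/(m-1))) to the SE.
    """
    t = summary.table
    if len(t) < 2:
        raise InsufficientDataError("IVW needs >= 2 variants")
    x = t["beta_gx"].to_numpy()
    y = t["beta_gy"].to_numpy()
    w = 1.0 / t["se_gy"].to_numpy() ** 2
    sxx = float(w @ x**2)
    beta = float(w @ (x * y)) / sxx
    se = np.sqrt(1.0 / sxx)
    if random_effects:
        q = float(w @ (y - beta * x) ** 2)
        se *= max(1.0, np.sqrt(q / (len(t) - 1)))
    return EstimateRecord.from_beta_se("", "ivw", "per-SD beta", beta, se, len(t))


def mr_egger(
    summary: SummaryStats, random_effects: bool = True
) -> tuple[EstimateRecord, EstimateRecord]:
    """MR-Egger regression: returns (slope record, intercept record).

    Weighted least squares of beta_gy on beta_gx with a free intercept and
    weights 1/se_gy^2.  By convention the SEs use the multiplicative
    random-effects scale max(1, sqrt(RSS_w/(m-2))).
    """
    t = summary.table
    m = len(t)
    if m < 3:
        raise InsufficientDataError("MR-Egger needs >= 3 variants")
    x = t["beta_gx"].to_numpy()
    y = t["beta_gy"].to_numpy()
    w = 1.0 / t["se_gy"].to_numpy() ** 2
    sw = np.sqrt(w)
    X = np.column_stack([np.ones(m), x]) * sw[:, None]
    yw = y * sw
    XtXinv = np.linalg.inv(X.T @ X)
    coef = XtXinv @ (X.T @ yw)
    resid = yw - X @ coef
    scale = float(resid @ resid) / (m - 2)
    if random_effects:
        scale = max(1.0, scale)
    else:
        scale = 1.0
    se = np.sqrt(scale * np.diag(XtXinv))
    slope = EstimateRecord.from_beta_se(
        "", "egger_slope", "per-SD beta", coef[1], se[1], m
    )
    intercept = EstimateRecord.from_beta_se(
        "", "egger_intercept", "per-SD beta", coef[0], se[0], m
    )
    return slope, intercept


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cum = np.cumsum(w) - 0.5 * w
    cum /= w.sum()
    return float(np.interp(0.5, cum, v))


def weighted_median(
    summary: SummaryStats, n_boot: int = 1000, seed: int = 0
) -> EstimateRecord:
    """Weighted median of per-variant Wald ratios.

    Weights are inverse delta-method variances of the ratios; the SE comes
    from a parametric bootstrap (``n_boot`` draws, seeded).  Variants with
    ``beta_gx == 0`` after harmonization are dropped with a warning.
    """
    t = summary.table
    zero = t["beta_gx"] == 0.0
    if zero.any():
        warnings.warn(
            f"dropping {int(zero.sum())} variant(s) with beta_gx = 0 "
            "(undefined Wald ratio)"
        )
        t = t[~zero]
    if len(t) < 3:
        raise InsufficientDataError("weighted median needs >= 3 usable variants")
    x = t["beta_gx"].to_numpy()
    y = t["beta_gy"].to_numpy()
    sx = t["se_gx"].to_numpy()
    sy = t["se_gy"].to_numpy()

    def estimate(bx, by):
        ratio = by / bx
        var = sy**2 / bx**2 + by**2 * sx**2 / bx**4
        return _weighted_median(ratio, 1.0 / var)

    beta = estimate(x, y)
    rng = np.random.default_rng(seed)
    draws = np.array(
        [
            estimate(rng.normal(x, sx), rng.normal(y, sy))
            for _ in range(n_boot)
        ]
    )
    se = float(np.std(draws, ddof=1))
    if se == 0.0:
        se = 1e-12  # degenerate bootstrap (all ratios identical)
    return EstimateRecord.from_beta_se(
        "", "weighted_median", "per-SD beta", beta, se, len(t)
    )


def summary_stats_from_cohort(
    genotypes: pd.DataFrame,
    cohort: pd.DataFrame,
    exposure: str,
    outcome: str,
    covariates: list[str] | None = None,
) -> SummaryStats:
    """Per-variant regressions of exposure and outcome on each dosage.

    Generates in-sample summary statistics (both betas from the same
    cohort, a known sample-overlap caveat for sensitivity analyses).
    Exposure, outcome and dosages are residualized on the covariates once,
    then per-variant simple-regression slopes and SEs are computed in a
    single vectorized pass.
    """
    covariates = covariates or []
    D = genotypes.to_numpy(dtype=float)
    xv = cohort[exposure].to_numpy(dtype=float)
    yv = cohort[outcome].to_numpy(dtype=float)
    n, m = D.shape
    C = _with_const(build_design(cohort, covariates)) if covariates else np.ones((n, 1))

    def residualize(mat):
        coef, *_ = np.linalg.lstsq(C, mat, rcond=None)
        return mat - C @ coef

    Dr = residualize(D)
    xr = residualize(xv)
    yr = residualize(yv)
    dd = np.einsum("ij,ij->j", Dr, Dr)
    df = n - C.shape[1] - 1

    def slopes(target):
        b = (Dr.T @ target) / dd
        rss = float(target @ target) - b**2 * dd
        se = np.sqrt(rss / df / dd)
        return b, se

    bx, sx = slopes(xr)
    by, sy = slopes(yr)
    return SummaryStats(
        pd.DataFrame(
            {
                "variant_id": genotypes.columns,
                "beta_gx": bx,
                "se_gx": sx,
                "beta_gy": by,
                "se_gy": sy,
            }
        )
    )


def simulate_summary_stats(
    n_variants: int = 73,
    true_slope: float = 0.1,
    pleiotropy_mean: float = 0.0,
    pleiotropy_sd: float = 0.0,
    invalid_fraction: float = 0.0,
    invalid_effect: float = 0.0,
    gx_range: tuple[float, float] = (0.015, 0.08),
    se_gx: float = 0.003,
    se_gy: float = 0.003,
    seed: int = 0,
) -> SummaryStats:
    """Generative model for testing the pleiotropy-sensitivity estimators.

    True variant->exposure effects are uniform on ``gx_range`` — the
    magnitude band of genome-wide-significant hits, all comfortably above
    the estimation noise ``se_gx`` as a selected panel's effects are.
    Variant->outcome effects are ``true_slope * beta_gx`` plus, for a
    random ``invalid_fraction`` of variants, a gross pleiotropic
    ``invalid_effect``, plus N(pleiotropy_mean, pleiotropy_sd) directional
    pleiotropy satisfying InSIDE.  Observed betas add N(0, se) noise.
    """
    rng = np.random.default_rng(seed)
    bx = rng.uniform(gx_range[0], gx_range[1], size=n_variants)
    alpha = (
        rng.normal(pleiotropy_mean, pleiotropy_sd, size=n_variants)
        if (pleiotropy_mean or pleiotropy_sd)
        else np.zeros(n_variants)
    )
    if invalid_fraction > 0.0:
        # gross invalid instruments with random sign; directional (signed)
        # pleiotropy is controlled separately via pleiotropy_mean
        bad = rng.random(n_variants) < invalid_fraction
        signs = rng.choice([-1.0, 1.0], size=n_variants)
        alpha = alpha + np.where(bad, signs * invalid_effect, 0.0)
    by = true_slope * bx + alpha
    return SummaryStats(
        pd.DataFrame(
            {
                "variant_id": [f"rs{i}" for i in range(n_variants)],
                "beta_gx": rng.normal(bx, se_gx),
                "se_gx": np.full(n_variants, se_gx),
                "beta_gy": rng.normal(by, se_gy),
                "se_gy": np.full(n_variants, se_gy),
            }
        )
    )
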