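"""Non-linear MR by stratification on the IV-free exposure.

The exposure is residualized on the genetic instrument (plus covariates) —
the "IV-free" exposure — and the sample is cut into K equal strata of the
residual (deciles by default, chosen a priori).  Within each stratum the
localized average causal effect (LACE) is the ratio

    lace_k = (stratum-specific score->outcome association)
             / (full-sample score->exposure association)

per exposure unit, with a delta-method SE that propagates the estimated
denominator.  The per-stratum slopes integrate into a continuous
piecewise-linear exposure-outcome curve anchored at a reference knot, and
non-linearity is tested two ways: a meta-regression of LACE on mean
stratum exposure (the "quadratic" trend test) and Cochran's Q for
heterogeneity of the LACEs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import DegenerateInputError, EstimationError, InsufficientDataError
from .estimators import FirstStage, _with_const, build_design, fit_first_stage


@dataclass
class StratumEstimate:
    """LACE for one stratum of the IV-free exposure."""

    stratum_index: int  # 1-based
    range_low: float
    range_high: float
    mean_exposure: float
    lace_beta: float
    lace_se: float
    n_stratum: int


@dataclass
class NonLinearResult:
    strata: list[StratumEstimate]
    curve: list[tuple[float, float]]  # (exposure knot, cumulative effect)
    p_quadratic: float
    p_cochran_q: float

    def strata_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "stratum": s.stratum_index,
                    "range_low": s.range_low,
                    "range_high": s.range_high,
                    "mean_exposure": s.mean_exposure,
                    "lace": s.lace_beta,
                    "se": s.lace_se,
                    "n": s.n_stratum,
                }
                for s in self.strata
            ]
        )


def iv_free_exposure(
    cohort: pd.DataFrame,
    score: str,
    exposure: str,
    covariates: list[str] | None = None,
) -> np.ndarray:
    """Residuals of exposure on score (+ covariates): the IV-free exposure."""
    g = cohort[score].to_numpy(dtype=float)
    if np.ptp(g) == 0.0:
        raise DegenerateInputError("score has no variance")
    x = cohort[exposure].to_numpy(dtype=float)
    X = _with_const(g, build_design(cohort, covariates or []))
    coef, *_ = np.linalg.lstsq(X, x, rcond=None)
    return x - X @ coef


def assign_strata(residuals: np.ndarray, k: int = 10) -> np.ndarray:
    """Cut the IV-free exposure into k equal-count strata (labels 1..k).

    Ties are broken by stable input order, so per-stratum counts are always
    within +-1 of n/k.
    """
    n = len(residuals)
    if n < 10 * k:
        raise InsufficientDataError(f"need n >= 10*k = {10 * k}, got {n}")
    order = np.argsort(residuals, kind="stable")
    labels = np.empty(n, dtype=int)
    for idx, block in enumerate(np.array_split(order, k)):
        labels[block] = idx + 1
    return labels


def _stratum_association(
    sub: pd.DataFrame, score: str, outcome: str,
    covariates: list[str], family: str,
) -> tuple[float, float]:
    """Score->outcome association within one stratum (numerator of LACE)."""
    y = sub[outcome].to_numpy(dtype=float)
    X = _with_const(sub[score].to_numpy(dtype=float), build_design(sub, covariates))
    if len(y) <= X.shape[1] + 2:
        raise EstimationError("stratum too small")
    if family == "linear":
        res = sm.OLS(y, X).fit()
    else:
        res = sm.Logit(y, X).fit(disp=0)
    return float(res.params[1]), float(res.bse[1])


def stratum_lace(
    sub: pd.DataFrame,
    score: str,
    outcome: str,
    covariates: list[str],
    family: str,
    first_stage: FirstStage,
    stratum_index: int,
    exposure_range: tuple[float, float],
    mean_exposure: float,
) -> StratumEstimate:
    """LACE for one stratum given the shared full-sample first stage.

    Delta-method SE treats the denominator as estimated:
    se^2 = se_num^2/d^2 + num^2 se_d^2 / d^4.
    """
    num, se_num = _stratum_association(sub, score, outcome, covariates, family)
    d, se_d = first_stage.coef, first_stage.se
    if abs(d) < 2.0 * se_d:
        warnings.warn("weak LACE denominator: first-stage coefficient within 2 SE of 0")
    lace = num / d
    se = np.sqrt(se_num**2 / d**2 + num**2 * se_d**2 / d**4)
    return StratumEstimate(
        stratum_index=stratum_index,
        range_low=exposure_range[0],
        range_high=exposure_range[1],
        mean_exposure=mean_exposure,
        lace_beta=lace,
        lace_se=se,
        n_stratum=len(sub),
    )


def piecewise_curve(
    strata: list[StratumEstimate],
    reference: float | None = None,
    edges: list[float] | None = None,
) -> list[tuple[float, float]]:
    """Integrate per-stratum slopes into a continuous piecewise-linear curve.

    Knots are the stratum exposure boundaries (``edges`` overrides them,
    e.g. to integrate on the analysis scale when the stored ranges are
    natural-unit labels); within stratum k the curve has slope lace_k.
    The curve is anchored to 0 at ``reference`` (default: the lowest
    knot); changing the reference translates every knot value by a
    constant.
    """
    if edges is None:
        edges = [strata[0].range_low] + [s.range_high for s in strata]
    values = [0.0]
    for s, lo, hi in zip(strata, edges[:-1], edges[1:]):
        values.append(values[-1] + s.lace_beta * (hi - lo))
    if reference is None:
        reference = edges[0]
    offset = float(np.interp(reference, edges, values))
    return [(e, v - offset) for e, v in zip(edges, values)]


def test_nonlinearity(strata: list[StratumEstimate]) -> tuple[float, float]:
    """(p_quadratic, p_cochran_q) for K >= 3 strata.

    p_quadratic: inverse-variance-weighted meta-regression of LACE on mean
    stratum exposure, normal test of zero slope.  p_cochran_q: Q =
    sum w_k (lace_k - lace_IVW)^2 against chi-square(K-1).
    """
    if len(strata) < 3:
        raise InsufficientDataError("non-linearity tests need K >= 3 strata")
    lace = np.array([s.lace_beta for s in strata])
    se = np.array([s.lace_se for s in strata])
    if np.any(se == 0.0):
        raise DegenerateInputError("a stratum has zero LACE standard error")
    mx = np.array([s.mean_exposure for s in strata])
    w = 1.0 / se**2

    # weighted meta-regression slope test
    X = np.column_stack([np.ones(len(strata)), mx]) * np.sqrt(w)[:, None]
    yw = lace * np.sqrt(w)
    XtXinv = np.linalg.inv(X.T @ X)
    coef = XtXinv @ (X.T @ yw)
    z = coef[1] / np.sqrt(XtXinv[1, 1])
    p_quad = float(np.clip(2.0 * stats.norm.sf(abs(z)), 1e-300, 1.0))

    pooled = float(w @ lace / w.sum())
    q = float(w @ (lace - pooled) ** 2)
    p_q = float(stats.chi2.sf(q, len(strata) - 1))
    return p_quad, p_q


def nonlinear_mr(
    cohort: pd.DataFrame,
    outcome: str,
    exposure: str,
    score: str,
    covariates: list[str] | None = None,
    k: int = 10,
    family: str = "linear",
    exposure_natural: str | None = None,
    reference: float | None = None,
) -> NonLinearResult:
    """Full stratified non-linear MR for one outcome.

    ``exposure_natural`` names the column used for reported stratum
    boundaries and mean exposures (defaults to the analysis exposure).
    With k < 3 the non-linearity tests are skipped (p = NaN); k = 1 reduces
    exactly to the linear IV (Wald ratio) estimate.
    """
    covariates = covariates or []
    fs = fit_first_stage(cohort, score, exposure, covariates)
    resid = iv_free_exposure(cohort, score, exposure, covariates)
    labels = assign_strata(resid, k) if k > 1 else np.ones(len(cohort), dtype=int)
    nat = cohort[exposure_natural or exposure].to_numpy(dtype=float)
    edges = np.quantile(nat, np.linspace(0.0, 1.0, k + 1))

    strata = []
    for j in range(1, k + 1):
        mask = labels == j
        sub = cohort[mask].reset_index(drop=True)
        strata.append(
            stratum_lace(
                sub, score, outcome, covariates, family, fs,
                stratum_index=j,
                exposure_range=(float(edges[j - 1]), float(edges[j])),
                mean_exposure=float(nat[mask].mean()),
            )
        )
    if k >= 3:
        p_quad, p_q = test_nonlinearity(strata)
    else:
        p_quad = p_q = float("nan")
    # integrate the curve on the analysis-exposure scale so slope and width
    # units agree even when stratum ranges are labelled in natural units
    analysis = cohort[exposure].to_numpy(dtype=float)
    curve_edges = list(np.quantile(analysis, np.linspace(0.0, 1.0, k + 1)))
    return NonLinearResult(
        strata=strata,
        curve=piecewise_curve(strata, reference, edges=curve_edges),
        p_quadratic=p_quad,
        p_cochran_q=p_q,
    )
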