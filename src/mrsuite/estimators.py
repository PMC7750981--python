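"""Observational regression and one-sample Mendelian randomization.

Continuous outcomes use two-stage least squares (2SLS): the exposure is
regressed on the genetic score plus covariates, the outcome on the
genotype-predicted exposure, and the variance uses residuals computed with
the *observed* exposure (heteroskedasticity-robust HC1 by default).  Binary
outcomes use the two-stage plug-in form ("2SPS"): logistic regression of
the outcome on the first-stage fitted exposure with sandwich standard
errors, reporting a log-odds-ratio per unit of exposure.

Sex differences between two estimates on the same scale are tested with
the normal z statistic

    z = (beta_male - beta_female) / sqrt(se_male^2 + se_female^2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import DegenerateInputError, EstimationError, WeakInstrumentWarning

Z95 = 1.96  # Wald multiplier used for all reported CIs
WEAK_F_FLOOR = 10.0


@dataclass
class EstimateRecord:
    """One effect estimate: the universal result currency of the pipeline."""

    outcome: str
    method: str
    scale: str  # "per-SD beta" or "per-SD log-OR"
    beta: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    subgroup: str = "all"

    @classmethod
    def from_beta_se(
        cls, outcome, method, scale, beta, se, n, subgroup="all"
    ) -> "EstimateRecord":
        if not np.isfinite(se) or se <= 0:
            raise EstimationError(f"invalid standard error {se} for {outcome}/{method}")
        p = float(np.clip(2.0 * stats.norm.sf(abs(beta / se)), 1e-300, 1.0))
        return cls(
            outcome=outcome,
            method=method,
            scale=scale,
            beta=float(beta),
            se=float(se),
            ci_low=float(beta - Z95 * se),
            ci_high=float(beta + Z95 * se),
            p=p,
            n=int(n),
            subgroup=subgroup,
        )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class FirstStage:
    """Exposure predicted from genotype: the 2SLS/2SPS first stage."""

    fitted: np.ndarray
    coef: float
    se: float
    partial_f: float
    n: int


def build_design(cohort: pd.DataFrame, covariates: list[str]) -> np.ndarray | None:
    """Covariate design matrix (no constant); categoricals become dummies."""
    if not covariates:
        return None
    parts = []
    for col in covariates:
        s = cohort[col]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            parts.append(pd.get_dummies(s, prefix=col, drop_first=True, dtype=float).to_numpy())
        else:
            parts.append(s.to_numpy(dtype=float)[:, None])
    return np.column_stack(parts)


def _with_const(*blocks) -> np.ndarray:
    cols = [np.ones((len(blocks[0]), 1))]
    for b in blocks:
        if b is None:
            continue
        b = np.asarray(b, float)
        cols.append(b[:, None] if b.ndim == 1 else b)
    return np.column_stack(cols)


def _check_rank(X: np.ndarray) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise EstimationError("design matrix is rank deficient")


def fit_observational(
    cohort: pd.DataFrame,
    outcome: str,
    exposure: str,
    covariates: list[str] | None = None,
    family: str = "linear",
    subgroup: str = "all",
) -> EstimateRecord:
    """Outcome regressed on exposure + covariates (OLS or logistic).

    The reported coefficient is per unit of the exposure column, so pass an
    SD-scale exposure to obtain per-SD effects.
    """
    covariates = covariates or []
    y = cohort[outcome].to_numpy(dtype=float)
    X = _with_const(cohort[exposure].to_numpy(dtype=float), build_design(cohort, covariates))
    if len(y) <= X.shape[1] + 1:
        raise EstimationError("too few observations")
    _check_rank(X)
    if family == "linear":
        res = sm.OLS(y, X).fit()
        scale = "per-SD beta"
    elif family == "logistic":
        _check_binary(y)
        try:
            res = sm.Logit(y, X).fit(disp=0)
        except Exception as exc:  # separation / non-convergence
            raise EstimationError(f"logistic fit failed: {exc}") from exc
        scale = "per-SD log-OR"
    else:
        raise ValueError(f"unknown family {family!r}")
    return EstimateRecord.from_beta_se(
        outcome, "observational", scale, res.params[1], res.bse[1], len(y), subgroup
    )


def _check_binary(y: np.ndarray) -> None:
    vals = np.unique(y)
    if not np.all(np.isin(vals, (0.0, 1.0))) or vals.size < 2:
        raise EstimationError("binary outcome must contain both 0s and 1s")


def fit_first_stage(
    cohort: pd.DataFrame,
    score: str,
    exposure: str,
    covariates: list[str] | None = None,
    weak_f_floor: float = WEAK_F_FLOOR,
) -> FirstStage:
    """Linear regression of exposure on score + covariates.

    Emits :class:`WeakInstrumentWarning` when the partial F of the score is
    below ``weak_f_floor``; estimation proceeds regardless.
    """
    g = cohort[score].to_numpy(dtype=float)
    if np.ptp(g) == 0.0:
        raise DegenerateInputError("score has no variance")
    x = cohort[exposure].to_numpy(dtype=float)
    X = _with_const(g, build_design(cohort, covariates or []))
    if len(x) <= X.shape[1]:
        raise EstimationError("too few observations for first stage")
    _check_rank(X)
    res = sm.OLS(x, X).fit()
    f = float(res.tvalues[1] ** 2)
    if f < weak_f_floor:
        warnings.warn(
            f"weak instrument: first-stage F = {f:.2f} < {weak_f_floor}",
            WeakInstrumentWarning,
        )
    return FirstStage(
        fitted=np.asarray(res.fittedvalues),
        coef=float(res.params[1]),
        se=float(res.bse[1]),
        partial_f=f,
        n=len(x),
    )


def _iv_fit(
    y: np.ndarray,
    x_endog: np.ndarray,
    instruments: np.ndarray,
    exog: np.ndarray | None,
    robust: str = "HC1",
    cluster: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """2SLS point estimates and covariance (endogenous regressor first).

    The covariance uses residuals e = y - X beta with the *observed*
    endogenous regressor, sandwiched through the projected design — the
    correct 2SLS variance, not the naive second-stage OLS one.
    """
    def _stack(first):
        first = np.asarray(first, float)
        cols = [first[:, None] if first.ndim == 1 else first, np.ones((len(y), 1))]
        if exog is not None:
            ex = np.asarray(exog, float)
            cols.append(ex[:, None] if ex.ndim == 1 else ex)
        return np.column_stack(cols)

    X = _stack(x_endog)  # endogenous regressor first, then const, then exog
    Z = _stack(instruments)
    n, k = X.shape
    _check_rank(Z)
    gamma, *_ = np.linalg.lstsq(Z, X, rcond=None)
    Xhat = Z @ gamma
    A = Xhat.T @ Xhat
    beta = np.linalg.solve(A, Xhat.T @ y)
    e = y - X @ beta
    Ainv = np.linalg.inv(A)
    if cluster is not None:
        s = Xhat * e[:, None]
        groups = pd.factorize(cluster)[0]
        ngroups = groups.max() + 1
        sums = np.zeros((ngroups, k))
        np.add.at(sums, groups, s)
        meat = sums.T @ sums
        corr = (ngroups / (ngroups - 1)) * ((n - 1) / (n - k))
        V = Ainv @ meat @ Ainv * corr
    elif robust == "HC1":
        meat = Xhat.T @ (Xhat * (e**2)[:, None])
        V = Ainv @ meat @ Ainv * n / (n - k)
    else:
        sigma2 = float(e @ e) / (n - k)
        V = sigma2 * Ainv
    return beta, V


def tsls_continuous(
    cohort: pd.DataFrame,
    outcome: str,
    exposure: str,
    score: str,
    covariates: list[str] | None = None,
    robust: str = "HC1",
    cluster: str | None = None,
    subgroup: str = "all",
    weak_f_floor: float = WEAK_F_FLOOR,
) -> EstimateRecord:
    """Two-stage least squares for a continuous outcome, score as instrument."""
    covariates = covariates or []
    fit_first_stage(cohort, score, exposure, covariates, weak_f_floor)  # weak-IV warning
    y = cohort[outcome].to_numpy(dtype=float)
    beta, V = _iv_fit(
        y,
        cohort[exposure].to_numpy(dtype=float),
        cohort[score].to_numpy(dtype=float),
        build_design(cohort, covariates),
        robust=robust,
        cluster=None if cluster is None else cohort[cluster].to_numpy(),
    )
    return EstimateRecord.from_beta_se(
        outcome, "tsls", "per-SD beta", beta[0], np.sqrt(V[0, 0]), len(y), subgroup
    )


def two_stage_logistic(
    cohort: pd.DataFrame,
    outcome: str,
    exposure: str,
    score: str,
    covariates: list[str] | None = None,
    cluster: str | None = None,
    subgroup: str = "all",
    weak_f_floor: float = WEAK_F_FLOOR,
) -> EstimateRecord:
    """Two-stage plug-in MR for a binary outcome (2SPS).

    First stage: exposure ~ score + covariates (OLS).  Second stage:
    logistic regression of the outcome on the fitted exposure + covariates
    with sandwich (HC1; cluster-robust if ``cluster`` given) standard
    errors.  Reports a log-OR per unit exposure; exponentiate for the OR.
    """
    covariates = covariates or []
    y = cohort[outcome].to_numpy(dtype=float)
    _check_binary(y)
    fs = fit_first_stage(cohort, score, exposure, covariates, weak_f_floor)
    X = _with_const(fs.fitted, build_design(cohort, covariates))
    try:
        if cluster is not None:
            res = sm.Logit(y, X).fit(
                disp=0,
                cov_type="cluster",
                cov_kwds={"groups": pd.factorize(cohort[cluster])[0]},
            )
        else:
            res = sm.Logit(y, X).fit(disp=0, cov_type="HC1")
    except Exception as exc:
        raise EstimationError(f"second-stage logistic fit failed: {exc}") from exc
    return EstimateRecord.from_beta_se(
        outcome, "two_stage_logistic", "per-SD log-OR",
        res.params[1], res.bse[1], len(y), subgroup,
    )


def sex_difference_z(
    est_male: EstimateRecord, est_female: EstimateRecord
) -> tuple[float, float]:
    """z test for a male-female difference of two estimates on one scale."""
    if est_male.scale != est_female.scale:
        raise DegenerateInputError(
            f"cannot compare estimates on scales {est_male.scale!r} vs "
            f"{est_female.scale!r}"
        )
    z = (est_male.beta - est_female.beta) / np.hypot(est_male.se, est_female.se)
    p = float(np.clip(2.0 * stats.norm.sf(abs(z)), 1e-300, 1.0))
    return float(z), p


_METHODS = {
    "observational": lambda c, o, fam, exp, sc, cov, sub: fit_observational(
        c, o, exp, cov, fam, sub
    ),
    "tsls": lambda c, o, fam, exp, sc, cov, sub: (
        tsls_continuous(c, o, exp, sc, cov, subgroup=sub)
        if fam == "linear"
        else two_stage_logistic(c, o, exp, sc, cov, subgroup=sub)
    ),
}


def run_subgroups(
    cohort: pd.DataFrame,
    outcomes: list[tuple[str, str]],
    exposure: str,
    score: str,
    covariates: list[str] | None = None,
    methods: tuple[str, ...] = ("observational", "tsls"),
    subgroups: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Run every (outcome, method, subgroup) cell; failures are flagged rows.

    ``outcomes`` is a list of ``(name, family)``; ``subgroups`` maps labels
    to pandas query strings (``{"all": ""}`` is implied first).  Returns a
    tidy frame with one row per cell, ordered deterministically, with a
    ``status`` column (``ok`` or the error message).
    """
    subgroups = {"all": "", **(subgroups or {})}
    rows = []
    for name, fam in outcomes:
        for label, query in subgroups.items():
            sub = cohort if query == "" else cohort.query(query)
            for method in methods:
                base = {"outcome": name, "method": method, "subgroup": label}
                if sub.empty:
                    rows.append({**base, "status": "empty subgroup"})
                    continue
                try:
                    rec = _METHODS[method](
                        sub.reset_index(drop=True), name, fam, exposure, score,
                        covariates, label,
                    )
                    rows.append({**rec.to_dict(), "status": "ok"})
                except Exception as exc:
                    rows.append({**base, "status": str(exc)})
    return pd.DataFrame(rows)
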