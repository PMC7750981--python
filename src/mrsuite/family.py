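"""Within-sibling non-genetic and MR analyses via family centring.

Subtracting the sibship mean from the exposure (non-genetic analysis) or
from the genetic score (MR) leaves only within-family variation, which is
orthogonal to every family-constant quantity — parental scores, dynastic
effects, shared environment — and therefore robust to family-level
confounding.  The between-family component (the family mean) enters the
model as a covariate rather than being absorbed by per-family fixed
effects; for balanced sibships the within coefficient is identical.
Standard errors are cluster-robust by family throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import DegenerateInputError, EstimationError
from .estimators import (
    EstimateRecord,
    _iv_fit,
    _with_const,
    build_design,
)


@dataclass
class SibshipIndex:
    """Families retained for within-sibling analysis."""

    members: pd.DataFrame  # columns: individual_id, family_id
    min_sibs: int
    sex_filter: str | None = None

    @property
    def n_families(self) -> int:
        return self.members["family_id"].nunique()

    @property
    def n_individuals(self) -> int:
        return len(self.members)

    def sizes(self) -> pd.Series:
        return self.members.groupby("family_id").size()


def build_sibships(
    cohort: pd.DataFrame, min_sibs: int = 2, sex_filter: str | None = None
) -> SibshipIndex:
    """Index families with >= ``min_sibs`` members (optionally of one sex).

    With ``sex_filter`` ('male'/'female') membership is restricted to that
    sex *before* the size filter, matching the families-with-two-or-more-
    same-sex-siblings design of sex-stratified sibling analyses.
    """
    if "family_id" not in cohort.columns:
        raise DegenerateInputError("cohort has no family_id column")
    members = cohort[cohort["family_id"].notna()][["individual_id", "family_id", "sex"]]
    if sex_filter is not None:
        members = members[members["sex"] == sex_filter]
    sizes = members.groupby("family_id")["individual_id"].transform("size")
    members = members[sizes >= min_sibs]
    if members.empty:
        raise DegenerateInputError("no families satisfy the sibship filter")
    return SibshipIndex(
        members=members[["individual_id", "family_id"]].reset_index(drop=True),
        min_sibs=min_sibs,
        sex_filter=sex_filter,
    )


def center_within_family(
    values: pd.Series, cohort: pd.DataFrame, index: SibshipIndex
) -> tuple[pd.Series, pd.Series]:
    """Centre a per-individual variable within each retained family.

    ``values`` must be indexed like ``cohort``.  Returns (centered values,
    per-individual family means), both restricted to index members.
    Families with any missing member value are dropped with a warning.
    """
    sub = cohort.merge(index.members, on=["individual_id", "family_id"])
    v = values.loc[cohort["individual_id"].isin(sub["individual_id"])]
    frame = pd.DataFrame(
        {"family_id": sub["family_id"].to_numpy(), "v": v.to_numpy(dtype=float)}
    )
    bad = frame.groupby("family_id")["v"].transform(lambda s: s.isna().any())
    if bad.any():
        import warnings

        warnings.warn(
            f"dropping {frame.loc[bad, 'family_id'].nunique()} families with "
            "missing member values"
        )
        frame = frame[~bad]
    means = frame.groupby("family_id")["v"].transform("mean")
    return (frame["v"] - means).rename("centered"), means.rename("family_mean")


def _sib_frame(cohort: pd.DataFrame, index: SibshipIndex) -> pd.DataFrame:
    sub = cohort.merge(index.members, on=["individual_id", "family_id"])
    return sub.reset_index(drop=True)


def _add_centered(sub: pd.DataFrame, col: str) -> pd.DataFrame:
    grp = sub.groupby("family_id")[col]
    sub = sub.copy()
    sub[f"{col}_fammean"] = grp.transform("mean")
    sub[f"{col}_centered"] = sub[col] - sub[f"{col}_fammean"]
    return sub


def sib_nongenetic(
    cohort: pd.DataFrame,
    index: SibshipIndex,
    outcome: str,
    exposure: str,
    covariates: list[str] | None = None,
    family: str = "linear",
    subgroup: str = "all",
) -> EstimateRecord:
    """Within-sibling non-genetic estimate.

    Outcome on family-centred exposure + family-mean exposure + covariates;
    the reported effect is the centred (within-family) coefficient with
    cluster-robust SEs by family.
    """
    covariates = covariates or []
    sub = _add_centered(_sib_frame(cohort, index), exposure)
    if np.allclose(sub[f"{exposure}_centered"], 0.0):
        raise EstimationError("exposure is constant within every family")
    y = sub[outcome].to_numpy(dtype=float)
    X = _with_const(
        sub[f"{exposure}_centered"].to_numpy(),
        np.column_stack(
            [sub[f"{exposure}_fammean"].to_numpy()[:, None]]
            + ([build_design(sub, covariates)] if covariates else [])
        ),
    )
    groups = pd.factorize(sub["family_id"])[0]
    try:
        model = sm.OLS(y, X) if family == "linear" else sm.Logit(y, X)
        res = model.fit(
            **(dict(disp=0) if family == "logistic" else {}),
            cov_type="cluster",
            cov_kwds={"groups": groups},
        )
    except Exception as exc:
        raise EstimationError(f"sib_nongenetic fit failed: {exc}") from exc
    scale = "per-SD beta" if family == "linear" else "per-SD log-OR"
    return EstimateRecord.from_beta_se(
        outcome, "sib_nongenetic", scale, res.params[1], res.bse[1], len(y), subgroup
    )


def sib_mr(
    cohort: pd.DataFrame,
    index: SibshipIndex,
    outcome: str,
    exposure: str,
    score: str,
    covariates: list[str] | None = None,
    family: str = "linear",
    subgroup: str = "all",
) -> EstimateRecord:
    """Within-sibling MR with the family-centred score as instrument.

    First stage: exposure ~ centred score + family-mean score + covariates.
    Continuous outcomes use 2SLS treating the exposure as endogenous with
    instrument = centred score and the family-mean score among the
    exogenous regressors; on two-sib families this equals the sib-pair
    difference (Wald ratio of outcome and exposure differences on score
    differences) exactly.  Binary outcomes use the two-stage logistic
    plug-in on the within-fitted exposure.  SEs cluster by family.
    """
    covariates = covariates or []
    sub = _add_centered(_sib_frame(cohort, index), score)
    gc = sub[f"{score}_centered"].to_numpy(dtype=float)
    if np.allclose(gc, 0.0):
        raise EstimationError("score is constant within every family")
    gbar = sub[f"{score}_fammean"].to_numpy(dtype=float)
    exog = np.column_stack(
        [gbar[:, None]] + ([build_design(sub, covariates)] if covariates else [])
    )
    groups = sub["family_id"].to_numpy()
    y = sub[outcome].to_numpy(dtype=float)

    # within-family first-stage strength (for the weak-instrument report)
    fs_X = _with_const(gc, exog)
    fs = sm.OLS(sub[exposure].to_numpy(dtype=float), fs_X).fit()
    partial_f = float(fs.tvalues[1] ** 2)
    if partial_f < 10.0:
        import warnings

        from .errors import WeakInstrumentWarning

        warnings.warn(
            f"weak within-family first stage: F = {partial_f:.2f}",
            WeakInstrumentWarning,
        )

    if family == "linear":
        beta, V = _iv_fit(
            y,
            sub[exposure].to_numpy(dtype=float),
            gc,
            exog,
            cluster=groups,
        )
        b, se = beta[0], np.sqrt(V[0, 0])
        scale = "per-SD beta"
    else:
        X2 = _with_const(np.asarray(fs.fittedvalues), exog)
        try:
            res = sm.Logit(y, X2).fit(
                disp=0,
                cov_type="cluster",
                cov_kwds={"groups": pd.factorize(groups)[0]},
            )
        except Exception as exc:
            raise EstimationError(f"sib MR logistic fit failed: {exc}") from exc
        b, se = res.params[1], res.bse[1]
        scale = "per-SD log-OR"
    return EstimateRecord.from_beta_se(
        outcome, "sib_mr", scale, b, se, len(y), subgroup
    )
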