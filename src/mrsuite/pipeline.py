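"""Orchestration: simulate -> score -> transform -> estimate -> report.

An :class:`AnalysisPlan` declares the outcome/method/subgroup matrix; on a
valid cohort :func:`run_plan` fills every cell (or flags its failure),
producing a tidy results table — one row per estimate with outcome,
method, subgroup, scale, beta, se, ci_low, ci_high, p, n — plus a
machine-readable run manifest recording the seed, sample sizes and
per-outcome missingness exclusions.  No multiple-testing adjustment is
applied; p-values are reported unadjusted.
"""

from __future__ import annotations

import json
import sys
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .errors import InvalidConfigError
from .estimators import run_subgroups
from .family import build_sibships, sib_mr, sib_nongenetic
from .grs import compute_scores
from .nonlinear import nonlinear_mr
from .phenotransform import TransformRecord, inverse_normal_transform, sd_to_natural
from .twosample import harmonize, ivw, mr_egger, summary_stats_from_cohort, weighted_median

RESULT_COLUMNS = [
    "outcome", "method", "subgroup", "scale", "beta", "se",
    "ci_low", "ci_high", "p", "n", "status",
]


@dataclass
class AnalysisPlan:
    """Declarative description of the analysis matrix."""

    exposure: str = "bmi"
    outcomes: list[dict] = field(
        default_factory=lambda: [
            {"name": "deprivation", "family": "linear", "transform": True},
            {"name": "cohabit", "family": "logistic", "transform": False},
        ]
    )
    covariates: list[str] = field(default_factory=lambda: ["age", "sex"])
    subgroups: dict[str, str] = field(
        default_factory=lambda: {"men": "sex == 'male'", "women": "sex == 'female'"}
    )
    methods: list[str] = field(default_factory=lambda: ["observational", "tsls"])
    k_nonlinear: int = 10
    min_sibs: int = 2
    seed: int = 0

    def validate(self, cohort: pd.DataFrame) -> None:
        """Pre-flight schema check; raises one error listing every problem."""
        problems = []
        known_methods = {
            "observational", "tsls", "sib_nongenetic", "sib_mr",
            "ivw", "egger", "weighted_median", "nonlinear",
        }
        if self.exposure not in cohort.columns:
            problems.append(f"exposure column {self.exposure!r} missing")
        for spec in self.outcomes:
            if spec["name"] not in cohort.columns:
                problems.append(f"outcome column {spec['name']!r} missing")
            if spec.get("family", "linear") not in ("linear", "logistic"):
                problems.append(f"unknown family for {spec['name']!r}")
        for cov in self.covariates:
            if cov not in cohort.columns:
                problems.append(f"covariate column {cov!r} missing")
        for m in self.methods:
            if m not in known_methods:
                problems.append(f"unknown method {m!r}")
        for label, query in self.subgroups.items():
            try:
                cohort.head(5).query(query)
            except Exception as exc:
                problems.append(f"subgroup {label!r} query invalid: {exc}")
        if problems:
            raise InvalidConfigError("; ".join(problems))


def _log(msg: str) -> None:
    print(f"[{time.strftime('%H:%M:%S')}] {msg}", file=sys.stderr)


def run_plan(
    plan: AnalysisPlan,
    cohort: pd.DataFrame,
    genotypes: pd.DataFrame | None = None,
    weights: pd.DataFrame | None = None,
    scores: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict, dict[str, TransformRecord]]:
    """Execute an analysis plan; returns (results, manifest, transform records).

    Scores may be passed precomputed, or are built from genotypes +
    weights.  The exposure is inverse-normal transformed to the SD scale
    before every model; outcomes flagged ``transform`` likewise.
    Deterministic given the plan and inputs.
    """
    plan.validate(cohort)
    if scores is None:
        if genotypes is None or weights is None:
            raise InvalidConfigError("need either scores or genotypes + weights")
        scores = compute_scores(genotypes, weights)
    work = cohort.merge(
        scores[["individual_id", "rescaled"]].rename(columns={"rescaled": "grs"}),
        on="individual_id",
    )

    records: dict[str, TransformRecord] = {}
    exposed, rec = inverse_normal_transform(work[plan.exposure], name=plan.exposure)
    work["_exposure_sd"] = exposed
    records[plan.exposure] = rec

    manifest = {
        "package_version": __version__,
        "seed": plan.seed,
        "n_cohort": int(len(cohort)),
        "exposure": plan.exposure,
        "excluded_missing": {},
    }

    all_rows = []
    classic = [m for m in plan.methods if m in ("observational", "tsls")]
    sib_methods = [m for m in plan.methods if m in ("sib_nongenetic", "sib_mr")]
    ts_methods = [m for m in plan.methods if m in ("ivw", "egger", "weighted_median")]

    for spec in plan.outcomes:
        name, fam = spec["name"], spec.get("family", "linear")
        sub = work[work[name].notna() & work[plan.exposure].notna()].reset_index(drop=True)
        n_excl = len(work) - len(sub)
        manifest["excluded_missing"][name] = int(n_excl)
        _log(f"outcome {name}: n = {len(sub)} ({n_excl} excluded for missingness)")

        ycol = name
        if spec.get("transform", False) and fam == "linear":
            transformed, rec = inverse_normal_transform(sub[name], name=name)
            ycol = f"_{name}_sd"
            sub[ycol] = transformed
            records[name] = rec

        if classic:
            res = run_subgroups(
                sub,
                outcomes=[(ycol, fam)],
                exposure="_exposure_sd",
                score="grs",
                covariates=plan.covariates,
                methods=tuple(classic),
                subgroups=plan.subgroups,
            )
            res["outcome"] = name
            all_rows.append(res)

        if sib_methods and sub["family_id"].notna().any():
            sib_groups = {"all": None}
            if "men" in plan.subgroups:
                sib_groups["men"] = "male"
            if "women" in plan.subgroups:
                sib_groups["women"] = "female"
            for label, sexf in sib_groups.items():
                for m in sib_methods:
                    fn = sib_nongenetic if m == "sib_nongenetic" else sib_mr
                    try:
                        index = build_sibships(sub, plan.min_sibs, sexf)
                        args = dict(
                            cohort=sub, index=index, outcome=ycol,
                            covariates=plan.covariates, family=fam, subgroup=label,
                        )
                        if m == "sib_nongenetic":
                            rec_ = fn(exposure="_exposure_sd", **args)
                        else:
                            rec_ = fn(exposure="_exposure_sd", score="grs", **args)
                        row = {**rec_.to_dict(), "status": "ok", "outcome": name}
                    except Exception as exc:
                        row = {
                            "outcome": name, "method": m, "subgroup": label,
                            "status": str(exc),
                        }
                    all_rows.append(pd.DataFrame([row]))

        if ts_methods and genotypes is not None:
            geno_sub = genotypes.loc[sub["individual_id"]]
            ss = harmonize(
                summary_stats_from_cohort(
                    geno_sub, sub, "_exposure_sd", ycol, plan.covariates
                )
            )
            for m in ts_methods:
                try:
                    if m == "ivw":
                        recs = [ivw(ss)]
                    elif m == "egger":
                        recs = list(mr_egger(ss))
                    else:
                        recs = [weighted_median(ss, seed=plan.seed)]
                    for r in recs:
                        r.outcome = name
                        all_rows.append(
                            pd.DataFrame([{**r.to_dict(), "status": "ok"}])
                        )
                except Exception as exc:
                    all_rows.append(
                        pd.DataFrame(
                            [{"outcome": name, "method": m, "status": str(exc)}]
                        )
                    )

    results = pd.concat(all_rows, ignore_index=True) if all_rows else pd.DataFrame()
    for col in RESULT_COLUMNS:
        if col not in results.columns:
            results[col] = np.nan
    results = results[RESULT_COLUMNS].sort_values(
        ["outcome", "method", "subgroup"], kind="stable"
    ).reset_index(drop=True)
    manifest["n_result_rows"] = int(len(results))
    manifest["n_failed_cells"] = int((results["status"] != "ok").sum())
    return results, manifest, records


def report_natural_units(
    results: pd.DataFrame, records: dict[str, TransformRecord]
) -> pd.DataFrame:
    """Add natural-unit effect and CI columns to SD-scale result rows.

    Rows whose outcome lacks a :class:`TransformRecord` are flagged in
    ``natural_status`` rather than dropped.
    """
    out = results.copy()
    beta_nat, lo_nat, hi_nat, status = [], [], [], []
    for _, row in out.iterrows():
        rec = records.get(row["outcome"])
        if rec is None or row.get("scale") != "per-SD beta" or pd.isna(row["beta"]):
            beta_nat.append(np.nan)
            lo_nat.append(np.nan)
            hi_nat.append(np.nan)
            status.append("no transform record" if rec is None else "not SD scale")
            continue
        beta_nat.append(sd_to_natural(row["beta"], rec.natural_sd))
        lo_nat.append(sd_to_natural(row["ci_low"], rec.natural_sd))
        hi_nat.append(sd_to_natural(row["ci_high"], rec.natural_sd))
        status.append("ok")
    out["beta_natural"] = beta_nat
    out["ci_low_natural"] = lo_nat
    out["ci_high_natural"] = hi_nat
    out["natural_status"] = status
    return out


def run_nonlinear(
    plan: AnalysisPlan,
    cohort: pd.DataFrame,
    scores: pd.DataFrame,
) -> dict:
    """Non-linear MR for every plan outcome; returns {outcome: result dict}."""
    work = cohort.merge(
        scores[["individual_id", "rescaled"]].rename(columns={"rescaled": "grs"}),
        on="individual_id",
    )
    exposed, _ = inverse_normal_transform(work[plan.exposure], name=plan.exposure)
    work["_exposure_sd"] = exposed
    out = {}
    for spec in plan.outcomes:
        name, fam = spec["name"], spec.get("family", "linear")
        sub = work[work[name].notna()].reset_index(drop=True)
        ycol = name
        if spec.get("transform", False) and fam == "linear":
            sub[ycol + "_sd"], _ = inverse_normal_transform(sub[name], name=name)
            ycol = ycol + "_sd"
        res = nonlinear_mr(
            sub, ycol, "_exposure_sd", "grs", plan.covariates,
            k=plan.k_nonlinear, family=fam, exposure_natural=plan.exposure,
        )
        out[name] = {
            "strata": res.strata_frame(),
            "curve": res.curve,
            "p_quadratic": res.p_quadratic,
            "p_cochran_q": res.p_cochran_q,
        }
    return out


def write_outputs(out_dir, results: pd.DataFrame, manifest: dict) -> None:
    from .io import ensure_dir

    d = ensure_dir(out_dir)
    results.to_csv(d / "results.csv", index=False)
    with open(d / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
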