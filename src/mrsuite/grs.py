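"""Weighted genetic risk score construction and instrument strength.

The score of individual j is the weighted allele-dosage sum

    weighted_j = sum_i beta_i * dosage_ij

optionally rescaled to the trait-raising-allele-count scale

    rescaled_j = weighted_j * n_snps / sum_i beta_i

so one unit corresponds to one (average-effect) raising allele.  Downstream
IV estimates are invariant to this linear rescaling.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import AlignmentError, DegenerateInputError, EstimationError

_AMBIGUOUS = ({"A", "T"}, {"C", "G"})


def exclude_variants(weights: pd.DataFrame, exclusion_ids) -> pd.DataFrame:
    """Drop listed variants (e.g. known-pleiotropic ones) from a weights table.

    Unknown ids raise a warning, not an error.
    """
    exclusion = set(exclusion_ids)
    known = set(weights["variant_id"])
    unknown = exclusion - known
    if unknown:
        warnings.warn(f"exclusion ids not in weights table: {sorted(unknown)}")
    kept = weights[~weights["variant_id"].isin(exclusion)].reset_index(drop=True)
    if kept.empty:
        warnings.warn("all variants excluded; weights table is empty")
    return kept


def align_dosages(
    genotypes: pd.DataFrame,
    weights: pd.DataFrame,
    dosage_alleles: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Reorder dosage columns to the weights order and fix allele orientation.

    ``dosage_alleles`` (columns ``variant_id, effect_allele, other_allele``)
    states which allele the stored dosages count.  Where that allele is the
    weights table's *other* allele the dosage is flipped to ``2 - dosage``;
    strand-ambiguous variants (A/T, C/G) with mismatching alleles are
    rejected because the flip cannot be distinguished from a strand error.
    Without ``dosage_alleles`` the dosages are assumed already oriented.
    """
    missing = [v for v in weights["variant_id"] if v not in genotypes.columns]
    if missing:
        raise AlignmentError(f"variants missing from dosage matrix: {missing}")
    aligned = genotypes[weights["variant_id"].tolist()].copy()
    if dosage_alleles is None:
        return aligned

    meta = dosage_alleles.set_index("variant_id")
    for _, row in weights.iterrows():
        vid = row["variant_id"]
        if vid not in meta.index:
            raise AlignmentError(f"no allele metadata for variant {vid}")
        eff, oth = meta.loc[vid, "effect_allele"], meta.loc[vid, "other_allele"]
        if eff == row["effect_allele"] and oth == row["other_allele"]:
            continue
        if eff == row["other_allele"] and oth == row["effect_allele"]:
            if {eff, oth} in _AMBIGUOUS:
                raise AlignmentError(
                    f"strand-ambiguous allele mismatch at {vid} ({eff}/{oth}); "
                    "refusing to flip"
                )
            aligned[vid] = 2.0 - aligned[vid]
        else:
            raise AlignmentError(
                f"alleles at {vid} ({eff}/{oth}) do not match weights "
                f"({row['effect_allele']}/{row['other_allele']})"
            )
    return aligned


def weighted_score(
    genotypes: pd.DataFrame,
    weights: pd.DataFrame,
    missing: str = "error",
) -> pd.Series:
    """Per-individual weighted dosage sum (the raw score).

    ``missing='error'`` (default) rejects any missing dosage;
    ``missing='mean'`` imputes the per-variant mean dosage first.
    """
    aligned = genotypes[weights["variant_id"].tolist()]
    if aligned.isna().any().any():
        if missing == "mean":
            aligned = aligned.fillna(aligned.mean())
        else:
            bad = aligned.columns[aligned.isna().any()].tolist()
            raise DegenerateInputError(
                f"missing dosages at {bad}; pass missing='mean' to impute"
            )
    return pd.Series(
        aligned.to_numpy() @ weights["beta"].to_numpy(),
        index=genotypes.index,
        name="weighted",
    )


def rescale_score(weighted: pd.Series, weights: pd.DataFrame) -> pd.Series:
    """Rescale to the allele-count scale: weighted * n_snps / sum(beta)."""
    beta_sum = float(weights["beta"].sum())
    if beta_sum == 0.0:
        raise DegenerateInputError("sum of betas is zero; rescaling undefined")
    return (weighted * len(weights) / beta_sum).rename("rescaled")


def compute_scores(
    genotypes: pd.DataFrame,
    weights: pd.DataFrame,
    dosage_alleles: pd.DataFrame | None = None,
    missing: str = "error",
) -> pd.DataFrame:
    """Align, score and rescale in one step; returns a ScoreVector table."""
    aligned = align_dosages(genotypes, weights, dosage_alleles)
    w = weighted_score(aligned, weights, missing=missing)
    return pd.DataFrame(
        {
            "individual_id": genotypes.index,
            "weighted": w.to_numpy(),
            "rescaled": rescale_score(w, weights).to_numpy(),
        }
    )


def instrument_strength(
    score: np.ndarray,
    exposure: np.ndarray,
    covariates: np.ndarray | pd.DataFrame | None = None,
) -> tuple[float, float]:
    """Incremental R^2 of the score beyond covariates, and its partial F.

    Fits exposure ~ covariates and exposure ~ covariates + score; returns
    (R2_full - R2_reduced, partial F for the one added score term).
    """
    score = np.asarray(score, float)
    exposure = np.asarray(exposure, float)
    n = exposure.size
    base = np.ones((n, 1))
    if covariates is not None:
        cov = np.asarray(covariates, float)
        if cov.ndim == 1:
            cov = cov[:, None]
        base = np.column_stack([base, cov])
    if np.linalg.matrix_rank(base) < base.shape[1]:
        raise EstimationError("covariate matrix is rank deficient")
    full = np.column_stack([base, score])
    k = full.shape[1]
    if n <= k + 1:
        raise EstimationError("too few observations for instrument_strength")

    tss = float(np.sum((exposure - exposure.mean()) ** 2))
    rss0 = float(np.sum((exposure - base @ np.linalg.lstsq(base, exposure, rcond=None)[0]) ** 2))
    rss1 = float(np.sum((exposure - full @ np.linalg.lstsq(full, exposure, rcond=None)[0]) ** 2))
    r2_incr = (rss0 - rss1) / tss
    f_stat = (rss0 - rss1) / (rss1 / (n - k)) if rss1 > 0 else np.inf
    return r2_incr, f_stat
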