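"""Rank-based inverse-normal transformation and SD <-> natural-unit conversion.

Continuous phenotypes (deprivation index, income, years of education,
BMI itself) are mapped to normal quantiles of their rank fractions using
the Blom offset, Phi^{-1}((r - 3/8)/(n + 1/4)), with average ranks for
ties; effects estimated on that SD scale are converted back to natural
units by multiplying by the raw variable's standard deviation (e.g. a
0.05 SD effect on a deprivation index with SD 2.99 is 0.150 index units).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError


@dataclass(frozen=True)
class TransformRecord:
    """Audit record for one transformed variable."""

    variable_name: str
    n_nonmissing: int
    natural_sd: float
    tie_policy: str = "average-rank, Blom offset 3/8"


def inverse_normal_transform(
    values, name: str = ""
) -> tuple[np.ndarray, TransformRecord]:
    """Blom rank-based inverse-normal transform.

    Missing entries (NaN) are preserved; ties get average ranks so equal
    inputs map to equal outputs and the result is invariant to any strictly
    monotone re-labelling of the input.

    Returns the transformed vector and a :class:`TransformRecord` carrying
    the raw variable's SD for later natural-unit conversion.

    Raises
    ------
    DegenerateInputError
        Fewer than 2 non-missing values, or all non-missing values equal.
    """
    arr = np.asarray(values, dtype=float)
    mask = ~np.isnan(arr)
    obs = arr[mask]
    n = obs.size
    if n < 2:
        raise DegenerateInputError("need at least 2 non-missing values")
    if np.ptp(obs) == 0.0:
        raise DegenerateInputError("all non-missing values are equal")
    ranks = stats.rankdata(obs, method="average")
    out = np.full(arr.shape, np.nan)
    out[mask] = stats.norm.ppf((ranks - 0.375) / (n + 0.25))
    record = TransformRecord(
        variable_name=name, n_nonmissing=int(n), natural_sd=float(np.std(obs, ddof=1))
    )
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index, name=values.name), record
    return out, record


def sd_to_natural(beta_sd: float, natural_sd: float) -> float:
    """Convert an SD-scale effect to natural units: beta_sd * natural_sd.

    Exact (unrounded); callers round for reporting.  Raises on
    non-positive ``natural_sd``.
    """
    if natural_sd <= 0:
        raise DegenerateInputError(f"natural_sd must be > 0, got {natural_sd}")
    return beta_sd * natural_sd
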