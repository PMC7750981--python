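"""Shared helpers for the test suite: simulate + score + standardize."""

from __future__ import annotations

import numpy as np
import pandas as pd

from mrsuite import (
    SimConfig,
    compute_scores,
    simulate_sibships,
    simulate_unrelated,
    simulate_variant_panel,
)


def add_sd_scale(cohort: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Recover the latent SD-scale exposure/outcome via the config constants."""
    out = cohort.copy()
    out["x"] = (out["bmi"] - config.exposure_mean) / config.exposure_sd
    out["y"] = (out["deprivation"] - config.outcome_mean) / config.outcome_sd
    return out


def merge_scores(
    genotypes: pd.DataFrame, cohort: pd.DataFrame, weights: pd.DataFrame
) -> pd.DataFrame:
    scores = compute_scores(genotypes, weights)
    return cohort.merge(
        scores.rename(columns={"rescaled": "grs"})[
            ["individual_id", "grs", "weighted"]
        ],
        on="individual_id",
    )


def simulate_ready(config: SimConfig, design: str = "unrelated"):
    """Panel + cohort + scores + SD-scale columns in one call."""
    weights = simulate_variant_panel(config)
    sim = simulate_unrelated if design == "unrelated" else simulate_sibships
    genotypes, cohort = sim(config, weights)
    cohort = add_sd_scale(merge_scores(genotypes, cohort, weights), config)
    return weights, genotypes, cohort


def ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    """Simple-regression slope: an independent closed-form oracle."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc = x - x.mean()
    return float(xc @ (y - y.mean()) / (xc @ xc))
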