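"""Stress-tolerance indices and descriptive phenotype statistics.

The stress index of a yield-related trait is the ratio of its value under
stress (drought or chronic low nitrogen) to its value under the non-stress
condition; the complementary percent reduction is
``100 (control - stress) / control``, so ``index + reduction/100 == 1``
whenever both derive from the same pair of measurements.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["stress_index", "percent_reduction", "stress_index_table", "trait_correlations"]


def stress_index(trait_stress: float, trait_control: float) -> float:
    """Stress/control ratio of one trait (reported to two decimals)."""
    if trait_control <= 0:
        raise ValueError("control value must be positive")
    return trait_stress / trait_control


def percent_reduction(
    trait_control: float,
    absolute_reduction: float | None = None,
    trait_stress: float | None = None,
) -> float:
    """Percent reduction under stress, ``100 * reduction / control``.

    Accepts either the absolute reduction or the stressed trait value
    (exactly one of the two).
    """
    if trait_control <= 0:
        raise ValueError("control value must be positive")
    if (absolute_reduction is None) == (trait_stress is None):
        raise ValueError("give exactly one of absolute_reduction or trait_stress")
    if absolute_reduction is None:
        absolute_reduction = trait_control - trait_stress
    return 100.0 * absolute_reduction / trait_control


def stress_index_table(
    phenotypes: pd.DataFrame,
    stress: str,
    control: str = "normal",
    traits: tuple[str, ...] = ("PN", "FGN", "TGW", "SF", "GY"),
) -> pd.DataFrame:
    """Per-line stress indices for each yield-related trait.

    Line means are taken within each environment first; lines lacking either
    environment, or with a non-positive control mean, get missing entries.
    Columns: ``index_<trait>`` (ratio) and ``reduction_<trait>`` (percent).
    """
    out = None
    for which, env in (("stress", stress), ("control", control)):
        sub = phenotypes[phenotypes["environment"] == env]
        if sub.empty:
            raise ValueError(f"no phenotypes for environment {env!r}")
        means = sub.groupby("line_id")[list(traits)].mean()
        means.columns = [f"{which}_{t}" for t in traits]
        out = means if out is None else out.join(means, how="outer")
    for t in traits:
        c = out[f"control_{t}"]
        s = out[f"stress_{t}"]
        valid = c > 0
        out[f"index_{t}"] = np.where(valid, s / c, np.nan)
        out[f"reduction_{t}"] = np.where(valid, 100.0 * (c - s) / c, np.nan)
    return out[[f"index_{t}" for t in traits] + [f"reduction_{t}" for t in traits]].reset_index()


def trait_correlations(
    phenotypes: pd.DataFrame,
    environment: str,
    traits: tuple[str, ...] = ("HD", "PH", "PN", "FGN", "TGW", "SF", "GY"),
    cross_environment: str | None = None,
) -> pd.DataFrame:
    """Pearson correlations among line-mean traits within one environment.

    Pairwise-complete handling; entries with fewer than 3 complete pairs are
    set to missing.  If ``cross_environment`` is given, an extra row
    ``cross_env`` holds, per trait, the correlation of the same trait's line
    means between the two environments (low values indicate strong G x E).
    """
    sub = phenotypes[phenotypes["environment"] == environment]
    if sub.empty:
        raise ValueError(f"no phenotypes for environment {environment!r}")
    means = sub.groupby("line_id")[list(traits)].mean()
    corr = means.corr(method="pearson", min_periods=3)
    if cross_environment is not None:
        other = phenotypes[phenotypes["environment"] == cross_environment]
        other_means = other.groupby("line_id")[list(traits)].mean()
        joined = means.join(other_means, how="inner", lsuffix="_a", rsuffix="_b")
        row = {}
        for t in traits:
            pair = joined[[f"{t}_a", f"{t}_b"]].dropna()
            row[t] = pair[f"{t}_a"].corr(pair[f"{t}_b"]) if len(pair) >= 3 else np.nan
        corr.loc["cross_env"] = pd.Series(row)
    return corr
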