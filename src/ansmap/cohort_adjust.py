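"""Age/gender adjustment of autonomic proxies via saturated 2-way ANOVA.

Clinical groups in ambulatory cohorts differ systematically in age and sex
composition (athletes young and mostly male, hypertensives older, obese
cohorts mostly female), so raw proxies are not comparable across groups.
Each proxy is therefore replaced by its residual from a full two-way ANOVA
with age class, gender and their interaction.  Because the model is
saturated, the fitted value in every age-class x gender cell is the cell
mean, and the residual is simply the deviation from it; the adjusted
proxies are free of age and gender effects by construction (every cell of
adjusted values has mean zero).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .beat_spectral import PROXY_COLUMNS
from .errors import DegenerateInputError

__all__ = ["AgeClass", "DEFAULT_AGE_BINS", "bin_age", "adjust_proxies", "AdjustedProxyTable"]

AGE_MIN, AGE_MAX = 18, 75


@dataclass(frozen=True)
class AgeClass:
    """A closed age interval labelling one level of the age factor."""

    label: str
    low: float
    high: float

    def __contains__(self, age: float) -> bool:
        return self.low <= age <= self.high


#: Default 3-class binning: the cohort narrative hinges on the 34- and
#: 50-year cut points (nearly all athletes under 34; about half of the
#: hypertensives over 50), so those are the default boundaries.
DEFAULT_AGE_BINS = (
    AgeClass("young", 18, 34),
    AgeClass("middle", 35, 50),
    AgeClass("older", 51, 75),
)


def bin_age(age: float, bins: tuple[AgeClass, ...] = DEFAULT_AGE_BINS) -> AgeClass:
    """Map an age in years to its age class.

    Ages outside [18, 75] mirror the eligibility window of ambulatory
    screening cohorts and raise an error.
    """
    if not (AGE_MIN <= age <= AGE_MAX):
        raise ValueError(
            f"age {age} outside the eligible range [{AGE_MIN}, {AGE_MAX}] years"
        )
    # fractional ages between integer bounds (e.g. 34.5 with bins ..-34, 35-..)
    # belong to the class below the next lower bound
    ordered = sorted(bins, key=lambda c: c.low)
    chosen = ordered[0]
    for cls in ordered:
        if age >= cls.low:
            chosen = cls
    return chosen


@dataclass
class AdjustedProxyTable:
    """Adjusted proxies plus an audit of the fitted cell structure."""

    table: pd.DataFrame          # same rows as input; proxy columns are residuals
    cell_means: pd.DataFrame     # (age_class, gender) x proxy fitted means
    cell_counts: pd.Series       # subjects per cell

    def audit(self) -> dict:
        singles = self.cell_counts[self.cell_counts == 1]
        return {
            "cells": {str(k): int(v) for k, v in self.cell_counts.items()},
            "single_subject_cells": [str(k) for k in singles.index],
        }


def adjust_proxies(
    records: pd.DataFrame,
    age_bins: tuple[AgeClass, ...] = DEFAULT_AGE_BINS,
    proxies: list[str] | None = None,
) -> AdjustedProxyTable:
    """Residualise each proxy on age class x gender (saturated model).

    Parameters
    ----------
    records:
        Cohort table with the proxy columns plus ``age``, ``gender``,
        ``group``.
    age_bins:
        Partition of [18, 75] defining the categorical age factor.

    Returns the adjusted table (proxy columns replaced by residuals,
    covariate columns untouched) with the fitted cell means for audit.
    Cells with a single subject get residual 0 by construction and are
    flagged in the audit.
    """
    if len(records) == 0:
        raise DegenerateInputError("empty cohort: nothing to adjust")
    proxies = proxies or [c for c in PROXY_COLUMNS if c in records.columns]
    df = records.copy()
    age_class = df["age"].map(lambda a: bin_age(a, age_bins).label)
    genders = df["gender"].unique()
    if len(genders) < 2:
        warnings.warn("only one gender present; gender effect is not estimable", stacklevel=2)
    grouper = pd.DataFrame({"age_class": age_class.values, "gender": df["gender"].values},
                           index=df.index)
    means = df.groupby([grouper["age_class"], grouper["gender"]], observed=True)[proxies].transform("mean")
    adjusted = df.copy()
    adjusted[proxies] = df[proxies] - means
    for p in proxies:
        if np.isclose(df[p].std(ddof=0), 0.0):
            warnings.warn(f"proxy {p} is constant; residuals are all zero", stacklevel=2)
    cell_means = df.groupby([grouper["age_class"], grouper["gender"]], observed=True)[proxies].mean()
    cell_counts = df.groupby([grouper["age_class"], grouper["gender"]], observed=True).size()
    return AdjustedProxyTable(table=adjusted, cell_means=cell_means, cell_counts=cell_counts)
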