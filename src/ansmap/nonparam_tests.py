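"""Non-parametric two-sample permutation tests for test-vs-reference comparisons.

Two complementary procedures are applied to every adjusted proxy in every
clinical-group-vs-reference comparison:

* a permutation test of equality between the two kernel-estimated density
  functions (the Bowman-Azzalini construction): the statistic is the
  integrated squared difference between the two estimates computed with a
  common bandwidth, and a pointwise "reference band for equality" around
  the pooled estimate visualises where the curves separate;

* two one-sided Jonckheere-Terpstra permutation tests, one against the
  *increasing* alternative (the test group concentrated on smaller values
  than the reference) and one against the *decreasing* alternative.  With
  two groups the JT statistic reduces to the Mann-Whitney count of
  (reference, test) pairs in which the test value is larger, with ties
  contributing one half.

A proxy is *individually discriminant* only when both procedures reject at
the nominal level, which drives the joint type-I error below the nominal
level of either test alone (0.05^2 = 0.0025 under independence).  The
direction of a significant JT test and the magnitude of the worse of the
two p-values grade the finding for the significance diagram.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb, sqrt, pi
from typing import Literal

import numpy as np

__all__ = [
    "DensityComparison",
    "TestResult",
    "kernel_density",
    "normal_optimal_bandwidth",
    "ba_test",
    "jt_statistic",
    "jt_test",
    "joint_rule",
    "compare_groups",
]

GAUSS_ROUGHNESS = 1.0 / (2.0 * sqrt(pi))  # integral of the squared Gaussian kernel
EXACT_LIMIT = 12  # complete enumeration of group assignments up to this pooled n


@dataclass
class DensityComparison:
    """Density-equality comparison of a test sample against the reference.

    ``f_test`` and ``f_ref`` are the kernel estimates on ``grid`` with the
    common ``bandwidth``; ``band_low``/``band_high`` bound the reference
    band for equality around the pooled estimate; ``statistic`` is the
    integrated squared difference and ``p_value`` its permutation p-value.
    """

    grid: np.ndarray
    f_test: np.ndarray
    f_ref: np.ndarray
    band_low: np.ndarray
    band_high: np.ndarray
    bandwidth: float
    statistic: float
    p_value: float
    n_perm: int


@dataclass
class TestResult:
    """Outcome of the joint BA + JT evaluation for one proxy and one group."""

    proxy: str
    group: str
    ba_p: float
    jt_p_increasing: float
    jt_p_decreasing: float
    direction: Literal["higher", "lower", "none"] = "none"
    discriminant: bool = False
    shade: Literal["strong", "medium", "weak", "none"] = "none"


def normal_optimal_bandwidth(values: np.ndarray) -> float:
    """Normal-optimal (rule-of-thumb) bandwidth for a Gaussian kernel."""
    values = np.asarray(values, dtype=float)
    sd = float(np.std(values, ddof=1))
    if sd == 0.0:
        sd = max(abs(float(np.mean(values))), 1.0) * 1e-8  # degenerate sample
    return sd * (4.0 / (3.0 * values.size)) ** 0.2


def kernel_density(
    values: np.ndarray,
    bandwidth: float | str = "auto",
    grid: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Gaussian kernel density estimate.

    Returns ``(grid, density, bandwidth)``.  ``"auto"`` uses the
    normal-optimal rule.  The default grid spans the data range plus three
    bandwidths on 200 equally spaced points.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 10:
        raise ValueError(f"kernel density needs >= 10 observations, got {values.size}")
    h = normal_optimal_bandwidth(values) if bandwidth == "auto" else float(bandwidth)
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    if grid is None:
        grid = np.linspace(values.min() - 3 * h, values.max() + 3 * h, 200)
    z = (grid[None, :] - values[:, None]) / h
    dens = np.exp(-0.5 * z * z).sum(axis=0) / (values.size * h * sqrt(2 * pi))
    return grid, dens, h


def _kernel_matrix(pooled: np.ndarray, grid: np.ndarray, h: float) -> np.ndarray:
    z = (grid[None, :] - pooled[:, None]) / h
    return np.exp(-0.5 * z * z) / (h * sqrt(2 * pi))


def ba_test(
    test_vals: np.ndarray,
    ref_vals: np.ndarray,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> DensityComparison:
    """Permutation test of equality between two kernel density estimates.

    The common bandwidth is the geometric mean of the two samples'
    normal-optimal bandwidths.  The null distribution of the integrated
    squared difference is obtained by randomly permuting the group labels
    over the pooled sample; the p-value uses the add-one correction
    ``(1 + #{T_perm >= T_obs}) / (1 + n_perm)``.

    The reference band for equality is the pooled density estimate plus or
    minus one standard error of the estimated density difference under
    equality: two curves lying inside the band are consistent with a common
    density at that point.
    """
    test_vals = np.asarray(test_vals, dtype=float)
    ref_vals = np.asarray(ref_vals, dtype=float)
    if test_vals.size < 10 or ref_vals.size < 10:
        raise ValueError("each sample needs >= 10 observations")
    if n_perm < 200:
        raise ValueError("n_perm < 200 gives unstable permutation p-values")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_t, n_r = test_vals.size, ref_vals.size
    h = sqrt(normal_optimal_bandwidth(test_vals) * normal_optimal_bandwidth(ref_vals))
    pooled = np.concatenate([test_vals, ref_vals])
    n = pooled.size
    lo, hi = pooled.min() - 3 * h, pooled.max() + 3 * h
    grid = np.linspace(lo, hi, 200)
    dx = grid[1] - grid[0]

    K = _kernel_matrix(pooled, grid, h)          # n x grid
    w_obs = np.concatenate([np.full(n_t, 1.0 / n_t), np.full(n_r, -1.0 / n_r)])
    f_test = K[:n_t].mean(axis=0)
    f_ref = K[n_t:].mean(axis=0)

    # T(w) = integral (sum_i w_i k_i)^2 = w' M w with M the kernel Gram matrix
    M = (K * dx) @ K.T
    t_obs = float(w_obs @ M @ w_obs)

    # each permutation row lists the pooled indices assigned to the test group
    perm_idx = np.argsort(rng.random((n_perm, n)), axis=1)
    W = np.full((n_perm, n), -1.0 / n_r)
    rows = np.repeat(np.arange(n_perm), n_t)
    W[rows, perm_idx[:, :n_t].ravel()] = 1.0 / n_t
    t_perm = np.einsum("pi,ij,pj->p", W, M, W)
    p = (1.0 + int(np.sum(t_perm >= t_obs - 1e-15))) / (1.0 + n_perm)

    f_pool = K.mean(axis=0)
    se = np.sqrt(np.clip(f_pool, 0.0, None) * GAUSS_ROUGHNESS * (1.0 / n_t + 1.0 / n_r) / h)
    return DensityComparison(
        grid=grid,
        f_test=f_test,
        f_ref=f_ref,
        band_low=np.clip(f_pool - se, 0.0, None),
        band_high=f_pool + se,
        bandwidth=h,
        statistic=t_obs,
        p_value=p,
        n_perm=n_perm,
    )


def jt_statistic(ref_vals: np.ndarray, test_vals: np.ndarray) -> float:
    """Two-group JT statistic: #{(r, t) : t > r} + half the ties."""
    r = np.asarray(ref_vals, dtype=float)[:, None]
    t = np.asarray(test_vals, dtype=float)[None, :]
    return float(np.sum(t > r) + 0.5 * np.sum(t == r))


def jt_test(
    test_vals: np.ndarray,
    ref_vals: np.ndarray,
    alternative: Literal["increasing", "decreasing"],
    n_perm: int | str = 1000,
    seed: int | np.random.Generator | None = None,
    method: Literal["auto", "exact", "perm"] = "auto",
) -> float:
    """One-sided two-group Jonckheere-Terpstra permutation p-value.

    Groups are ordered (reference, test).  Under the *increasing*
    alternative the test group is concentrated on smaller values than the
    reference (small JT statistic); under the *decreasing* alternative on
    larger values (large statistic).  The null distribution is obtained by
    complete enumeration of group assignments when the pooled sample has at
    most 12 observations or when ``n_perm="exact"``, otherwise by random
    permutation with the add-one correction.
    """
    test_vals = np.asarray(test_vals, dtype=float)
    ref_vals = np.asarray(ref_vals, dtype=float)
    if test_vals.size < 2 or ref_vals.size < 2:
        raise ValueError("each sample needs >= 2 observations")
    if alternative not in ("increasing", "decreasing"):
        raise ValueError(f"unknown alternative {alternative!r}")
    pooled = np.concatenate([ref_vals, test_vals])
    n_r, n_t = ref_vals.size, test_vals.size
    n = pooled.size
    if np.all(pooled == pooled[0]):
        return 1.0
    u_obs = jt_statistic(ref_vals, test_vals)

    if method == "auto":
        exact = n_perm == "exact" or n <= EXACT_LIMIT
    else:
        exact = method == "exact"
    tol = 1e-9
    if exact:
        total = comb(n, n_t)
        count = 0
        idx_all = frozenset(range(n))
        for test_idx in combinations(range(n), n_t):
            t = pooled[list(test_idx)]
            r = pooled[list(idx_all - set(test_idx))]
            u = jt_statistic(r, t)
            if alternative == "increasing":
                count += u <= u_obs + tol
            else:
                count += u >= u_obs - tol
        return count / total

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_perm = int(n_perm)
    # rank-based evaluation: U = sum of midranks of the test group - n_t(n_t+1)/2
    from scipy.stats import rankdata

    ranks = rankdata(pooled)
    perm_idx = np.argsort(rng.random((n_perm, n)), axis=1)[:, :n_t]
    u_perm = ranks[perm_idx].sum(axis=1) - n_t * (n_t + 1) / 2.0
    if alternative == "increasing":
        count = int(np.sum(u_perm <= u_obs + tol))
    else:
        count = int(np.sum(u_perm >= u_obs - tol))
    return (1.0 + count) / (1.0 + n_perm)


_SHADES = ((0.001, "strong"), (0.01, "medium"), (0.05, "weak"))


def joint_rule(
    ba_p: float,
    jt_p_inc: float,
    jt_p_dec: float,
    alpha: float = 0.05,
    *,
    proxy: str = "",
    group: str = "",
) -> TestResult:
    """Combine BA and JT p-values into the joint discriminance verdict.

    A proxy is discriminant only if the BA test *and* at least one one-sided
    JT test reject at ``alpha``.  Direction follows the significant JT
    alternative: *increasing* significant means the test group sits on
    smaller values (direction ``lower``), *decreasing* means ``higher``.
    The shade grades joint significance by the worse of the BA p-value and
    the better JT p-value (<=0.001 strong, <=0.01 medium, <=0.05 weak).
    """
    for name, p in (("ba_p", ba_p), ("jt_p_inc", jt_p_inc), ("jt_p_dec", jt_p_dec)):
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"{name}={p} outside [0, 1]")
    inc_sig = jt_p_inc < alpha
    dec_sig = jt_p_dec < alpha
    if inc_sig and dec_sig:
        raise ValueError(
            "both one-sided JT alternatives significant simultaneously; "
            "inconsistent input p-values"
        )
    direction = "lower" if inc_sig else "higher" if dec_sig else "none"
    discriminant = ba_p < alpha and (inc_sig or dec_sig)
    shade = "none"
    if discriminant:
        joint = max(ba_p, min(jt_p_inc, jt_p_dec))
        for cut, label in _SHADES:
            if joint <= cut:
                shade = label
                break
    return TestResult(
        proxy=proxy,
        group=group,
        ba_p=ba_p,
        jt_p_increasing=jt_p_inc,
        jt_p_decreasing=jt_p_dec,
        direction=direction,
        discriminant=discriminant,
        shade=shade,
    )


def compare_groups(
    adjusted,
    reference: str = "Normal",
    proxies: list[str] | None = None,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int | None = None,
) -> list[TestResult]:
    """Run the BA + JT battery for every proxy in every test group.

    ``adjusted`` is a cohort DataFrame (typically of adjusted proxies) with
    ``group`` labels; every non-reference group is compared to the
    reference.  Results are deterministic for a given seed.
    """
    import pandas as pd

    from .beat_spectral import PROXY_COLUMNS

    if reference not in set(adjusted["group"]):
        raise ValueError(f"reference group {reference!r} absent from the table")
    proxies = proxies or [c for c in PROXY_COLUMNS if c in adjusted.columns]
    rng = np.random.default_rng(seed)
    ref_df = adjusted[adjusted["group"] == reference]
    results: list[TestResult] = []
    groups = [g for g in pd.unique(adjusted["group"]) if g != reference]
    for group in groups:
        test_df = adjusted[adjusted["group"] == group]
        for proxy in proxies:
            t = test_df[proxy].dropna().to_numpy()
            r = ref_df[proxy].dropna().to_numpy()
            ba = ba_test(t, r, n_perm=n_perm, seed=rng)
            p_inc = jt_test(t, r, "increasing", n_perm=n_perm, seed=rng)
            p_dec = jt_test(t, r, "decreasing", n_perm=n_perm, seed=rng)
            results.append(
                joint_rule(ba.p_value, p_inc, p_dec, alpha, proxy=proxy, group=group)
            )
    return results
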