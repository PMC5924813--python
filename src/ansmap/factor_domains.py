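"""Latent autonomic domains by principal-factor analysis with varimax rotation.

The 16 autonomic proxies are heavily redundant: normalized oscillatory
indices move together, absolute powers move together, and so do the
pressure and the pulse measures.  Factor analysis of the proxy correlation
matrix compresses this redundancy into a few uncorrelated latent domains.
Extraction is iterated principal-axis factoring (squared multiple
correlations as starting communalities), rotation is orthogonal varimax
with Kaiser row normalization.  A factor is retained as a latent domain
when it explains at least 10% of the total communality; each proxy is then
assigned to the retained factor on which it loads most strongly, provided
that loading reaches the salience threshold (default |loading| >= 0.5),
and is excluded from the domain structure otherwise.

Domains whose memberships coincide with the canonical autonomic sets are
named accordingly: Oscillatory (normalized LF/HF indices and the
orthostatic LFnu change), Amplitude (absolute powers and baroreflex gain),
Pressure (arterial pressures), Pulse (heart rate and mean RR).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .beat_spectral import PROXY_COLUMNS
from .errors import DegenerateInputError

__all__ = [
    "LoadingMatrix",
    "Domain",
    "DomainStructure",
    "CANONICAL_DOMAINS",
    "correlation_matrix",
    "principal_factor",
    "varimax",
    "retain_and_assign",
    "extract_domains",
    "tucker_congruence",
]

#: Canonical proxy memberships used to name recovered domains.
CANONICAL_DOMAINS = {
    "Oscillatory": frozenset({"RR_LFnu", "RR_HFnu", "RR_LF_HF", "dRRLFnu"}),
    "Amplitude": frozenset({"RR_TP", "RR_LFa", "RR_HFa", "alpha"}),
    "Pressure": frozenset({"SAP", "DAP", "SAP_Mean"}),
    "Pulse": frozenset({"HR", "RR_Mean"}),
}


@dataclass
class LoadingMatrix:
    """Proxy x factor loading matrix (entries are proxy-factor correlations)."""

    loadings: np.ndarray           # (n_proxies, n_factors)
    proxies: list[str]

    def __post_init__(self):
        L = np.asarray(self.loadings, dtype=float)
        if L.ndim != 2 or L.shape[0] != len(self.proxies):
            raise ValueError("loadings shape must be (n_proxies, n_factors)")
        if np.any(np.abs(L) > 1 + 1e-8):
            raise ValueError("|loading| must not exceed 1")
        self.loadings = L

    @property
    def communalities(self) -> np.ndarray:
        """Per-proxy share of variance reproduced by the common factors."""
        return (self.loadings ** 2).sum(axis=1)

    @property
    def total_communality(self) -> float:
        return float(self.communalities.sum())

    def factor_shares(self) -> np.ndarray:
        """Each factor's fraction of the total communality."""
        return (self.loadings ** 2).sum(axis=0) / self.total_communality


@dataclass
class Domain:
    """One retained latent domain."""

    name: str
    members: dict[str, float]      # proxy -> rotated loading (signed)
    share: float                   # fraction of total communality

    @property
    def proxies(self) -> list[str]:
        return list(self.members)


@dataclass
class DomainStructure:
    """Retained domains, proxy assignments and exclusions."""

    domains: list[Domain]
    excluded: list[str]
    salience: float
    loading_matrix: LoadingMatrix = field(repr=False, default=None)

    @property
    def cumulative_shares(self) -> list[float]:
        return list(np.cumsum([d.share for d in self.domains]))

    def membership(self) -> dict[str, str]:
        return {p: d.name for d in self.domains for p in d.members}

    def to_dict(self) -> dict:
        return {
            "salience": self.salience,
            "domains": [
                {
                    "name": d.name,
                    "members": {k: round(v, 4) for k, v in d.members.items()},
                    "percent_communality": round(100 * d.share, 2),
                }
                for d in self.domains
            ],
            "cumulative_percent_communality": [
                round(100 * c, 2) for c in self.cumulative_shares
            ],
            "excluded": self.excluded,
        }


def correlation_matrix(table: pd.DataFrame, proxies: list[str] | None = None,
                       min_records: int = 50) -> pd.DataFrame:
    """Pearson correlation matrix of the proxy columns (complete records)."""
    proxies = proxies or [c for c in PROXY_COLUMNS if c in table.columns]
    data = table[proxies].dropna()
    if len(data) < min_records:
        raise DegenerateInputError(
            f"only {len(data)} complete records; >= {min_records} required"
        )
    stds = data.std(ddof=0)
    constant = stds[stds == 0].index.tolist()
    if constant:
        raise DegenerateInputError(f"constant proxy column(s): {constant}")
    return data.corr()


def _smc(corr: np.ndarray) -> np.ndarray:
    """Squared multiple correlations (starting communalities)."""
    try:
        inv = np.linalg.inv(corr)
        return 1.0 - 1.0 / np.diag(inv)
    except np.linalg.LinAlgError:
        # singular matrix: fall back to max absolute off-diagonal correlation
        off = corr - np.eye(corr.shape[0])
        return np.max(np.abs(off), axis=1)


def principal_factor(
    corr: pd.DataFrame | np.ndarray,
    n_factors: int,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> LoadingMatrix:
    """Iterated principal-axis factor extraction.

    Communalities start at the squared multiple correlations, replace the
    diagonal of the correlation matrix, and are re-estimated from the
    leading eigenstructure until convergence.  Heywood cases (communality
    above 1) are clamped with a warning.
    """
    if isinstance(corr, pd.DataFrame):
        proxies = list(corr.columns)
        R = corr.to_numpy(dtype=float)
    else:
        R = np.asarray(corr, dtype=float)
        proxies = [f"var{i}" for i in range(R.shape[0])]
    p = R.shape[0]
    if n_factors >= p:
        raise ValueError("n_factors must be smaller than the number of proxies")
    if not np.allclose(R, R.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    h2 = np.clip(_smc(R), 0.0, 1.0)
    L = np.zeros((p, n_factors))
    for _ in range(max_iter):
        Rr = R.copy()
        np.fill_diagonal(Rr, h2)
        vals, vecs = np.linalg.eigh(Rr)
        idx = np.argsort(vals)[::-1][:n_factors]
        lam = np.clip(vals[idx], 0.0, None)
        L = vecs[:, idx] * np.sqrt(lam)
        h2_new = (L ** 2).sum(axis=1)
        if np.any(h2_new > 1.0):
            warnings.warn("Heywood case: communality above 1 clamped", stacklevel=2)
            h2_new = np.clip(h2_new, 0.0, 1.0)
        if np.max(np.abs(h2_new - h2)) < tol:
            h2 = h2_new
            break
        h2 = h2_new
    # order factors by explained communality, largest first
    order = np.argsort((L ** 2).sum(axis=0))[::-1]
    return LoadingMatrix(np.clip(L[:, order], -1.0, 1.0), proxies)


def varimax(
    lm: LoadingMatrix, kaiser: bool = True, tol: float = 1e-12, max_iter: int = 500
) -> LoadingMatrix:
    """Orthogonal varimax rotation (Kaiser row normalization on by default).

    Per-proxy communalities are invariant under the rotation; after
    rotation, column signs are fixed so each factor's largest-magnitude
    loading is positive, and columns are re-ordered by explained
    communality.
    """
    L = lm.loadings.copy()
    p, k = L.shape
    if k < 2:
        return LoadingMatrix(L, list(lm.proxies))
    h = np.sqrt(np.clip((L ** 2).sum(axis=1), 1e-12, None)) if kaiser else np.ones(p)
    A = L / h[:, None]
    R = np.eye(k)
    d_old = 0.0
    for _ in range(max_iter):
        B = A @ R
        G = A.T @ (B ** 3 - B @ np.diag((B ** 2).mean(axis=0)))
        U, s, Vt = np.linalg.svd(G)
        R = U @ Vt
        d = s.sum()
        if d_old != 0 and d < d_old * (1 + tol):
            break
        d_old = d
    out = (A @ R) * h[:, None]
    # sign convention: dominant loading of each factor positive
    for j in range(out.shape[1]):
        if out[np.argmax(np.abs(out[:, j])), j] < 0:
            out[:, j] = -out[:, j]
    order = np.argsort((out ** 2).sum(axis=0))[::-1]
    return LoadingMatrix(np.clip(out[:, order], -1.0, 1.0), list(lm.proxies))


def retain_and_assign(lm: LoadingMatrix, salience: float = 0.5,
                      min_share: float = 0.10) -> DomainStructure:
    """Retain factors by the 10%-of-communality rule and assign proxies.

    Factors are scanned in decreasing order of explained communality; the
    leading run of factors each holding at least ``min_share`` of the total
    communality is retained.  A proxy joins the retained factor on which
    its absolute loading is maximal if that loading reaches ``salience``;
    otherwise it is excluded.  Domains matching the canonical autonomic
    membership sets get their conventional names, others are ``Unnamed-k``.
    """
    shares = lm.factor_shares()
    # columns arrive ordered by explained communality; retain the leading
    # run of factors that each pass the minimum-share rule
    retained: list[int] = []
    for j in range(len(shares)):
        if shares[j] >= min_share:
            retained.append(j)
        else:
            break
    if not retained:
        raise DegenerateInputError(
            "no factor explains the minimum share of total communality"
        )
    L = lm.loadings
    members: dict[int, dict[str, float]] = {j: {} for j in retained}
    excluded: list[str] = []
    for i, proxy in enumerate(lm.proxies):
        sub = np.abs(L[i, retained])
        best = int(np.argmax(sub))
        if sub[best] >= salience:
            members[retained[best]][proxy] = float(L[i, retained[best]])
        else:
            excluded.append(proxy)
    domains = []
    unnamed = 0
    for j in retained:
        mem = members[j]
        if not mem:
            continue
        name = None
        for cname, cset in CANONICAL_DOMAINS.items():
            if frozenset(mem) == cset:
                name = cname
                break
        if name is None:
            unnamed += 1
            name = f"Unnamed-{unnamed}"
        domains.append(Domain(name=name, members=mem, share=float(shares[j])))
    if not domains:
        raise DegenerateInputError("all proxies fell below the salience threshold")
    return DomainStructure(domains=domains, excluded=excluded, salience=salience,
                           loading_matrix=lm)


def extract_domains(
    table: pd.DataFrame,
    n_factors: int = 4,
    salience: float = 0.5,
    proxies: list[str] | None = None,
) -> DomainStructure:
    """Correlations -> principal factoring -> varimax -> domain retention."""
    corr = correlation_matrix(table, proxies=proxies)
    lm = principal_factor(corr, n_factors=n_factors)
    rotated = varimax(lm)
    return retain_and_assign(rotated, salience=salience)


def tucker_congruence(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise Tucker congruence coefficients between factor columns."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    num = a.T @ b
    den = np.sqrt(np.outer((a ** 2).sum(axis=0), (b ** 2).sum(axis=0)))
    return num / den
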