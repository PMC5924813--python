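"""Autoregressive spectral analysis of beat-by-beat cardiovascular series.

Short-term heart rate variability (HRV) work decomposes the tachogram (the
beat-indexed series of RR intervals, in ms) and the systogram (beat-indexed
systolic arterial pressure, in mmHg) into oscillatory components.  An AR
model is fitted to the mean-removed series by Burg's method; the spectrum is
then split into components by evaluating the residues of the AR power
spectral density at its poles, so that each pole pair contributes one
component with a center frequency and an absolute power.  Component powers
sum to the process variance, which makes band powers directly comparable to
the total power (variance) of the series.

Frequencies are natively in cycles/beat; they are converted to Hz by
dividing by the mean beat interval in seconds, so that the conventional
low-frequency (0.03-0.14 Hz) and high-frequency (0.15-0.35 Hz) band limits
apply.  Components carrying less than 5% of total power are treated as
noise and excluded from the bands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .errors import DegenerateInputError, SeriesTooShortError

__all__ = [
    "BeatSeries",
    "SpectralComponent",
    "SpectrumDecomposition",
    "ProxyRecord",
    "PROXY_COLUMNS",
    "burg_ar",
    "fit_ar_spectrum",
    "classify_band",
    "band_powers",
    "normalized_units",
    "alpha_index",
    "compute_proxies",
]

MIN_BEATS = 64

#: The 16 autonomic proxies, in canonical column order.
PROXY_COLUMNS = [
    "HR", "RR_Mean", "RR_TP", "RR_LFa", "RR_HFa", "RR_LFnu", "RR_HFnu",
    "RR_LF_HF", "RR_LFHz", "RR_HFHz", "dRRLFnu", "alpha",
    "SAP", "DAP", "SAP_Mean", "SAP_LFa",
]

LF_BAND = (0.03, 0.14)  # Hz
HF_BAND = (0.15, 0.35)  # Hz
NOISE_FRACTION = 0.05


@dataclass(frozen=True)
class BeatSeries:
    """One subject's beat-indexed series in one posture condition.

    ``values`` are per-beat measurements: RR intervals in ms or systolic
    pressures in mmHg.  Values must be strictly positive and free of
    missing entries; cleaning (ectopy editing etc.) is the caller's
    responsibility.
    """

    values: np.ndarray
    kind: Literal["RR", "SAP"]
    condition: Literal["rest", "stand"] = "rest"
    subject_id: str = ""

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size == 0:
            raise ValueError("BeatSeries values must be a non-empty 1-d array")
        if not np.all(np.isfinite(v)):
            raise ValueError("BeatSeries values contain NaN/inf; clean the series first")
        if np.any(v <= 0):
            raise ValueError("BeatSeries values must be strictly positive")
        if self.kind not in ("RR", "SAP"):
            raise ValueError(f"kind must be 'RR' or 'SAP', got {self.kind!r}")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class SpectralComponent:
    """One AR spectral component (one pole or conjugate pole pair)."""

    center_freq: float            # Hz
    power: float                  # ms^2 (RR) or mmHg^2 (SAP)
    power_fraction: float         # power / total spectral power
    band: Literal["VLF", "LF", "HF", "noise", "unclassified"] = "unclassified"


@dataclass(frozen=True)
class SpectrumDecomposition:
    """Full AR decomposition of one beat series."""

    components: tuple[SpectralComponent, ...]
    total_power: float            # variance units of the series
    ar_order: int
    mean_interval_s: float        # beat -> Hz conversion factor

    def classified(self) -> "SpectrumDecomposition":
        """Return a copy with every component assigned to a band."""
        comps = tuple(classify_band(c, self) for c in self.components)
        return replace(self, components=comps)


def burg_ar(x: np.ndarray, order: int) -> tuple[np.ndarray, float]:
    """Fit an AR(order) model by Burg's method.

    Returns ``(a, sigma2)`` where ``a`` is the prediction polynomial
    ``[1, a1, ..., ap]`` (poles are the roots of ``sum a_k z^{p-k}``) and
    ``sigma2`` the driving-noise variance, normalised so that the discrete
    PSD ``sigma2 / |A(e^{-i 2 pi f})|^2`` integrates over ``[-1/2, 1/2]``
    to the process variance.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if order >= n:
        raise ValueError(f"AR order {order} requires more than {order} samples")
    f = x.copy()
    b = x.copy()
    a = np.array([1.0])
    e = float(np.dot(x, x)) / n
    if e == 0.0:
        raise DegenerateInputError("zero-variance series: AR model is undefined")
    for _ in range(order):
        ff = f[1:]
        bb = b[:-1]
        den = float(np.dot(ff, ff) + np.dot(bb, bb))
        if den == 0.0:
            raise DegenerateInputError("Burg recursion collapsed (degenerate series)")
        k = -2.0 * float(np.dot(ff, bb)) / den
        a = np.concatenate([a, [0.0]])
        a = a + k * a[::-1]
        f, b = ff + k * bb, bb + k * ff
        e *= max(1.0 - k * k, np.finfo(float).tiny)
    return a, e


def _aic_order(x: np.ndarray, orders: Sequence[int]) -> int:
    n = x.size
    best, best_aic = orders[0], np.inf
    for p in orders:
        _, e = burg_ar(x, p)
        aic = n * np.log(e) + 2.0 * p
        if aic < best_aic:
            best, best_aic = p, aic
    return best


def _pole_components(a: np.ndarray, sigma2: float) -> list[tuple[float, float]]:
    """Split the AR PSD into per-pole-pair components by residues.

    The PSD in the z-domain is ``S(z) = sigma2 / (A(z) A(1/z))``; the process
    variance is the sum over poles inside the unit circle of the residues of
    ``S(z)/z``.  A conjugate pole pair contributes twice the real part of one
    residue; that contribution is the component's absolute power and the pole
    angle its center frequency (cycles/beat).
    """
    p = a.size - 1
    poly = a  # coefficients of P(z) = z^p A(z), highest degree first
    poles = np.roots(poly)
    dpoly = np.polyder(poly)
    # Q(z) = A(1/z) has coefficients a reversed (ascending in z)
    out: list[tuple[float, float]] = []
    seen = np.zeros(poles.size, dtype=bool)
    for i, pk in enumerate(poles):
        if seen[i]:
            continue
        seen[i] = True
        q = np.polyval(poly[::-1], pk)  # A(1/pk) since coeffs reversed
        dp = np.polyval(dpoly, pk)
        res = sigma2 * pk ** (p - 1) / (dp * q)
        if abs(pk.imag) > 1e-10:
            # find and mark the conjugate partner
            j = int(np.argmin(np.abs(poles - np.conj(pk)) + seen * 1e9))
            seen[j] = True
            power = 2.0 * res.real
            freq = abs(np.angle(pk)) / (2.0 * np.pi)
        else:
            power = res.real
            freq = 0.0 if pk.real >= 0 else 0.5
        out.append((freq, max(power, 0.0)))
    return out


def fit_ar_spectrum(
    series: BeatSeries,
    order: int | str = 12,
    mean_interval_s: float | None = None,
) -> SpectrumDecomposition:
    """Fit an AR model and decompose its spectrum into components.

    Parameters
    ----------
    series:
        Beat series of at least 64 beats with nonzero variance.
    order:
        AR model order, or ``"auto"`` for AIC selection over orders 8-20.
    mean_interval_s:
        Mean beat interval in seconds, used to convert cycles/beat to Hz.
        Defaults to the series' own mean / 1000 for RR series; systogram
        spectra must receive the companion tachogram's mean interval.
    """
    x = series.values
    if x.size < MIN_BEATS:
        raise SeriesTooShortError(
            f"series has {x.size} beats; at least {MIN_BEATS} are required"
        )
    if mean_interval_s is None:
        if series.kind == "RR":
            mean_interval_s = float(np.mean(x)) / 1000.0
        else:
            raise ValueError(
                "SAP series need mean_interval_s from the companion RR series "
                "for the beat->Hz frequency conversion"
            )
    xc = x - np.mean(x)
    if np.allclose(xc, 0.0):
        raise DegenerateInputError("constant series: spectral decomposition undefined")
    if order == "auto":
        order = _aic_order(xc, range(8, 21))
    order = int(order)
    a, sigma2 = burg_ar(xc, order)
    raw = _pole_components(a, sigma2)
    total = sum(p for _, p in raw)
    if total <= 0:
        raise DegenerateInputError("AR spectrum has no positive power")
    comps = tuple(
        SpectralComponent(
            center_freq=f / mean_interval_s,
            power=p,
            power_fraction=p / total,
        )
        for f, p in sorted(raw)
    )
    dec = SpectrumDecomposition(
        components=comps,
        total_power=total,
        ar_order=order,
        mean_interval_s=mean_interval_s,
    )
    return dec.classified()


def classify_band(
    component: SpectralComponent, decomposition: SpectrumDecomposition
) -> SpectralComponent:
    """Assign a component to a band: noise, VLF, LF, HF or unclassified.

    Components below 5% of total power are noise regardless of frequency;
    the remaining ones are banded by center frequency in Hz.
    """
    f = component.center_freq
    if component.power_fraction < NOISE_FRACTION:
        band = "noise"
    elif f < LF_BAND[0]:
        band = "VLF"
    elif f <= LF_BAND[1]:
        band = "LF"
    elif HF_BAND[0] <= f <= HF_BAND[1]:
        band = "HF"
    else:
        band = "unclassified"
    return replace(component, band=band)


def band_powers(decomposition: SpectrumDecomposition) -> dict:
    """Band summaries: absolute powers, power-weighted center frequencies, TP.

    Empty bands yield power 0.0 and center frequency ``nan`` (flagged
    undefined).  VLF power is returned as well because the normalized-unit
    denominator needs it.
    """
    out = {"TP": decomposition.total_power}
    for band, pk, fk in (("LF", "LFa", "LFHz"), ("HF", "HFa", "HFHz")):
        members = [c for c in decomposition.components if c.band == band]
        power = sum(c.power for c in members)
        out[pk] = power
        out[fk] = (
            sum(c.power * c.center_freq for c in members) / power
            if power > 0
            else float("nan")
        )
    out["VLFa"] = sum(c.power for c in decomposition.components if c.band == "VLF")
    return out


def normalized_units(powers: dict, vlf_power: float | None = None) -> dict:
    """Normalized LF/HF powers: 100 * band power / (TP - VLF power).

    Noise components stay in the denominator, so LFnu + HFnu <= 100 in
    general.
    """
    vlf = powers.get("VLFa", 0.0) if vlf_power is None else vlf_power
    denom = powers["TP"] - vlf
    if denom <= 0:
        raise DegenerateInputError("total power does not exceed VLF power")
    return {
        "LFnu": 100.0 * powers["LFa"] / denom,
        "HFnu": 100.0 * powers["HFa"] / denom,
    }


def alpha_index(
    rr_decomp: SpectrumDecomposition, sap_decomp: SpectrumDecomposition
) -> float:
    """Frequency-domain baroreflex gain (ms/mmHg).

    Average of the square roots of the RR/SAP spectral power ratios in the
    LF and HF bands.
    """
    rr = band_powers(rr_decomp)
    sap = band_powers(sap_decomp)
    for band in ("LFa", "HFa"):
        if sap[band] <= 0:
            raise DegenerateInputError(
                f"SAP spectrum has zero {band[:-1]} power; alpha index undefined"
            )
        if rr[band] <= 0:
            raise DegenerateInputError(
                f"RR spectrum has zero {band[:-1]} power; alpha index undefined"
            )
    return 0.5 * (
        np.sqrt(rr["LFa"] / sap["LFa"]) + np.sqrt(rr["HFa"] / sap["HFa"])
    )


@dataclass
class ProxyRecord:
    """The 16 autonomic proxies for one subject, plus covariates.

    Units: HR beat/min; RR_Mean ms; powers ms^2 (RR) or mmHg^2 (SAP);
    nu values in [0, 100]; frequencies Hz; alpha ms/mmHg; pressures mmHg.
    ``dRRLFnu`` is the stand-minus-rest change in RR LFnu and is ``nan``
    when no standing series is available (missing, never silently zero).
    """

    HR: float
    RR_Mean: float
    RR_TP: float
    RR_LFa: float
    RR_HFa: float
    RR_LFnu: float
    RR_HFnu: float
    RR_LF_HF: float
    RR_LFHz: float
    RR_HFHz: float
    dRRLFnu: float
    alpha: float
    SAP: float
    DAP: float
    SAP_Mean: float
    SAP_LFa: float
    age: float = float("nan")
    gender: str = ""
    group: str = ""
    subject_id: str = ""

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in PROXY_COLUMNS + ["age", "gender", "group", "subject_id"]}


def compute_proxies(
    rr_rest: BeatSeries,
    sap_rest: BeatSeries,
    rr_stand: BeatSeries | None = None,
    *,
    cuff_sap: float,
    cuff_dap: float,
    age: float = float("nan"),
    gender: str = "",
    group: str = "",
    order: int | str = 12,
) -> ProxyRecord:
    """Compute all 16 autonomic proxies for one subject.

    The tachogram and systogram at rest drive the spectral proxies and the
    baroreflex alpha index; the standing tachogram, when present, provides
    the orthostatic change in normalized LF power.  Cuff pressures enter
    directly as SAP/DAP.
    """
    rr_mean = float(np.mean(rr_rest.values))
    rr_dec = fit_ar_spectrum(rr_rest, order=order)
    sap_dec = fit_ar_spectrum(sap_rest, order=order, mean_interval_s=rr_mean / 1000.0)
    rr_bp = band_powers(rr_dec)
    sap_bp = band_powers(sap_dec)
    nu = normalized_units(rr_bp)
    if rr_bp["HFa"] <= 0:
        warnings.warn(
            "HF band carries <5% of RR power; respiratory confirmation of the "
            "HF component is not possible on this recording",
            stacklevel=2,
        )
        lf_hf = float("nan")
    else:
        lf_hf = rr_bp["LFa"] / rr_bp["HFa"]
    if rr_stand is not None:
        stand_dec = fit_ar_spectrum(rr_stand, order=order)
        stand_nu = normalized_units(band_powers(stand_dec))
        d_lfnu = stand_nu["LFnu"] - nu["LFnu"]
    else:
        d_lfnu = float("nan")
    return ProxyRecord(
        HR=60000.0 / rr_mean,
        RR_Mean=rr_mean,
        RR_TP=rr_bp["TP"],
        RR_LFa=rr_bp["LFa"],
        RR_HFa=rr_bp["HFa"],
        RR_LFnu=nu["LFnu"],
        RR_HFnu=nu["HFnu"],
        RR_LF_HF=lf_hf,
        RR_LFHz=rr_bp["LFHz"],
        RR_HFHz=rr_bp["HFHz"],
        dRRLFnu=d_lfnu,
        alpha=alpha_index(rr_dec, sap_dec),
        SAP=cuff_sap,
        DAP=cuff_dap,
        SAP_Mean=float(np.mean(sap_rest.values)),
        SAP_LFa=sap_bp["LFa"],
        age=age,
        gender=gender,
        group=group,
        subject_id=rr_rest.subject_id,
    )
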