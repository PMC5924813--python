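"""Seeded synthetic cohorts and beat series with planted autonomic structure.

No individual-level cardiovascular variability cohort is shipped with the
package, so every pipeline stage is exercised on synthetic data whose
statistical structure matches what the method assumes:

* a 4-factor latent structure ties the 16 proxies into oscillatory,
  amplitude, pressure and pulse blocks (default loading pattern below);
* clinical groups differ from the reference ("Normal") group through mean
  shifts of the latent factors, calibrated in sign and rough magnitude to
  published ambulatory descriptive statistics (per-group means/SDs of the
  proxies);
* group composition is skewed in age and gender the way real screening
  cohorts are: athletes young and mostly male, obese cohorts mostly
  female, hypertensives older;
* positive, strongly right-skewed proxies (spectral powers, the LF/HF
  ratio, baroreflex gain) are generated log-normally — their SDs rival or
  exceed their means in real cohorts, which is exactly why the pipeline is
  non-parametric.

The beat-series generator plants sinusoidal LF/HF oscillations in a
systogram and transfers them into the tachogram with a known baroreflex
gain, giving closed-form targets for the spectral estimators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .beat_spectral import PROXY_COLUMNS, BeatSeries

__all__ = [
    "CohortConfig",
    "SeriesConfig",
    "DEFAULT_GROUP_SIZES",
    "DEFAULT_LOADINGS",
    "PROXY_CALIBRATION",
    "LOG_SCALE_PROXIES",
    "domain_shift_targets",
    "generate_cohort",
    "generate_beat_series",
]

#: Default group sizes of the emulated ambulatory cohort (total 1352).
DEFAULT_GROUP_SIZES = {
    "Athlete": 149,
    "Normal": 547,
    "Obese": 102,
    "Stress": 190,
    "Hypertensive": 271,
    "HT-Obese": 55,
    "HT-Stress": 38,
}

GROUPS = list(DEFAULT_GROUP_SIZES)

#: Default proxy x factor loading pattern (oscillatory, amplitude,
#: pressure, pulse), on the correlation scale.
DEFAULT_LOADINGS = pd.DataFrame(
    {
        "RR_HFnu":  ( .92,  .10, -.12, -.14),
        "dRRLFnu":  ( .65,  .12, -.22, -.08),
        "RR_LF_HF": (-.57, -.02,  .06,  .11),
        "RR_LFnu":  (-.96, -.07,  .08,  .11),
        "RR_TP":    ( .15,  .96, -.11, -.17),
        "RR_HFa":   ( .40,  .77, -.11, -.09),
        "RR_LFa":   (-.21,  .74, -.11, -.15),
        "alpha":    ( .17,  .63, -.27, -.25),
        "SAP":      (-.12, -.12,  .96,  .03),
        "SAP_Mean": (-.11, -.13,  .91,  .03),
        "DAP":      (-.19, -.14,  .82,  .08),
        "HR":       (-.15, -.20,  .09,  .96),
        "RR_HFHz":  (-.14, -.09, -.03,  .29),
        "RR_Mean":  ( .13,  .19, -.07, -.94),
        "RR_LFHz":  ( .12,  .06, -.08,  .17),
        "SAP_LFa":  (-.14,  .05,  .12,  .03),
    },
    index=["Oscillatory", "Amplitude", "Pressure", "Pulse"],
).T

#: Per-group descriptive calibration: proxy -> group -> (mean, SD), on the
#: natural scale of each proxy.  Used to place the reference distribution
#: and to derive the latent-domain shifts of every test group.
PROXY_CALIBRATION = {
    "HR":       {"Athlete": (55.54, 11.22), "Normal": (67.02, 10.39), "Obese": (73.85, 11.05), "Stress": (61.27, 12.40), "Hypertensive": (71.83, 11.39), "HT-Obese": (73.82, 10.66), "HT-Stress": (66.39, 12.01)},
    "RR_Mean":  {"Athlete": (1124.00, 227.53), "Normal": (917.62, 148.68), "Obese": (831.11, 128.45), "Stress": (1019.18, 206.29), "Hypertensive": (855.47, 131.71), "HT-Obese": (828.11, 110.57), "HT-Stress": (934.15, 176.69)},
    "RR_TP":    {"Athlete": (6086.07, 6843.65), "Normal": (3184.62, 3414.38), "Obese": (1643.55, 1689.91), "Stress": (2616.41, 2388.96), "Hypertensive": (1507.40, 1412.89), "HT-Obese": (1068.84, 1189.08), "HT-Stress": (1718.37, 1266.80)},
    "RR_LFa":   {"Athlete": (1180.54, 1186.36), "Normal": (1022.47, 1491.71), "Obese": (501.45, 608.27), "Stress": (804.60, 1006.64), "Hypertensive": (460.29, 530.03), "HT-Obese": (355.92, 421.25), "HT-Stress": (556.36, 815.79)},
    "RR_HFa":   {"Athlete": (2672.21, 3800.57), "Normal": (998.40, 1672.46), "Obese": (378.76, 511.09), "Stress": (664.46, 999.15), "Hypertensive": (294.30, 594.16), "HT-Obese": (222.18, 357.88), "HT-Stress": (231.21, 280.84)},
    "RR_LFnu":  {"Athlete": (34.98, 17.92), "Normal": (51.16, 20.33), "Obese": (53.92, 21.94), "Stress": (54.47, 22.19), "Hypertensive": (58.59, 20.49), "HT-Obese": (54.69, 22.95), "HT-Stress": (61.28, 20.95)},
    "RR_HFnu":  {"Athlete": (59.53, 19.08), "Normal": (41.61, 20.23), "Obese": (37.51, 21.36), "Stress": (37.74, 21.61), "Hypertensive": (31.75, 18.73), "HT-Obese": (36.57, 20.91), "HT-Stress": (29.66, 18.92)},
    "RR_LF_HF": {"Athlete": (0.82, 0.91), "Normal": (2.28, 3.24), "Obese": (4.29, 9.87), "Stress": (3.34, 4.97), "Hypertensive": (3.99, 5.82), "HT-Obese": (3.18, 4.59), "HT-Stress": (5.98, 12.33)},
    "RR_LFHz":  {"Athlete": (0.10, 0.02), "Normal": (0.10, 0.02), "Obese": (0.09, 0.03), "Stress": (0.09, 0.02), "Hypertensive": (0.10, 0.03), "HT-Obese": (0.09, 0.03), "HT-Stress": (0.09, 0.02)},
    "RR_HFHz":  {"Athlete": (0.27, 0.06), "Normal": (0.27, 0.06), "Obese": (0.30, 0.07), "Stress": (0.25, 0.06), "Hypertensive": (0.28, 0.06), "HT-Obese": (0.30, 0.08), "HT-Stress": (0.23, 0.06)},
    "dRRLFnu":  {"Athlete": (47.57, 20.92), "Normal": (27.44, 20.54), "Obese": (14.45, 23.40), "Stress": (23.05, 21.90), "Hypertensive": (15.44, 20.21), "HT-Obese": (7.95, 23.12), "HT-Stress": (15.85, 17.76)},
    "alpha":    {"Athlete": (34.78, 22.62), "Normal": (24.67, 16.25), "Obese": (12.99, 9.24), "Stress": (20.41, 14.81), "Hypertensive": (11.45, 8.31), "HT-Obese": (8.11, 4.06), "HT-Stress": (15.45, 14.72)},
    "SAP":      {"Athlete": (112.53, 15.36), "Normal": (113.55, 11.86), "Obese": (119.49, 9.88), "Stress": (117.26, 12.63), "Hypertensive": (147.75, 16.67), "HT-Obese": (149.47, 15.01), "HT-Stress": (140.00, 11.45)},
    "DAP":      {"Athlete": (68.63, 7.62), "Normal": (70.87, 7.71), "Obese": (75.11, 6.80), "Stress": (74.26, 8.46), "Hypertensive": (93.50, 9.62), "HT-Obese": (93.76, 11.61), "HT-Stress": (91.66, 5.71)},
    "SAP_Mean": {"Athlete": (108.62, 12.91), "Normal": (114.38, 12.49), "Obese": (120.30, 12.06), "Stress": (119.17, 13.69), "Hypertensive": (150.95, 19.91), "HT-Obese": (144.06, 12.26), "HT-Stress": (140.34, 14.41)},
    "SAP_LFa":  {"Athlete": (4.28, 4.46), "Normal": (4.12, 5.79), "Obese": (4.96, 6.75), "Stress": (4.82, 6.30), "Hypertensive": (5.70, 8.50), "HT-Obese": (6.61, 8.25), "HT-Stress": (6.23, 8.91)},
}

#: Positive, right-skewed proxies generated on the log scale.
LOG_SCALE_PROXIES = frozenset({"RR_TP", "RR_LFa", "RR_HFa", "SAP_LFa", "RR_LF_HF", "alpha"})

#: Per-group gender mix (fraction male) and triangular age distribution
#: (low, mode, high) in years, emulating typical screening-cohort skews.
GROUP_MALE_FRACTION = {
    "Athlete": 0.711, "Normal": 0.45, "Obese": 0.244, "Stress": 0.35,
    "Hypertensive": 0.55, "HT-Obese": 0.40, "HT-Stress": 0.50,
}
GROUP_AGE_TRIANGLE = {
    "Athlete": (18, 22, 36), "Normal": (18, 35, 72), "Obese": (20, 45, 70),
    "Stress": (20, 40, 68), "Hypertensive": (22, 52, 75),
    "HT-Obese": (25, 52, 75), "HT-Stress": (25, 50, 72),
}

#: Additive age-class effect (z units per class step away from 'middle';
#: spectral powers and vagal indices decline with age, pressures rise) and
#: gender effect (z units, male minus female) per proxy.
AGE_EFFECT = {
    "RR_TP": -0.35, "RR_LFa": -0.30, "RR_HFa": -0.40, "alpha": -0.35,
    "RR_HFnu": -0.20, "RR_LFnu": 0.20, "dRRLFnu": -0.20, "RR_LF_HF": 0.20,
    "SAP": 0.35, "DAP": 0.30, "SAP_Mean": 0.35, "SAP_LFa": 0.10,
}
GENDER_EFFECT = {
    "RR_LFnu": 0.15, "RR_HFnu": -0.15, "RR_LF_HF": 0.15,
    "SAP": 0.20, "DAP": 0.20, "SAP_Mean": 0.20, "RR_TP": 0.10, "RR_Mean": 0.10,
}


def _log_params(mean: float, sd: float) -> tuple[float, float]:
    """Log-normal (mu, sigma) matching a natural-scale mean and SD."""
    sigma2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - 0.5 * sigma2, np.sqrt(sigma2)


def _reference_scale(proxy: str) -> tuple[float, float]:
    """(location, scale) of the reference group on the generating scale."""
    m, s = PROXY_CALIBRATION[proxy]["Normal"]
    if proxy in LOG_SCALE_PROXIES:
        return _log_params(m, s)
    return m, s


def domain_shift_targets() -> pd.DataFrame:
    """Per-group latent-domain mean shifts implied by the calibration.

    Each group's 16 proxy shifts (in reference-scale z units) are projected
    onto the loading pattern by least squares, giving one shift per latent
    domain; the planted group differences then live exactly in the latent
    space the factor analysis is asked to recover.
    """
    proxies = list(DEFAULT_LOADINGS.index)
    lam = DEFAULT_LOADINGS.to_numpy()
    shifts = {}
    for group in GROUPS:
        t = np.zeros(len(proxies))
        for i, proxy in enumerate(proxies):
            mu_n, sig_n = _reference_scale(proxy)
            m, s = PROXY_CALIBRATION[proxy][group]
            if proxy in LOG_SCALE_PROXIES:
                mu_g, _ = _log_params(m, s)
                t[i] = (mu_g - mu_n) / sig_n
            else:
                t[i] = (m - mu_n) / sig_n
        d, *_ = np.linalg.lstsq(lam, t, rcond=None)
        shifts[group] = d
    return pd.DataFrame(shifts, index=DEFAULT_LOADINGS.columns).T


@dataclass
class CohortConfig:
    """Configuration of the synthetic cohort generator."""

    group_sizes: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    loadings: pd.DataFrame = field(default_factory=lambda: DEFAULT_LOADINGS.copy())
    domain_shifts: pd.DataFrame | None = None  # group x domain; default from calibration
    male_fraction: dict = field(default_factory=lambda: dict(GROUP_MALE_FRACTION))
    age_triangle: dict = field(default_factory=lambda: dict(GROUP_AGE_TRIANGLE))
    age_effect: dict = field(default_factory=lambda: dict(AGE_EFFECT))
    gender_effect: dict = field(default_factory=lambda: dict(GENDER_EFFECT))
    noise_scale: float = 1.0  # multiplier on the uniqueness SDs
    seed: int | None = None

    def __post_init__(self):
        if any(n <= 0 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be positive")
        if np.any(np.abs(self.loadings.to_numpy()) > 1):
            raise ValueError("loadings must lie in [-1, 1]")
        for g, frac in self.male_fraction.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"male fraction for {g} outside [0, 1]")
        if self.domain_shifts is None:
            full = domain_shift_targets()
            self.domain_shifts = full.loc[[g for g in self.group_sizes if g in full.index]]


@dataclass
class SeriesConfig:
    """Configuration of the synthetic tachogram/systogram generator."""

    n_beats: int = 300
    mean_rr_ms: float = 1000.0
    mean_sap_mmhg: float = 120.0
    lf_freq: float = 0.10          # cycles/beat
    hf_freq: float = 0.25          # cycles/beat
    sap_lf_amp: float = 3.0        # mmHg
    sap_hf_amp: float = 2.5        # mmHg
    baroreflex_gain: float = 10.0  # ms/mmHg
    rr_noise_sd: float = 5.0       # ms
    sap_noise_sd: float = 0.5      # mmHg
    seed: int | None = None

    def __post_init__(self):
        for f in (self.lf_freq, self.hf_freq):
            if not 0.0 < f < 0.5:
                raise ValueError("oscillation frequencies must lie in (0, 0.5) cycles/beat")
        if min(self.sap_lf_amp, self.sap_hf_amp, self.baroreflex_gain) < 0:
            raise ValueError("amplitudes and gain must be nonnegative")


def generate_cohort(config: CohortConfig | None = None,
                    seed: int | None = None) -> pd.DataFrame:
    """Generate a synthetic proxy cohort table.

    Each subject's proxies follow ``group latent shift + age effect +
    gender effect + Lambda f + unique noise`` on a standardized scale with
    independent standard-normal latent factors ``f`` (centred on the
    group's domain shifts), then map to each proxy's natural scale —
    log-normally for the positive right-skewed proxies.  Group counts and
    composition match the configuration exactly and the same seed always
    reproduces the same table.
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    lam = config.loadings.to_numpy()
    n_dom = lam.shape[1]
    uniq_sd = np.sqrt(np.clip(1.0 - (lam ** 2).sum(axis=1), 0.0, None)) * config.noise_scale
    proxies = list(config.loadings.index)
    rows = []
    for group, n in config.group_sizes.items():
        d = (config.domain_shifts.loc[group].to_numpy()
             if group in config.domain_shifts.index else np.zeros(n_dom))
        f = rng.standard_normal((n, n_dom)) + d
        eps = rng.standard_normal((n, len(proxies))) * uniq_sd
        z = f @ lam.T + eps
        male = rng.random(n) < config.male_fraction.get(group, 0.5)
        lo, mode, hi = config.age_triangle.get(group, (18, 40, 75))
        ages = rng.triangular(lo, mode, hi, size=n)
        # same class convention as the default adjustment bins
        age_step = np.where(ages < 35, -1, np.where(ages < 51, 0, 1))
        for j, proxy in enumerate(proxies):
            z[:, j] += config.age_effect.get(proxy, 0.0) * age_step
            z[:, j] += config.gender_effect.get(proxy, 0.0) * np.where(male, 0.5, -0.5)
        data = {}
        for j, proxy in enumerate(proxies):
            mu, sig = _reference_scale(proxy)
            x = mu + sig * z[:, j]
            if proxy in LOG_SCALE_PROXIES:
                x = np.exp(x)
            elif proxy in ("RR_LFnu", "RR_HFnu"):
                x = np.clip(x, 0.1, 99.9)
            elif proxy in ("RR_LFHz", "RR_HFHz"):
                x = np.clip(x, 0.01, 0.5)
            data[proxy] = x
        df = pd.DataFrame(data)
        df["age"] = np.round(ages, 1)
        df["gender"] = np.where(male, "M", "F")
        df["group"] = group
        rows.append(df)
    out = pd.concat(rows, ignore_index=True)
    out.insert(0, "subject_id", [f"S{i:05d}" for i in range(len(out))])
    return out


def generate_beat_series(config: SeriesConfig | None = None,
                         seed: int | None = None) -> tuple[BeatSeries, BeatSeries]:
    """Generate a coupled (tachogram, systogram) pair.

    The systogram carries planted LF and HF sinusoids plus white noise; the
    tachogram receives the oscillatory part scaled by the baroreflex gain
    (ms/mmHg) plus independent noise, so the spectral gain estimator has a
    known target.
    """
    config = config or SeriesConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = np.arange(config.n_beats)
    osc = (config.sap_lf_amp * np.sin(2 * np.pi * config.lf_freq * n)
           + config.sap_hf_amp * np.sin(2 * np.pi * config.hf_freq * n + 0.7))
    sap = config.mean_sap_mmhg + osc + rng.normal(0.0, config.sap_noise_sd, config.n_beats)
    rr = (config.mean_rr_ms + config.baroreflex_gain * osc
          + rng.normal(0.0, config.rr_noise_sd, config.n_beats))
    return (
        BeatSeries(rr, kind="RR", condition="rest"),
        BeatSeries(sap, kind="SAP", condition="rest"),
    )
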