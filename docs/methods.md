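# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `ansmap`.

## Spectral proxies (`beat_spectral`)

**Model.** A beat series (RR intervals in ms, or beat-by-beat systolic
pressure in mmHg) is treated as a realisation of a stationary AR(p)
process after mean removal.  The AR coefficients are estimated by Burg's
method, which minimises forward+backward prediction error and is the
standard choice for short (~300-beat) HRV segments because it never
produces an unstable model and resolves closely spaced oscillations
better than Yule–Walker at these lengths.  No detrending beyond mean
removal is applied: the series are assumed pre-cleaned and stationary.

**Component decomposition.** The AR power spectral density
σ²/|A(e^{−i2πf})|² is split into components by evaluating the residues of
S(z)/z at the AR poles inside the unit circle.  Each conjugate pole pair
contributes one component whose power is twice the real part of the
residue and whose center frequency is the pole angle; real poles
contribute components at 0 or 0.5 cycles/beat.  Residue contributions sum
exactly to the process variance, so band powers are directly on the
variance scale; tiny negative contributions from nearly cancelling poles
are clamped to zero.

**Parameters.**

| parameter | default | meaning / rationale |
|---|---|---|
| `order` | 12 | AR order; `"auto"` selects by AIC over 8–20.  12 resolves two oscillations plus broadband noise on 300-beat segments without variance splitting. |
| LF band | 0.03–0.14 Hz | conventional low-frequency band of cardiovascular variability |
| HF band | 0.15–0.35 Hz | conventional respiratory band |
| noise cut | 5% of total power | components below it are labelled noise and excluded from bands |
| minimum length | 64 beats | AR(12–20) fits are unreliable below this |

Beat-domain frequencies (cycles/beat) are converted to Hz by dividing by
the mean beat interval in seconds; systogram spectra receive the companion
tachogram's mean interval, since the systogram is sampled once per beat.

**Normalized units.** LFnu = 100·LFa/(TP − VLF power), likewise HFnu.
Noise-labelled components stay in the denominator, so LFnu + HFnu ≤ 100.
This denominator choice (total minus VLF rather than LF+HF) is required
for nu sums below 100 to be representable.

**Baroreflex gain.** α = ½(√(RR_LFa/SAP_LFa) + √(RR_HFa/SAP_HFa)) in
ms/mmHg; both bands must carry nonzero power in both spectra, otherwise a
degenerate-input error is raised.  No respiration channel is modelled; the
usual respiratory-coherence confirmation of the HF component is replaced
by a warning when the RR spectrum has no HF component above the noise cut.

## Age/gender adjustment (`cohort_adjust`)

Each proxy is residualised on a saturated two-way ANOVA with categorical
age class, gender, and their interaction.  For a saturated model the
fitted value in every cell is the cell mean, so residuals are computed as
cell-mean deviations — identical to OLS residuals of the full interaction
model regardless of the sum-of-squares convention (verified against
statsmodels in the tests).  Default age classes are 18–34 / 35–50 / 51–75
years: the cohort narratives that motivate the adjustment hinge on the 34-
and 50-year cut points.  Fractional ages between integer bounds belong to
the class below the next lower bound.  Cells with a single subject get
residual 0 and are flagged in the audit output.  Consequences: adjusted
proxies have exactly zero mean in every cell, the adjustment is
idempotent, and equivariant under affine rescaling.

## Permutation tests (`nonparam_tests`)

**Density-equality (BA) test.**  Both samples are density-estimated with
a Gaussian kernel and a *common* bandwidth — the geometric mean of the two
normal-optimal bandwidths h = sd·(4/(3n))^{1/5}.  The statistic is the
integrated squared difference ∫(f̂₁ − f̂₂)² on a 200-point grid spanning
the pooled range ± 3 bandwidths.  The null distribution comes from
randomly permuting group labels over the pooled sample (default 1000
permutations, minimum 200), with the add-one correction
(1 + #{T* ≥ T})/(1 + n_perm) so p-values are never zero.  The statistic is
evaluated as a quadratic form w'Mw in the kernel Gram matrix, which makes
the permutation loop a single matrix contraction.  The *reference band for
equality* is the pooled density ± one standard error of the density
difference under equality, SE(x) = √(f̂_pool(x)·R(K)·(1/n₁+1/n₂)/h) with
R(K) = 1/(2√π); curves lying inside the band are consistent with a common
density at that point.  (The band is drawn on the density scale; the
classical construction bands √f̂ — the visual message is the same.)
Measured empirical size at α = 0.05: 0.045 over 500 null replicates.

**Trend (JT) test.**  With two groups ordered (reference, test) the JT
statistic is the Mann–Whitney count of (ref, test) pairs with the test
value larger, ties counting ½.  *Increasing* alternative = test group
concentrated on smaller values (left tail), *decreasing* = larger values
(right tail) — the direction semantics of the significance arrows depend
on this convention, so it is fixed and documented here.  P-values come
from complete enumeration of group assignments when the pooled sample has
≤ 12 observations (exact, no correction) and from seeded random
permutations with the add-one correction otherwise.

**Joint rule.**  A proxy is discriminant iff the BA p-value and the
smaller one-sided JT p-value are both below α = 0.05.  Direction follows
the significant JT side; the shade grades max(BA p, min JT p) at
0.001/0.01/0.05.  Because each one-sided JT test runs at 0.05, the JT
"significant either way" event has a ~10% null rate; the joint BA∧JT rate
stays well below 0.05 (the 0.05² = 0.0025 figure assumes independence and
a 0.05-level JT event, so it is a nominal, not an exact, level).  No
multiple-testing correction is applied across proxies or groups — the
joint rule is the protection; an optional Bonferroni flag is deliberately
absent from the default path.

## Latent domains (`factor_domains`)

Pearson correlations of the (by default unadjusted) proxies are factored
by iterated principal-axis extraction: squared multiple correlations start
the communalities, the reduced matrix is eigendecomposed, and
communalities are re-estimated until the largest change is below 1e-6
(max 100 iterations); communalities above 1 (Heywood cases) are clamped
with a warning.  Varimax rotation uses Kaiser row normalization and the
SVD-based iteration; per-proxy communalities are preserved to 1e-10,
column signs are fixed so each factor's dominant loading is positive, and
columns are ordered by explained communality.  Factors are retained while
each explains ≥ 10% of total communality (leading run); each proxy joins
its maximal-|loading| retained factor if that loading reaches the
salience threshold 0.5, else it is excluded.  Salience 0.5 is the
conventional cut; any value in roughly (0.40, 0.57) reproduces the
canonical assignment of the reference loading pattern.  Domains whose
memberships equal the canonical sets are named Oscillatory / Amplitude /
Pressure / Pulse, otherwise `Unnamed-k`.

## Grading and rendering (`differentiation_map`)

Majorities are *strict* (> half the member proxies), counted separately
per test (`counting="marginal"`, default): red = all members jointly
significant; dark pink = BA majority and JT majority; light pink = exactly
one of the two majorities; white otherwise.  The alternative reading that
counts jointly significant proxies only (`counting="joint"`) is available
behind a flag.  For the two-proxy Pulse domain a strict majority means
both proxies, so the dark-pink tier is nearly degenerate there.  Excluded
proxies never influence a grade.  Maps and significance diagrams are
written as hand-generated SVG (byte-identical for identical input) or as
PNG via matplotlib.

## Synthetic cohort (`synthetic_cohort`)

The generator emulates an ambulatory screening cohort of 1,352 subjects in
seven groups (Athlete 149, Normal 547, Obese 102, Stress 190, Hypertensive
271, HT-Obese 55, HT-Stress 38).  On a standardized scale each proxy is
`Λf + unique noise`, with Λ the canonical 4-factor loading pattern and
f ~ N(d_g, I): the group shift d_g is obtained by projecting the group's
published-calibration z-shifts onto Λ by least squares, so group
differences live exactly in the latent space the factor analysis must
recover.  Additive age-class and gender effects (powers and vagal indices
decline with age, pressures rise; modest gender effects) and per-group
age/gender compositions (athletes young and 71% male, obese cohorts 76%
female, hypertensives ~half over 50) reproduce the confounding the
adjustment step exists to remove.  Positive right-skewed proxies (RR TP,
RR LFa, RR HFa, SAP LFa, and also the LF/HF ratio and α, whose SDs rival
their means) are mapped through a log-normal transform; nu variables are
clipped to [0.1, 99.9].

What the generator does *not* emulate: the deterministic identities
HR = 60000/RR_Mean and LF/HF = LFa/HFa (each proxy is generated from the
latent model independently — the proxies computed from beat series by
`compute_proxies` do satisfy them), respiratory dynamics, ectopy or
artifacts, or heavy distribution tails beyond log-normal.  Passing
pipeline tests on synthetic cohorts therefore demonstrate statistical
recovery of planted structure, not clinical validity on real recordings.

A nonlinearity consequence worth knowing: the log-normal mapping
attenuates Pearson correlations, so on default synthetic cohorts the
LF/HF-ratio loading on the oscillatory factor lands just below the 0.5
salience cut and that domain is reported as `Unnamed-1` (its other three
members are recovered; factor congruence with the planted structure
exceeds 0.95 per factor).

The beat-series generator plants SAPₙ = mean + A_LF sin(2πf_LF n) +
A_HF sin(2πf_HF n + φ) + noise and RRₙ = mean + g·(SAP oscillation) +
independent noise, so spectral estimators have closed-form targets
(sinusoid power A²/2, gain g).

## Pipeline (`pipeline`, `cli`)

Stages run strictly in order (adjust → test → domains → map), each
consuming the previous stage's artifact; any failure aborts with a
stage-named error.  All randomness flows from one seed; the manifest
records SHA-256 digests of every artifact, and identical configurations
reproduce identical digests (SVG output is deterministic by
construction).  The reference group label is configurable (default
"Normal").

## Problem sizes used in tests and the acceptance script

Null calibrations use 500 replicates (samples of 40–50 per group, 500–1000
permutations); factor recovery uses cohorts of 1,000 subjects; the
planted-shift map experiment uses 50 seeds at 200 subjects per group with
permutation tests at 500 permutations; spectral fixtures use 300-beat
series.

## Known limitations

- The per-domain false-positive rate of the map's *medium* grade is larger
  than the per-test level: a JT result counts as significant when either
  one-sided test rejects (~10% marginal null rate), and proxies within a
  domain are strongly correlated, so null single-test majorities cluster.
  Measured on null cohorts with a shift planted only in the pressure
  proxies, the shifted domain is always detected but some other domain is
  spuriously non-white (almost always light pink) in ~15% of runs, the
  two-proxy Pulse domain being the dominant source.  The joint-counting
  flag does not reduce this.  Interpret light-pink cells accordingly.
- Factor analysis on raw (untransformed) right-skewed proxies attenuates
  loadings; a log transform before correlation would sharpen recovery but
  is deliberately not the default, to keep the analysis on the original
  proxy scale.
- No respiration channel: low-frequency breathing entrainment cannot be
  detected, only a missing-HF warning is emitted.
- Permutation p-values have granularity 1/(n_perm+1); comparisons at
  p ≈ α need n_perm ≥ 1000 to be stable.
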