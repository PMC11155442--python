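# Methods

This note documents the models implemented in `cervelast`: what the
synthetic data emulates, how the measurement chain works, which parameters
matter, and where the design was genuinely open.

## 1. Measurement principle

The device is a vaginal probe combining a tactile pressure array with a
single 5 MHz pulse-echo transducer. As the operator presses the probe
against the external cervical surface, each acquisition frame records the
aggregate applied pressure p (kPa) and one RF A-line. The internal cervical
surface returns the dominant echo; its round-trip time of flight τ converts
to depth d = c·τ/2. With the linear tissue law used throughout,

    L(p) = max(L_min, L0 − p / E),

the (d, p) points over a compression ramp lie on a line of absolute slope E
— the cervical elasticity, a stress-to-strain ratio in kPa/mm where the
"strain" is absolute shortening in millimetres — and the line's
intersection with the p = 0 axis is the cervical length L0.

## 2. Synthetic exam generator (`synthetic`)

**Probe** (defaults, all configurable): centre frequency 5 MHz, sampling
50 MHz (20 ns, one sample = 15.4 µm of depth at c = 1540 m/s), 100
frames/s, pressure range capped at 30 kPa with Gaussian sensor noise of
SD 30 Pa, record depth 60 mm (3896 samples per A-line). The transmit burst
is a Gaussian-windowed cosine with 50% fractional bandwidth (envelope
σ_t ≈ 0.15 µs, comfortably below the stated 1 µs pulse-length limit).

**Per-frame signal**: the surface echo is a Gabor burst at delay 2·L(p)/c
with amplitude `surface_reflectivity × 10^(−α·f·2L/20)` (α = 0.5 dB/cm/MHz,
the standard soft-tissue attenuation). Diffuse scatterers are Poisson-placed
along the cervix in material coordinates (default 1.5/mm, amplitudes
uniform up to 5% of the surface reflectivity, random phases); their
positions rescale with the compression ratio L(p)/L0, so the speckle moves
with the tissue. White Gaussian noise is added at a configurable SNR
relative to the attenuated surface-echo amplitude (default 20 dB; `None`
disables it). Seeded generation is bit-reproducible.

**Pressure program**: linear ramp, default 1 → 21 kPa over 3 s (300
frames), optional hold. The ramp shape and duration are modelling choices —
the acquisition rate and the 30 kPa cap are device constraints, the rest is
not specified by the instrument. `adaptive_protocol` emulates the operator
watching the echo in real time: the peak pressure is chosen so the cervix
compresses to 35% of its rest length (never below the tissue's hard floor),
capped at 21 kPa. Soft cervices therefore receive gentler peaks instead of
a flat, saturated over-compression segment.

**What the generator does not model**: probe-face ringdown, per-sensor
pressure asymmetry across the four tactile sensors (a single aggregate
channel is used, consistent with one stress value per frame), beam
geometry/angle corrections for the 40° sensitive plane, multi-layer tissue,
nonlinear (hyperelastic) stress-strain behaviour, and probe-placement
variability between repeat measurements. Consequences of the last omission
are discussed in §5.

## 3. Echo tracking (`tracking`) and fitting (`stress_strain`)

The envelope is `|s * w|` with the complex Gaussian wavelet
`w(t) = exp(−t²/2σ²)·exp(i2πf₀t)` at f₀ = 5 MHz and 50% fractional
bandwidth, truncated at ±6σ (truncation sidelobes below the Gaussian's own
out-of-band leakage; DC gain ≈ 1.5 × 10⁻⁵). Envelopes are computed in
single precision — a ~10⁻⁷ relative error, far below the 15.4 µm depth
quantum.

Per frame the largest envelope sample beyond a 5 mm blanking depth (probe
near field) is taken, refined by three-point parabolic interpolation, and
converted to depth. Frames after the first valid detection are searched
within ±3 mm of the last valid depth. A frame is flagged invalid — never
fatal — when its windowed peak falls below 30% of the whole-frame envelope
maximum (degraded or dead frames, content confined to the blanked zone).
Degraded frames are flagged, not interpolated; the fit stage decides.

The fit regresses pressure on depth by ordinary least squares over the
valid frames (a least-absolute-deviation variant is available); elasticity
is |slope| and length the depth intercept at p = 0. A fit is trusted only
when ≥ 20 frames contributed, the pressure span is ≥ 5 kPa and R² ≥ 0.8 —
invented, configurable gates protecting against the low-amplitude /
low-compression failure mode of very soft cervices. Only the loading ramp is
fitted; no hysteresis model. A subject's value is the arithmetic mean of
the valid sector fits (anterior = 12 o'clock, posterior = 6 o'clock), with
an explicit flag when only one sector survived. Measured lengths are
reported as extrapolated; no correction for initial contact deformation is
applied.

Accuracy, as established by the test suite: noise-free recovery of E is
exact to < 0.1% (quantisation-limited; the 43 mm → 25 mm at 21 kPa scenario
yields 1.1667 kPa/mm and 43.0 mm); at 20 dB SNR with speckle the median
per-exam relative error is well under 5% across E ∈ [0.3, 4] kPa/mm, and
the median depth-tracking error is below 0.1 mm.

## 4. Cohort model (`cohortgen`) and statistics (`stats`)

The default cohort itemises every published subgroup: 8 sPTB + 119 term +
5 indicated-preterm validation subjects, 34 development-phase subjects, and
5 non-attenders, 7 lost to follow-up, 2 operator-error exclusions.
(The published phase/attrition counts are not mutually consistent as a
single total; the itemised sum is used, and the analysis set is 132 − 5 =
127 either way.) Group distributions:

- **Average elasticity** (kPa/mm): truncated normal, sPTB 0.70 ± 0.26,
  term 1.63 ± 0.65, floor 0.05. Indicated-preterm subjects draw from the
  sPTB distribution (their cervices soften similarly).
- **Sector split**: anterior = A(1 + x), posterior = A(1 − x) with
  x ~ N(offset, 0.20), the offset reproducing the printed anterior/
  posterior mean gap. The average is preserved exactly. The printed
  per-sector SDs are deliberately not matched: no model in which the
  average is the mean of the sectors can give a posterior SD (0.21) below
  the average SD (0.26), so those rows necessarily include single-sector
  measurement/placement variance that the simulator does not model.
- **Average length** (mm): truncated normal, sPTB 34.9 ± 7.7, term
  30.4 ± 6.8, floor 10; same sector-split construction with 8% relative
  heterogeneity. Elasticity and length are drawn independently.
- **Demographics**: normal/Bernoulli models per the published group rows;
  gestational age at exam restricted to 24w0d–28w6d; birth before 259 days
  (37 completed weeks) defines preterm, with sPTB additionally requiring
  spontaneous delivery.

Statistics: two-sample t-tests from summary statistics (pooled-variance
Student t with df = n₁+n₂−2 by default — this flavour reproduces the
published elasticity and weight p-values — Welch optional; no
multiple-testing correction). Empirical AUC by Mann–Whitney pair counting
(higher score = more likely sPTB, i.e. negated elasticity), variance by
DeLong's structural components, Wald CI clipped to [0, 1]. Classification
rule: predicted sPTB iff average elasticity strictly below the 1.0 kPa/mm
cutoff (a tie counts negative); sensitivity/specificity carry exact
Clopper–Pearson intervals.

## 5. What passing tests do and do not show

The synthetic cohort establishes that the *measurement chain* is unbiased
and precise under the stated acquisition physics, and that the *statistical
machinery* is correct (the AUC matches exhaustive pair enumeration; the
DeLong interval covers a known binormal AUC ≈ 95% of the time; the exact
binomial bound for 7/8 is 0.473). It does not validate the clinical claim:
group separations and the resulting AUC are inherited from the configured
group distributions, not discovered. Real recordings add hazards the
generator omits — probe placement variability between sectors and repeats,
ringdown, low-amplitude echoes in very soft cervices, operator-dependent
ramps — so real-data performance must be established clinically.

Known residual effects, quantified on simulations: sectors softer than
about 0.2 kPa/mm cannot reach the 5 kPa quality span within the probe's
pressure budget and drop to the single-sector fallback, which nudges
recovered group means slightly upward (≈ +0.01–0.03 kPa/mm at the default
heterogeneity). Extrapolated lengths inherit any early-contact nonlinearity
in real tissue; the simulator's tissue is linear, so this appears only as a
documented caveat, not in the numbers.

## 6. Numerical and reproducibility choices

Stage seeds derive from the master seed through a fixed counter scheme,
`SeedSequence((master, stage, subject, sector))`, so any exam can be re-run
in isolation and full pipeline reruns are byte-identical. Problem sizes for
the shipped reproduction script — 100,000 draws for the cutoff sensitivity,
200 subjects per group (two sector exams each, 300 frames per exam) for
end-to-end recovery — were chosen to put Monte-Carlo error comfortably
inside the reported tolerances. Degenerate inputs are contracts, not
crashes: zero-compression tracks return invalid fits with reason codes,
perfectly separated ROC data returns a zero-variance flag with clipped CIs,
and zero-variance t-tests are defined only for equal means.
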