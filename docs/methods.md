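# Methods

This note documents the models, estimators, parameter choices and known
limitations of `alphacog`. It complements the README (what the package
does) with *why* each piece is the way it is.

## The target statistic

The individual alpha peak frequency (iAPF) is computed as the center of
gravity (COG) of the whole-head mean power spectral density over the alpha
band [7.5, 13] Hz:

    iAPF = ∫ f·P(f) df / ∫ P(f) df,   f ∈ [7.5, 13] Hz.

The COG form is robust for broad or split alpha peaks, where an argmax
would jump between local maxima. Integrals are trapezoid sums on the Welch
frequency grid; band edges falling on grid points receive half weight,
off-grid edges are linearly interpolated. Two consequences used by the
tests: the COG always lies inside the band (convexity), and it is
invariant to positive rescaling of the spectrum.

A COG is only meaningful when an alpha peak exists. The presence gate
requires the alpha-band peak of the mean PSD to be at least **1.3×** the
neighbor power, defined as the mean of the theta (4–7.5 Hz) and beta
(13–30 Hz) per-band average densities — equal weight *per band*, not per
hertz, because the 17-Hz-wide beta band would otherwise dominate the
3.5-Hz theta band. The comparison is inclusive (≥ 1.3). Subjects failing
the gate in any gate phase (the three analyzed phases plus the closed-eye
baseline) are excluded entirely, so the inferential table has complete
cases only.

## Processing chain and its parameters

Per phase segment, in order:

1. **Bad-channel detection** on the raw segment. A channel is bad when any
   single failure class accumulates more than 30 s of 1-s windows:
   isoelectric (window SD < 0.1 µV), saturated (≥ 50 % of samples within
   1 % of the channel's observed peak-to-peak span from its extremum), or
   artifactual (window RMS with a robust z-score > 5 against the channel's
   own median/MAD across windows). These thresholds are deterministic
   proxies for expert visual inspection; they are configurable
   (`QCThresholds`) and the defaults are fixed for reproducibility. When a
   channel exceeds the threshold in several classes the reported reason
   follows the priority isoelectric > saturated > artifactual, since a
   rail-pinned stretch necessarily also shows extreme amplitudes.
2. **Bandpass** 1–40 Hz Butterworth of overall order 30, realized as a
   cascade of second-order sections and applied forward–backward
   (zero-phase). Phase handling is irrelevant for PSD analysis, and the
   symmetric application avoids group delay; the effective magnitude is
   the squared design response, which the tests check against the designed
   transfer function (−3 dB at the cutoffs per pass, > 60 dB at 100 Hz).
3. **Average reference** over good channels only; the same mean is
   subtracted from bad channels so their interpolation lives in the same
   reference. The operation is idempotent and makes results independent of
   the original physical reference (mastoid for the dry cap, CPz for the
   gel cap).
4. **Spherical-spline interpolation** of bad channels from good ones
   (spline order m = 4, Legendre series truncated at 50 terms, ridge 1e-5
   on the kernel matrix). The mean-value constraint makes constants exact
   regardless of the ridge. Interpolation needs ≥ 10 good channels with
   montage positions, otherwise it is refused and the channel stays
   excluded.
5. **Welch PSD** per channel: the segment is cut into consecutive complete
   30-s intervals; within each interval, 4-s Hann windows with 50 %
   overlap; estimates averaged across windows and intervals, one-sided
   density scaling (integral = variance). The inner parameters give a
   0.25 Hz grid — fine enough that COG discretization bias is far below
   the 0.01 Hz reporting precision — while keeping ≥ 14 averages per
   interval. The phase-level iAPF is the COG of the interval-averaged mean
   PSD (not the mean of per-interval COGs), matching the definition of the
   statistic on the phase's mean spectrum; `process_segment` operates on
   the averaged spectrum throughout.
6. **Whole-head mean PSD** over all 64 channels, interpolated channels
   included (interpolation restores the missing spatial information before
   spectral analysis; excluding interpolated channels would re-weight the
   scalp coverage per subject).

## Synthetic study generator

The generator emulates the five-phase two-cap cycling protocol so the full
chain is verifiable without any recordings. Per channel,

    x_c(t) = w_c · a(t) + b_c(t) + bursts_c(t) + injected failures,

with all components in microvolts at 1024 samples/s.

**Background** `b_c(t)`: independent per channel, spectrally shaped
Gaussian noise with one-sided PSD `S(f) = s·(f/10)^(−β)` (flattened below
1 Hz), defaults β = 1 and s = 2 µV²/Hz at 10 Hz — a realistic resting-EEG
floor that makes the presence gate non-trivial (closed-eye presence ratios
around 4, open-eye around 1.8, alpha-deficient around 1.05).

**Alpha** `a(t)`: band-filtered Gaussian noise with a cos² spectral
envelope of full width 2 Hz. The envelope is symmetric, so the COG of the
alpha component alone equals its center frequency exactly — modeling alpha
as filtered noise rather than a sinusoid keeps the COG a nondegenerate
functional of a continuous spectrum (a pure tone would make it trivially
the tone frequency and mask discretization bugs). The closed-eye
whole-head peak density defaults to 7.8 µV²/Hz with an eyes-open scale of
2.25/7.8 ≈ 0.29, reproducing the grand-average eyes-closed/eyes-open
alpha-power contrast of roughly 3.5.

**Exact ground truth.** The 1/f background is not flat across the alpha
band, so it pulls the band COG below the alpha center. Both the in-band
background power and its COG are analytic, so the generator *solves* for
the alpha center that makes the COG of the total mean spectrum equal the
configured target (`compensated_alpha_center`), including the (n−1)/n
attenuation that average referencing applies to channel-independent signal
parts. Per-recording ground truth is therefore exact, not approximate; if
the required compensation would push the passband outside the alpha band
(very weak alpha), the center is clamped and the realized analytic COG is
recorded instead.

**Topography and coherence.** The spatial pattern `w_c` is a linear
anterior→posterior gradient of the unit-sphere y coordinate, demeaned
across channels (dipolar-like, so average referencing leaves the shared
alpha intact) and normalized to unit mean square (so the whole-head mean
alpha PSD equals the configured peak density). The rhythm is partially
coherent across channels: half the alpha power is one shared realization,
half is independent per channel (coherence 0.5). Real alpha is regionally
rather than globally coherent; a fully coherent rhythm would also make the
whole-head average useless as an averaging device.

**Failures and artifacts.** Injected per channel at phase- and
cap-dependent Bernoulli rates chosen to mirror the reported reliability
percentages (dry 80/66/91 % in Phases I/III/V, gel 95/85/82 %, with the
unreported Phases II/IV interpolated). Classes match the QC definitions:
isoelectric (constant), saturated (pinned at the ±400 µV rail with < 1 %
ripple for 31–54 s), artifactual (8× RMS broadband for 31–54 s). Movement
bursts are Poisson-timed 0.5–3 s windows of 5× broadband noise per
channel, rare at rest (0.3–0.6/min) and frequent during cycling (4–8/min)
— individually too short to flag a channel, matching their nuisance role.

**Study design.** Defaults: 17 subjects × 2 caps; phase means 10.22 /
10.36 / 10.41 Hz (dry) and 10.23 / 10.37 / 10.43 Hz (gel) for Phases
II/IV/V (baseline uses the Phase II value, the cycling phase the Phase IV
value); per-subject iAPF offsets drawn N(0, 0.26 Hz) and shared across
phases and caps; 4 subjects made alpha-deficient (peak-density scale 0.05)
in one random analyzed phase, so 13 enter the ANOVA. The offsets are
centered within the analyzed cohort (and separately within the deficient
cohort), making the analyzed-cohort mean of the true iAPF equal the
configured value *exactly*: parameter-recovery checks then measure
pipeline error, not cohort sampling error (a 13-subject mean of N(0, 0.26)
offsets would wander by ±0.07 Hz on its own, swamping a ±0.05 Hz check).
Phase durations follow the protocol (4 min baseline split open/closed,
2 min each for pre-cycling and the two recoveries); the cycling phase,
6–28 min in the field, defaults to 2 min here since it never enters iAPF
statistics. All randomness derives from one root seed through fixed
per-subject/cap/phase key tuples, so studies are bit-reproducible and
partially regenerable.

**What the generator does not emulate** — and hence what passing tests do
*not* establish about real data: biophysical forward modeling (volume
conduction, electrode bridges), non-stationary alpha (within-phase drift,
amplitude waxing/waning), ocular/cardiac/myogenic artifacts with realistic
morphology, sweat-induced impedance drift coupling into the signal, and
any systematic dry-vs-gel signal-quality difference beyond channel-failure
rates. Recovery results certify the estimator chain, not the physiology.

## Inferential statistics

The 2 (cap) × 3 (phase) within-subject ANOVA is computed from explicit
cell-mean sums of squares; each effect is tested against its
subject-by-effect interaction stratum. Sphericity of the phase and
interaction strata (k = 3) is assessed with Mauchly's W on the sample
covariance of orthonormal (normalized Helmert) contrast scores — for the
phase effect the contrasts apply to cap-averaged values, for the
interaction to cap differences scaled by 1/√2. Greenhouse–Geisser
ε = (tr S)² / (p·tr S²) shrinks both dfs **only when Mauchly rejects at
p < 0.05**; the two-level cap factor is spherical by construction (ε ≡ 1).
Partial η² = SS_effect/(SS_effect+SS_error). Observed power uses the
noncentral F with λ = F·df_num at α = 0.05, computed on the dfs actually
used for the p-value — a reporting convention (stated in the report
metadata), not an acceptance quantity. Post hoc phase comparisons are
paired t-tests on cap-averaged values with Bonferroni factor 3 and
Cohen's d_z = mean(differences)/SD(differences); the d_z convention is
declared in the output because paired-design d variants are not mutually
convertible.

Effect-size labels use inclusive thresholds 0.01/0.06/0.14 (partial η²)
and 0.20/0.50/0.80 (d); values below the smallest threshold are labelled
"negligible".

## Numerical and I/O choices

- EDF writer: one-second records, 16-bit, one symmetric physical range per
  file rounded *upward* through its ASCII header field so writer and any
  reader share the identical gain; quantization error ≤ range/2¹⁶ per
  sample. Whole-second data only (protocol segments always are).
  Annotations go out both as EDF+ TALs and as a JSON sidecar; plain-EDF
  consumers keep the sidecar. MNE reads the files back bit-compatibly
  (tested).
- Montages: the gel cap uses the standard idealized 10-05 positions
  (via MNE), sphere-fit, centered and projected to the unit sphere; the
  dry cap uses a golden-angle spiral over the head surface as an
  equidistant layout. Interpolation and synthesis only depend on this
  normalized geometry.
- Spline interpolation is exact for constants and ≤ 5 % leave-one-out
  error on smooth (≤ 3rd-order spherical-harmonic) fields for electrodes
  inside the cap hull. The two mastoids of the 10-20 layout sit well below
  the rim; evaluating the spline there is extrapolation with ~10 % error
  on such fields — a known limitation, acceptable because mastoids carry
  reference/ground in practice.
- Problem sizes: the default verification study analyzes 136 segments of
  120 s × 64 channels at 1024 samples/s (Phases I, II, IV, V for 17
  subjects × 2 caps); desk-scale smoke tests shrink the sampling rate and
  durations via explicit config fields, never the protocol defaults.

## Known limitations

- The acceptance-grade evidence is synthetic; see the generator's
  non-goals above.
- The alpha-presence reading ("peak vs mean of the two neighbor-band
  averages") and the neighbor-band edges (theta from 4 Hz, beta to 30 Hz,
  contiguous with the alpha band and the filter band) are one defensible
  operationalization; both are configurable.
- Phase I eyes-open spectra are computed but never gated or analyzed.
- No Huynh–Feldt correction, no multivariate alternative to the
  univariate ANOVA, no mixed models for incomplete designs: subjects with
  any missing cell are excluded, as in the complete-case design.
- Impedances are ingested and aggregated (kOhm tables), never measured or
  modeled; impedance is deliberately not used for channel rejection.
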