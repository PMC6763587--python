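# alphacog

EEG analysis pipeline around the **center-of-gravity individual alpha peak
frequency (iAPF)**, built for two-cap (dry multipin vs conventional gel)
mobile EEG studies of physical effort — e.g. a five-phase endurance-cycling
protocol where the iAPF shifts upward with fatigue.

The package is aimed at EEG researchers who want a reproducible,
fully-tested version of this analysis chain:

1. **I/O & segmentation** — EDF/EDF+ recordings (64 channels, 1024
   samples/s), montages on the unit sphere, phase annotations (EDF+ TALs
   or a JSON sidecar), per-phase segmentation.
2. **Preprocessing** — deterministic bad-channel detection (isoelectric,
   saturated, or predominantly artifactual signal for more than 30 s of a
   segment), zero-phase 30th-order Butterworth bandpass (1–40 Hz, SOS
   cascade), average re-referencing excluding bad channels, and Perrin-style
   spherical-spline interpolation (m = 4, 50 Legendre terms, ridge 1e-5).
3. **Spectra & iAPF** — Welch power spectral density averaged over
   consecutive 30-s intervals (4-s Hann windows, 50 % overlap), whole-head
   mean PSD, an alpha-presence gate, and the iAPF as the spectral center of
   gravity over the alpha band:

   iAPF = ∫ f·P(f) df / ∫ P(f) df over f ∈ [7.5, 13] Hz,

   computed only when the alpha peak is at least 1.3× the mean of the
   neighboring theta (4–7.5 Hz) and beta (13–30 Hz) band averages. Subjects
   lacking considerable alpha in any gate phase are excluded entirely.
4. **Reliability** — channel reliability (percentage of retained channels)
   per subject × cap × phase, plus per-electrode topographic grand averages.
5. **Inference** — a 2 (cap) × 3 (phase) within-subject RM-ANOVA implemented
   from explicit sums-of-squares and orthonormal-contrast formulas, with
   Mauchly's sphericity test, Greenhouse–Geisser df correction, partial η²,
   observed power, and Bonferroni-corrected paired post hocs with Cohen's
   d_z.
6. **Synthetic study generator** — a first-class module that emulates the
   full study (17 subjects × 2 caps × 5 phases) with *exact* ground truth:
   1/f background noise, partially coherent band-filtered alpha with a
   symmetric spectral envelope whose center is analytically compensated for
   the background's pull on the band center of gravity, eyes-open/closed
   alpha contrast, phase-dependent channel-failure rates, and Poisson-timed
   movement-artifact bursts.

## Worked example

Generate a small synthetic study (5 subjects, one of them alpha-deficient,
256 samples/s to keep it under a minute), analyze it, and inspect the
output:

```bash
cat > small.json <<'EOF'
{"n_subjects": 5, "n_excluded_no_alpha": 1, "fs": 256, "phases": ["I", "II", "IV", "V"]}
EOF
alphacog synth --seed 7 --config small.json --out study/
alphacog analyze --in study/ --out report.json
```

which prints:

```
analyzed subjects: 4 (excluded: 1)
  dry phase II: iAPF 10.23 ± 0.38 Hz (n=4)
  dry phase IV: iAPF 10.37 ± 0.38 Hz (n=4)
  dry phase  V: iAPF 10.39 ± 0.37 Hz (n=4)
  gel phase II: iAPF 10.23 ± 0.39 Hz (n=4)
  gel phase IV: iAPF 10.36 ± 0.39 Hz (n=4)
  gel phase  V: iAPF 10.42 ± 0.38 Hz (n=4)
```

The alpha-deficient subject was gated out by the 1.3× presence criterion;
the four remaining subjects' grand means recover the generator's configured
phase means (10.22 / 10.36 / 10.41 Hz dry, 10.23 / 10.37 / 10.43 Hz gel)
to within estimator noise, in the monotone fatigue ordering II < IV < V.
The ± values are the between-subject spread (the generator draws a
per-subject iAPF offset with 0.26 Hz SD; at n = 4 the sample SD is noisy).
In Python the full-scale equivalent (17 subjects at 1024 samples/s) is:

```python
from alphacog import PipelineConfig, SynthStudyConfig, run_pipeline
from alphacog.phases import Phase

config = SynthStudyConfig(seed=20260, phases=(Phase.I, Phase.II, Phase.IV, Phase.V))
report = run_pipeline(PipelineConfig(synth=config))
print(report.iapf_grand_means())
print(report.anova.effects["phase"].f, report.anova.effects["phase"].p_corrected)
```

## Layout

```
src/alphacog/
  recording.py    Recording container, phase segmentation
  phases.py       five-phase protocol model
  edf.py          EDF/EDF+ reader/writer + JSON annotation sidecar
  montage.py      equidistant-64 (dry) and 10-20-64 (gel) layouts
  synth.py        synthetic study generator with exact ground truth
  preprocessing.py  QC, bandpass, average reference, spherical splines
  spectral.py     Welch PSD, presence gate, center-of-gravity iAPF
  reliability.py  channel-reliability and topographic summaries
  stats.py        2x3 within-subject ANOVA, post hocs, effect sizes
  pipeline.py     end-to-end orchestration
  cli.py          `alphacog` command-line tool
docs/methods.md   model, assumptions, parameter choices, limitations
```
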