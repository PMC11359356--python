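# Methods

`articulab` studies how the place of articulation of the Polish sibilants
/s/ and /ʂ/ expresses itself in hybrid acoustic–visual feature vectors, and
which features separate articulation patterns (dental vs. interdental for
/s/; alveolar, dental, postalveolar for /ʂ/). Real multimodal recordings of
child speech are not distributable, so the package pairs the analysis
pipeline with a synthetic-cohort generator that reproduces the statistical
structure the analysis assumes; everything downstream of the generator is
the same code a real corpus would flow through.

## Pipeline

1. **Segments.** Audio is mono 44.1 kHz PCM; each annotated sibilant
   segment is min–max normalized to [0, 1] and cut into 33-ms,
   non-overlapping, Hamming-windowed frames (1455 samples; trailing
   partial frames dropped). The 33-ms grid matches the video frame rate,
   so every audio frame has one dual-camera video frame.
2. **Acoustic features (76).** Per frame: 4 time-domain (zero-cross rate,
   short-term energy, pitch, harmonic ratio), 24 full-band spectral
   (moments, crest, decrease, entropy, flatness, flux, rolloff, slope and
   13 MFCCs from a 26-filter mel bank), and 48 noise-band features
   computed on the power spectrum above 2 kHz, where sibilant frication
   noise lives: four noise-formant frequencies and levels, their ratios
   and distances, 13 cepstral coefficients from 20 linear triangular
   filters, 10 sub-band energies, and the noise-band peak amplitude and
   frequency.
3. **Visual features (87 per camera).** On the mouth region of interest
   (lips plus mouth interior, quantized to 32 gray levels): 22 global
   histogram/intensity features and 41 matrix texture features (GLCM,
   GLRLM, GLSZM, NGTDM), plus 8 shape descriptors (area, perimeter,
   circularity and its reciprocal, ellipse axes, elongation, maximum
   Feret diameter) for each of mouth, lips and tongue. Teeth labels are
   ignored. Left and right cameras contribute independent copies
   (`_L`/`_R`), 174 visual columns in total.
4. **Aggregation.** Each segment's frames are cropped by 25% at both ends
   (floor rule, at least one frame retained) to shed boundary
   contamination; all retained frames of a speaker's segments are
   averaged with equal weight per frame into one 250-feature vector per
   speaker, keeping the statistics on independent observations.
5. **Statistics.** Per feature: a Shapiro–Wilk screen per group
   (recorded, not gating — the battery is non-parametric throughout), a
   log transform `log(x - min + eps)` when pooled |skewness| > 2, a
   Brown–Forsythe test (recorded), and a variance-ratio screen excluding
   the feature when any between-group ratio leaves [0.1, 10]. Two groups
   are compared with the Mann–Whitney U test (midranks; exact enumeration
   when n1+n2 <= 20 and tie-free, tie-corrected normal approximation with
   continuity correction otherwise) and the rank-biserial magnitude
   rb = |1 − 2U/(n1·n2)|; three groups with the tie-corrected
   Kruskal–Wallis test, eta² = (H − k + 1)/(n − k), and pairwise
   Mann–Whitney post hocs with Bonferroni ×3 capped at 1. Output keeps
   p < 0.05 rows sorted by effect size descending. Effect bands: rb
   0.40/0.60 (below 0.10 negligible — the negligible floor for rb is a
   package convention, the usual bands specify only 0.39/0.59 cut
   points); eta² 0.01/0.06/0.14.

## The synthetic cohort

The generator's defaults are the study conditions: /s/ cohorts have 113
dental and 31 interdental speakers; /ʂ/ cohorts 106 alveolar, 27 dental
and 29 postalveolar. Each speaker contributes 2 words with segment
durations uniform on 0.12–0.30 s (3–9 frames, about 4 after cropping) —
compact but realistic sibilant segments, chosen once for tractable
Monte-Carlo studies.

**Audio.** White noise through a parallel bank of four second-order
band-pass resonators. The dominant resonance (0 dB, bandwidth
200 + 0.04·f Hz) sits at the class's noise peak; three weaker formants
(−10/−14/−18 dB, wider bands) at 1.45/1.9/2.4× the peak give the spectrum
fricative-like structure. Class peaks: /s/ 5100 (dental) vs. 4800 Hz
(interdental) — a deliberately small acoustic effect, since /s/ classes
separate mainly visually; /ʂ/ 3200/4800/2600 Hz for
alveolar/dental/postalveolar, the noise-band shift that dominates the /ʂ/
analysis.

**Video.** Each frame renders an elliptical lip annulus around a
mouth-interior region (96×128 px), with a thin teeth band and, with
class-dependent probability, an elliptical tongue whose area follows a
truncated normal law. Dental /s/: tongue visible in 15% of frames, mean
area 300 px; interdental: 75% and 900 px. Left/right cameras render the
same articulator state with independent jitter and pixel noise.

**Speakers.** Children vary: each speaker draws a noise-peak offset
(N(0, 350 Hz), the whole formant stack shifts together), a
tongue-visibility probability jittered on the logit scale, a mean tongue
area from the class law, and a small mouth-geometry offset. The logit
spread is class specific for /s/ (1.7 dental, 0.5 interdental): a mostly
hidden tongue appears erratically while deliberate protrusion is
consistent. These dispersions were calibrated so the dental/interdental
variance ratio of aggregated tongue areas stays well inside the battery's
own [0.1, 10] screen (median ≈ 3.5 across seeded cohorts): the configured
effect is meant to be measurable, not screened away.
Reproducibility is piecewise: speaker *i*, segment *j* uses the
`(master_seed, i, j)` sub-stream.

**What the generator does not emulate.** Real faces and lighting,
segmentation-model failures, coarticulation, word-dependent effects,
outlier speakers, or any coupling between acoustic and visual channels
beyond shared class membership. Passing calibration here shows the
pipeline recovers effects of the configured shape and size from data with
realistic sampling noise — not that the same features would win on real
recordings.

## Calibration results the test suite recomputes

* **Recovery (/s/):** on default 113/31 cohorts, tongue area and Feret
  diameter are significant with the interdental median higher in ≥95% of
  20 seeded runs.
* **Recovery (/ʂ/):** on default 106/27/29 cohorts (acoustic modality,
  where the configured effect lives), the noise-peak frequency reaches
  Kruskal–Wallis p < 0.001 with eta² in the high band in ≥95% of 20
  seeded runs.
* **Null calibration:** with identical class profiles the pooled
  feature-wise rejection rate at alpha = 0.05 stays within 0.05 ± 0.02
  over 40 seeded cohorts. Null cohorts use 45/15 speakers with one word
  each — rejection rates do not depend on cohort size, so a compact
  cohort keeps the study fast.

## Numerical choices

* Frame length 1455 samples = round(0.033·44100); FFT size 2048
  (zero-padded).
* The printed segment-normalization formula divides by the range without
  subtracting the minimum; the implementation uses full min–max
  normalization, the only reading consistent with the promised [0, 1]
  output. Zero-cross rate and autocorrelation consequently operate on the
  mean-centred frame (a [0, 1] signal never crosses zero).
* Pitch: autocorrelation peak in 50–500 Hz with a 0.3 voicing threshold;
  frication is unvoiced, so pitch 0 is the expected output.
* Noise-formant picking: 9-bin moving-average smoothing of the dB
  spectrum, the four most prominent `find_peaks` maxima, ascending;
  fewer than four peaks repeat the highest-frequency one, none at all
  fall back to the global maximum. Ratio orientation NFFRij = NFFi/NFFj,
  distances NFFDij = NFFj − NFFi; zero denominators yield 0 with a
  warning.
* Texture matrices follow common radiomics conventions: GLCM distance 1,
  4 directions, symmetric, matrices averaged then normalized; GLRLM
  matrices averaged over 4 directions; GLSZM 8-connected; NGTDM 3×3
  neighborhood with in-mask neighbors, coarseness capped at 1e6.
  Histogram features use quantized levels, intensity features raw gray
  values.
* Empty organ masks produce all-zero shape features rather than missing
  values: per-speaker averages then encode *how often* the tongue is
  visible as well as how large it is, which is the effect under study.
* Cropping precedes averaging (the only executable order); per-frame
  visual features are computed only for retained frames, an equivalent
  optimization.
* An all-identical sample gives Kruskal–Wallis H = 0, p = 1 (the tie
  correction is degenerate there).

## Limitations

* Mann–Whitney p-values for large groups rely on the normal
  approximation; with heavy ties in small groups the exact enumeration is
  skipped by design.
* The acoustic and visual channels of the generator are conditionally
  independent given the class; hybrid features cannot show cross-modal
  redundancy effects.
* No multiple-testing correction is applied across the 250 features — the
  battery mirrors a per-feature screening analysis; an FDR step would be
  a natural extension.
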