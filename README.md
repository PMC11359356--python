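# articulab

Hybrid acoustic–visual feature analysis of sibilant place of articulation,
for speech-science and computer-assisted speech-diagnosis research.

Misarticulated sibilants (sigmatism) are the most common speech disorder in
Polish-speaking children. Where in the vocal tract a child forms the
constriction — dental, interdental, alveolar, postalveolar — is hard to
assess without an expert, but it leaves traces in two observable channels:
the spectrum of the frication noise, and the visible configuration of lips,
mouth and tongue. `articulab` implements a full screening pipeline over
both channels for the sibilants /s/ and /ʂ/:

* a **synthetic multimodal cohort generator** (audio segments + dual-camera
  articulator label masks) with class-dependent structure, so the whole
  pipeline is testable without any recordings;
* **feature extraction**: 76 acoustic features per 33-ms frame (4
  time-domain, 24 full-band spectral, 48 noise-band spectral) and 87 visual
  features per camera view (63 texture features on the mouth region at 32
  gray levels, 8 shape descriptors each for mouth, lips, tongue);
* **per-speaker aggregation** (25% end-cropping, frame averaging) into one
  250-feature hybrid vector per speaker;
* a **non-parametric statistical battery** that screens distributions and
  variance ratios, then ranks features: Mann–Whitney U with the
  rank-biserial correlation rb = |1 − 2U/(n₁n₂)| for two articulation
  classes, Kruskal–Wallis with η² = (H − k + 1)/(n − k) and Bonferroni
  post hoc pairs for three.

## Worked example

```python
from articulab import CohortConfig, Sibilant, run_study, simulate_speaker_table

table = simulate_speaker_table(CohortConfig(sibilant=Sibilant.SH, seed=3))
res = run_study(table, Sibilant.SH)
print(res.summary(max_rows=3))
```

prints

```
Articulation study: /ʂ/ (alveolar, dental, postalveolar)
speakers: 162   features tested: 222   excluded: 28
test: Kruskal-Wallis + eta2   alpha = 0.05
significant features: 54

 no feature data  type camera        p statistic effect effect_band
  1    NCC3    A noise        1.57e-25   114.233  0.706        high
  2     NE2    A noise        1.82e-25   113.927  0.704        high
  3    NCC0    A noise        3.78e-25   112.471  0.695        high
... (51 more rows)
```

The default /ʂ/ cohort has 106 alveolar, 27 dental and 29 postalveolar
speakers whose frication-noise bands peak near 3200, 4800 and 2600 Hz.
The battery recovers that design: the strongest features are noise-band
acoustic (sub-band energies, noise cepstra, the noise peak frequency NPF),
each with a Kruskal–Wallis p far below 0.05 and η² in the high band
(> 0.14). `res.results` is the full ranked table (p < 0.05 only, sorted by
effect size), `res.excluded` lists features dropped by the variance-ratio
screen, and `res.plot_top(3)` draws per-class box plots of the strongest
features. For /s/ cohorts the same call uses the Mann–Whitney test and
ranks tongue-shape features (area, Feret diameter) on top — the visual
channel dominating, with only weak noise-band effects.

A command-line interface covers the same flow on disk corpora:

```bash
articulab simulate --sibilant s --out corpus/ --seed 7
articulab extract  --corpus corpus/ --out speakers.csv
articulab analyze  --features speakers.csv --out results.csv
articulab report   --features speakers.csv --out report.md
```

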