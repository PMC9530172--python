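# starchshg

Nondestructive profiling of leaf starch from paired two-photon-fluorescence
(TPF) and second-harmonic-generation (SHG) laser-scanning images.

Transitory starch in leaves is synthesized in chloroplasts during the day
and degraded at night. Because starch granules are semicrystalline (and thus
non-centrosymmetric), they emit SHG at exactly half the excitation
wavelength, while chlorophyll autofluorescence (TPF) marks the chloroplast
thylakoids around them — so a single multiphoton scan of a fresh, intact
leaf reports both where the chloroplasts are and how much starch they hold,
with no staining, extraction or transgenics. This package implements the
full analysis for such data, plus a synthetic scene generator so every stage
can be exercised and validated without a microscope.

## The statistic

For each imaged field, starch content is quantified as

    ratio = I_SHG / Cnt_TPF

where `I_SHG` is the summed SHG photon count over pixels whose count exceeds
a background level (default 2 counts at 0.128 ms dwell) and `Cnt_TPF` is the
number of TPF pixels above a morphology threshold (default 50 counts at
0.016 ms dwell), a proxy for chloroplast area. Tracked over Zeitgeber time
(ZT, hours after lights-on) in a 16 h light / 8 h dark photoperiod, the
ratio rises through the light phase and falls at night in wild-type
Arabidopsis (Col-0), but stays high in the degradation-deficient *sex1*
mutant.

The package has five parts:

* **simkit** — synthetic multiphoton scenes with ground truth: elliptical
  chloroplasts with TPF-dark stroma pockets, SHG granules confined to those
  pockets, Poisson photon counts scaling with dwell time, hyperspectral
  cubes (chlorophyll band, 532 nm SHG line, a weak ~590 nm contaminant), and
  piecewise-linear diel starch kinetics per genotype.
* **quantify** — the threshold-gated ratio statistic and the
  SHG-inside-chloroplast colocalization check (TPF mask via morphological
  closing of the thresholded autofluorescence).
* **spectral** — band integration over filter passbands (655–685 nm TPF,
  530.5–533.5 nm SHG), pseudo-color rendering, SHG peak detection at half
  the excitation wavelength, and a flanking-window estimate of fluorescence
  leakage under the SHG band.
* **diurnal** — per-ZT aggregation (mean ± SD over imaging areas),
  light/dark-phase OLS slopes with bootstrap confidence intervals, and
  diel-pattern classification (diel-cycling / non-degrading /
  indeterminate).
* **io / pipeline / cli** — TIFF + CSV + YAML formats, manifests, provenance
  records, the umbrella `run_pipeline`, and a thin `starchshg` console
  command (`simulate`, `quantify`, `spectral`, `diurnal`, `run`).

## Worked example

`examples/diel_classification.py` simulates one wild-type and one *sex1*
experiment (ZT 0–24 every 3 h, 12 imaging areas on 2 leaves), quantifies
every field and classifies the patterns:

```
--- col0 ---
  ZT   0: ratio  0.065 +/- 0.021 (n=12)
  ZT   3: ratio  0.429 +/- 0.095 (n=12)
  ...
  ZT  15: ratio  2.129 +/- 0.568 (n=12)
  ZT  18: ratio  1.484 +/- 0.317 (n=12)
  ZT  24: ratio  0.074 +/- 0.026 (n=12)
  light-phase slope +0.138/h, 95% CI (+0.121, +0.155)
  dark-phase slope -0.235/h, 95% CI (-0.264, -0.205)
  pattern: diel-cycling; Spearman(mean ratio, true mass) = 0.983
--- sex1 ---
  ...
  light-phase slope +0.028/h, 95% CI (+0.010, +0.047)
  dark-phase slope +0.050/h, 95% CI (-0.038, +0.140)
  pattern: non-degrading; Spearman(mean ratio, true mass) = 1.000
```

The wild type rises through the light phase and falls at night
(diel-cycling, with a small nonzero dawn baseline); the mutant accumulates
but never declines (non-degrading). The Spearman correlation against the
simulator's true starch mass shows the ratio statistic recovers the
underlying kinetics.

The other examples cover single-field quantification with colocalization
(`simulate_and_quantify.py`) and hyperspectral validation — the SHG peak at
532 nm = 1064/2 and the leakage fraction under the SHG band
(`spectral_validation.py`). The same workflow is available from the shell:

```sh
starchshg simulate --genotype col0 --zt-grid 0:24:3 --areas 12 --seed 1 --out run/
starchshg quantify --manifest run/manifest.csv --out run/quant.csv
starchshg diurnal --quant run/quant.csv --out run/diel/
```

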