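# Methods

## The measurement model

A multiphoton laser-scanning microscope with 1064 nm femtosecond excitation
acquires two photon-counting channels from a fresh leaf: chlorophyll
two-photon fluorescence through a 670/30 nm bandpass (TPF, 0.016 ms pixel
dwell) and second-harmonic generation through a 532/3 nm bandpass (SHG,
0.128 ms dwell). SHG is emitted at exactly half the excitation wavelength
and only by non-centrosymmetric material — in mesophyll, the semicrystalline
starch granules inside chloroplast stroma. TPF marks the thylakoid
membranes, which surround but do not fill the stroma, so granules appear as
SHG signal inside TPF-dark pockets of TPF-bright chloroplast regions.

Per-field starch content is `ratio = I_SHG / Cnt_TPF`: the summed SHG count
over pixels strictly above a background of 2 counts, divided by the number
of TPF pixels strictly above 50 counts. "Above" is strict (>) throughout,
isolated in one comparison utility (`quantify.above`) so the convention is a
single switch. Retained SHG pixels contribute their full count; the
background gates membership and is not subtracted. Both thresholds are
defined at the reference dwell times; for images at other dwells the
effective threshold scales linearly with dwell (counts are proportional to
integration time) and the rescaling is logged. `Cnt_TPF` uses the raw
thresholded mask by default; a morphologically cleaned variant is exposed
via `closing_radius_px`. A field with `Cnt_TPF = 0` yields a flagged record
with NaN ratio, never a silent zero, and aggregation excludes it explicitly.

The TPF threshold of 50 is treated as a given empirical constant of the
instrument configuration; this package does not attempt to re-derive it.

## Colocalization

The chloroplast region is the thresholded TPF mask closed with a disk
(default radius 2 px). Closing fills the TPF-dark stroma pockets — which is
where the granules sit — so "inside the chloroplast" includes them; closing
is extensive (never removes above-threshold pixels), and the implementation
pads before closing so border objects behave like interior ones. The
colocalization report is |SHG⁺ ∩ chloroplast| / |SHG⁺|, NaN-flagged when no
SHG-positive pixel exists. On synthetic scenes with the contaminant off,
the fraction is exactly 1 whenever the closing radius covers the stroma-site
radius (sites are kept disjoint precisely so each dark pocket is a closable
disk).

## Spectral validation

Hyperspectral cubes (x, y, wavelength) validate the filtered images.

* **Band integration** uses the trapezoid rule on the native grid with
  linearly interpolated band edges — exact for the piecewise-linear
  interpolant and therefore additive over adjacent bands; a plain bin-sum
  convention is available (`method="sum"`) since acquisition software often
  simply sums bins. Filter passbands come from center/width arithmetic:
  532/3 nm → 530.5–533.5 nm, 670/30 nm → 655–685 nm.
* **SHG peak detection** subtracts a local continuum — the chord between the
  median intensities of two 5 nm flanking windows offset 2 nm from the band
  edges — and accepts the strongest local maximum whose height above the
  continuum exceeds 3× a robust (MAD) noise scale of the flank residuals. A
  tiny relative floor guards the noiseless limit. Peak location is accurate
  to one grid step on noiseless lines.
* **Leakage estimation** reuses the flanking-window continuum: the leakage
  fraction is continuum-integral over total band integral, clipped to
  [0, 1], with negative interpolated continua clipped to zero under a
  warning. Both the prominence criterion and the estimator geometry are
  package choices (the phenomena they quantify are only qualitative in
  origin), fully parameterized. The estimator is exact for a linear
  continuum and overestimates a convex exponential tail by the chord-vs-arc
  gap, well under the ±0.05 documented accuracy at the default geometry.
* **Pseudo-color** rendering min–max scales each channel for display only;
  quantitative consumers get the raw band integrals.

## Diel analysis

Area-level ratios are aggregated per Zeitgeber time as sample mean and
sample SD (n−1); single-area rows carry sd 0 with an `n=1` flag; each row
records its own n rather than assuming a fixed number of areas. Light-phase
(ZT ∈ [0, 16]) and dark-phase (ZT ∈ [16, 24]) trends are ordinary
least-squares slopes over area-level points with a 95% case-resampling
bootstrap interval (default 2000 reps, seeded; degenerate resamples with a
single distinct ZT are dropped). The ZT16 boundary point belongs to both
phases; ZT0 and ZT24 are distinct measurements (this dawn vs the next), not
wrapped. At least three distinct ZT points per phase are required.

Classification: *diel-cycling* iff the light CI is entirely positive and the
dark CI entirely negative; *non-degrading* iff the light CI is positive (or,
when the caller supplies a `high_level` reference, flat with both phase
means above it) while the dark CI contains zero or is positive; otherwise
*indeterminate*. The flat-but-high branch needs a level scale that slopes
alone cannot provide, so it stays inert unless `high_level` is given.

## The synthetic scene generator

The generator emulates the study conditions, not the optics. Defaults (one
160×160 field): 12 elliptical chloroplasts with semi-axes 7–12 px; disjoint
disk-shaped stroma sites (radius 1.2–2.0 px) carved on a jittered lattice up
to a 0.2 area-fraction target; granules placed one per site (radius capped
by the site) until cumulative granule area reaches
`starch_mass × 15 px/unit`. Keeping sites disjoint guarantees every TPF-dark
pocket closes under the default 2 px closing radius; the lattice makes
placement O(sites) and deterministic under a seeded generator. The recorded
ground-truth mass is the requested (model) mass; realized granule area
quantizes it by up to one granule, which at the dawn baseline produces the
small nonzero dawn ratio expected of residual starch.

Photon statistics: thylakoid pixels have expected TPF counts of
7500/ms × dwell (120 at the reference dwell — comfortably above threshold
50); granule pixels 160/ms × dwell (≈20.5 at reference — comfortably above
background 2); realized counts are independent Poisson draws, so means scale
exactly with dwell. Outside signal regions the expectation is zero — no
dark-count floor — so zero-contaminant scenes give exact colocalization.

Spectra are built additively per pixel from three unit-peak shapes scaled by
integration time: a split Gaussian chlorophyll bump peaking at 678 nm
(σ 10 nm blue side, 18 nm red side — the same qualitative skew as a
skew-normal, but exactly peak-positioned and cheaper to evaluate); a
Gaussian SHG line at excitation/2 with σ 0.5 nm on granule pixels; and a
590 nm contaminant (Gaussian bump, σ 15 nm, plus exponential wings with
40 nm scale) on thylakoid pixels, whose short-wavelength tail is what leaks
into the SHG band. `leak590_amplitude` sets the contaminant peak relative to
the SHG line peak; at the default 0.1 the in-band contamination is ≈1% of
the in-band SHG integral, and the same spectral ratio converts into the
expected spurious SHG-channel count on thylakoid pixels in the filtered
images, keeping the two rendering paths consistent. Cubes are noiseless by
construction; component fields are returned on request and sum exactly to
the cube. The identity of the real-world ~590 nm emitter is unknown; the
generator treats it as a generic contaminant and makes no biological claim.

Diel kinetics are piecewise linear — the simplest shape with the described
rise, fall and nonzero dawn baseline: `baseline + synth_rate·zt` while the
light is on, then linear decay clamped at the baseline. *sex1* is the same
law with `degrade_rate = 0` (enforced as a model invariant), i.e.
`baseline + synth_rate·min(zt, 16)`. Wild-type defaults (baseline 0.2 units,
synthesis 1 unit/h, degradation 2 units/h) return to baseline exactly at the
next dawn; *sex1* defaults (baseline 10, synthesis 0.4) keep the mutant
persistently high with a mild daytime rise. Between-area variability is a
lognormal multiplier on starch mass (σ = 0.25), one independent draw per
area and time point, chosen to produce SD bars of roughly 10–30% of the
mean as in area-resolved imaging. Twelve areas distributed round-robin over
two leaves is the default sampling design.

### What the generator does not emulate

No point-spread function, phase matching or depth effects (single focal
plane, binary masks with hard edges); no detector dark counts or read
noise; no chloroplast movement or overlap of granules between sites; cube
noise is absent entirely. Passing tests therefore demonstrate the
correctness and statistical behavior of the *analysis* under the stated
generative model — threshold gating, Poisson dwell scaling, band
arithmetic, trend inference — not robustness to optical blur, motion or
detector artifacts in real acquisitions.

## Numerical and design choices

* Counts are stored as unsigned 16-bit (Poisson means here are far below
  saturation; a 65535-valued pixel is logged as saturated on read).
* Float-valued image TIFFs are rejected at load (photon-count contract);
  hyperspectral cubes are float32, with CCD-style continuous intensities.
* Bootstrap intervals are percentile-based; a fixed seed makes them, and
  every CSV the pipeline writes, byte-reproducible.
* Test and validation problem sizes (64×64–160×160 fields, 1000-render
  Poisson checks, 20 replicate experiments per genotype) were chosen as the
  smallest sizes at which the statistical criteria are comfortably
  resolved.

## Known limitations

The ratio is a relative, per-field quantity; it is not calibrated to
absolute starch mass and comparisons are only meaningful within an
instrument configuration (thresholds are dwell- and gain-specific). The
leakage estimator assumes a locally near-linear continuum; a continuum with
strong curvature inside the 3 nm band would bias it. The classifier's
flat-but-high branch requires an external level reference. Scene capacity
(stroma-site packing) caps extreme starch masses; beyond ≈25 mass units per
default field the realized granule area saturates, compressing — but never
reordering — the top of the ratio's dynamic range.
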