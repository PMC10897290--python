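# cristoscope

Quantitative morphometry for cryo-electron tomograms of mitochondria, built
around fully synthetic phantoms so that every measurement can be validated
against known ground truth without any microscope data.

Mitochondrial cristae — the folds of the inner membrane that house the
electron transport chain — remodel dramatically with the balance of long and
short forms of the fusion GTPase Opa1, and quantifying that remodeling in
situ means extracting numbers from noisy, missing-wedge-corrupted 3-D
volumes: crista membrane-to-membrane widths, junction widths and angles,
compartment volumes, crista lengths, and shape-class frequencies.  This
package implements that measurement layer as a tested library for anyone who
works with segmented cryo-ET volumes of double-membrane organelles.

## What's inside

* **`cristoscope.phantom`** — synthetic mitochondrion tomograms: nested
  ellipsoidal membranes, cristae of seven shape classes with configurable
  width/length/junction geometry, Gaussian noise at a chosen SNR, and a
  missing wedge applied in Fourier space (a ±70° tilt range leaves a 20°
  half-angle wedge unsampled).
* **`cristoscope.subtomo`** — the width estimator at the core of the
  pipeline.  A bank of 40 two-membrane templates with centre-to-centre
  separations *d<sub>k</sub> = k · 2.2 nm* (k = 1…40, spanning 2.2–88 nm) is
  cross-correlated against each membrane-pair subvolume; writing the masked,
  zero-mean normalized cross-correlation as

  &nbsp;&nbsp;&nbsp;&nbsp;CC(k) = max₍shift₎ ⟨P − μ_P, T_k − μ_T⟩_m / (σ_P σ_T),

  the particle's crista width is *d*<sub>argmax<sub>k</sub> CC(k)</sub>, the
  separation of the best-matching template.  Iterative subtomogram
  alignment/averaging (12-iteration budget, seeded random initial reference)
  is included.
* **`cristoscope.morpho2d` / `cristoscope.shape3d`** — projection-plane
  measurements (outline areas by the shoelace formula, field coverage,
  cristae per µm², matrix gray density, junction width/angle) and 3-D
  measurements (compartment volumes, skeleton-based crista length, and a
  rule-based classifier for lamellar / tubular / globular / ring / loop /
  straight-across / split / zipped / pinched / vesicular / amorphous cristae,
  plus stacking detection and mitochondrial outline classes).
* **`cristoscope.stats`** — the group-comparison policy: two-sided
  Mann–Whitney U (exact by full enumeration for small samples, tie- and
  continuity-corrected normal approximation otherwise) unless both samples
  pass Shapiro–Wilk normality, in which case Welch's t is used.
* **`cristoscope.pipeline` + `analysis/01…05`** — end-to-end drivers:
  simulate → measure → classify → widths → statistics, writing CSV tables
  and a JSON report.

## Worked example

`analysis/03_crista_widths.py` simulates two conditions — cristae of planted
width 15 nm and 20 nm at SNR 0.5 under a 20° missing wedge — samples 100
membrane-pair particles from each, and calls their widths against the
template bank:

```
narrow: planted 15 nm -> median call 15.4 nm over n = 100; average map (100 particles, 4 iterations) calls 15.4 nm
wide:   planted 20 nm -> median call 19.8 nm over n = 100; average map (100 particles, 6 iterations) calls 19.8 nm
```

Both medians land on the template-bank grid point nearest the planted truth
(the estimator reports widths in 2.2 nm steps), and the width called on the
subtomogram average agrees with the per-particle median.
`analysis/05_group_stats.py` then runs the statistics policy over three
conditions (15 nm reference, 15 nm replicate, 20 nm):

```
         metric group_b    test_name      p_value
crista_width_nm      KO mann_whitney 1.056152e-18
crista_width_nm      OE mann_whitney 3.295603e-01
```

— the planted 5 nm difference is detected decisively while the identical
replicate is (correctly) not distinguishable from the reference.

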