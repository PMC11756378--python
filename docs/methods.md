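# Methods

`tipshape` quantifies three things about microtubule (MT) plus ends: the 3D
shape of protofilament (PF) flares at the end, the number of fluorescent
molecules bound at the tip, and the end's dynamic behaviour over time. This
note records the models, the parameters that matter, and the design choices
made where more than one reasonable definition exists.

## Protofilament flare geometry

**Input model.** Each PF at an MT end is an ordered 3D polyline in nm. By
convention the first point sits on the MT wall, the point at `origin_index`
(1 for manually built contours) is the last point still inside the MT
cylinder, and subsequent points follow the bending part of the PF, placed
every 2–4 nm. The flare is everything from the origin point outward.

**Pipeline.** Flare points are resampled to uniform arc-length spacing by
piecewise-linear interpolation, smoothed with quadratic LOESS, and
differenced into per-joint turn angles:

- *Resampling* preserves the origin and terminus exactly; the final
  interval may be shorter than the step. The default step is **4.0 nm**.
  This is the coarse end of the manual point spacing, chosen so the LOESS
  window (see below) spans enough arc length that point noise does not
  dominate the curvature estimate: with ~1 nm click noise, a 10-point
  window at 2 nm spacing (18 nm of support) inflates the grand-mean
  curvature by >150% because the unsigned joint angles fold noise into a
  positive bias, while at 4 nm spacing (36 nm of support) recovery on
  simulated ends with known radius is accurate to well within 10%.
  Resampling finer than the raw ~3–4 nm information density of a manual
  trace adds no information; it only narrows the smoother's support.
- *LOESS* fits each coordinate against arc length with a locally weighted
  quadratic over the `window_points = 10` nearest samples, tricube
  weights, bandwidth equal to the distance of the farthest window member
  (which therefore gets weight zero — on a uniform interior grid this
  makes the effective window symmetric). Traces shorter than the window
  get a single global quadratic. Degree-2 polynomials pass through
  unchanged; the point count never changes. Because uniform resampling
  makes arc length equal index x step, the nominal grid is used as the
  regression abscissa.
- *Curvature* at each interior joint is the 3D angle between the two
  flanking segments (atan2 of cross/dot), in degrees, divided by the step
  to give deg/nm. The computation is fully three-dimensional and invariant
  under rigid motions; PFs that leave their initial bending plane are
  measured correctly. Conversions to degrees per joint and degrees per
  8-nm dimer are provided.

**Known estimator properties.**

- Equal-chord samples of a circle of radius R turn by exactly step/R
  radians at every joint; this survives LOESS exactly at interior joints.
  At the 2–3 joints nearest each trace end the asymmetric window shifts
  the smoothed points slightly off the circle (~0.25 deg at R = 20 nm,
  step 2 nm): local regression has boundary bias, and curvature, being a
  second difference, amplifies it.
- The same boundary bias flattens curvature *gradients* at the distal tip.
  In the tip-aligned mean profile the affected offsets are the tip-most
  half window; a linear fit over all offsets under-estimates a true
  curvature gradient by ~15–20%, while a fit excluding the tip-most half
  window recovers it to a few percent. The reported fit uses all offsets
  (matching how such profiles are usually fitted); users probing gradients
  should check the interior fit as well.
- Because joint angles are unsigned, any residual point noise biases mean
  curvature upward, never downward. The default step/window combination
  keeps this below ~8% at 1 nm click noise (verified by simulation
  against generated ends of known radius).

**Aggregation.** Per-end statistics average flare length, mean curvature
(mean of deg/nm over all joints) and terminal curvature (mean of the 3
distal-most joints — the window is a package choice, configurable) across
PFs with nonzero flare length; blunt PFs count toward the PF total but not
the means. PFs with a flare too short for curvature (< 3 resampled points)
still contribute length. Cap fractions are reported pooled (summed counts)
and per grid (mean ± SD across grids, the convention used for
capping-frequency plots). The curvature–length relation across ends is a
Pearson correlation with a two-sided p-value for zero slope.

The coiled-coil helper converts residue counts to axial length at
0.15 nm/residue (two-stranded alpha-helical coiled coil), the standard
figure for interpreting solution-scattering maximum dimensions; 80
residues give 12.0 nm.

## Single-molecule photometry

Spots are detected on a matched-filtered image (Gaussian of the nominal
PSF width, sigma 1.5 px) as local maxima exceeding
median + `min_snr` x MAD-sigma (default 4), with non-maximum suppression
at 3 px. Each candidate is fitted in an 11x11 ROI with an isotropic 2D
Gaussian plus constant offset; "intensity" means the fitted peak amplitude
(integrated intensity 2·pi·A·sigma^2 is available as an alternative).
Single-fluorophore amplitudes are modelled as lognormal; the MLE is the
mean/SD of log amplitudes and the reference intensity is the fitted
distribution mean exp(mu + sigma^2/2), not the arithmetic mean (which is
available via option). Molecules per tip spot = amplitude / reference
fitted mean; oligomer state = ratio of two fitted means (~1 monomer,
~2 dimer).

The synthetic spot generator draws each spot's amplitude as the sum of N
i.i.d. lognormal single-fluorophore intensities, renders an isotropic
Gaussian PSF over a constant background, then applies Poisson shot noise
and Gaussian read noise. It does not emulate EMCCD excess noise, drift,
photobleaching during acquisition, or non-uniform illumination — so
passing recovery tests demonstrate the estimator chain, not robustness to
those real-world effects. Recovery of N within 15% holds for N up to ~10;
beyond that spot overlap and detection bias against dim spots matter.

## Kymograph dynamics

Traced segments (dx pixels over dt frames) become events via the
calibration (defaults 0.064 µm/px, 3 s/frame): rate in µm/min, duration in
minutes. A segment is a **pause** iff |rate| ≤ 0.05 µm/min (the detection
floor for growth) **and** duration ≥ 15 s, inclusive at the boundary.
Near-zero segments shorter than 15 s are merged into the longer adjacent
growth event (displacement and duration combined, rate recomputed); an
isolated short stall stays a near-zero growth segment. Total traced time
is conserved through classification.

**Catastrophe frequency** = transitions into shrinkage (from growth *or*
pause, since transient pauses end in depolymerisation) divided by total
time in growth + pause. **End categories**: `fully_blocked` (no growth over
the whole observation span, default 10 min), `occasional_pauses` (≥ 1
pause plus growth), else `no_pauses` — every history maps to exactly one.
**Time-weighted rate distributions** weight each event by its share of
total event time, so the cumulative curve reads as "% of time spent at or
below this rate".

FRAP traces are normalised by the mean pre-bleach intensity only (no
reference-region double normalisation); recovery fraction is measured
relative to the post-bleach floor. Averaging across MTs assumes a common
time base.

The event generator alternates growth/pause sojourns and draws
catastrophes as a Poisson process on the growth+pause clock, which makes
the catastrophe-frequency estimator exactly the MLE of the simulated rate.
Default regimes: growth 1 µm/min (SD 0.2), pauses off unless enabled
(mean 0.5 min when on, matching the 0.28–0.72 min range typical of
transiently paused ends), shrinkage −12 µm/min, 10-min span. The
analysis drivers use 2 µm/min for the control condition and 0.075 µm/min
for the slow-growth condition (20–40x slower, at the detection floor).

## Problem sizes

Simulated studies use 50 ends x 14 PFs for flare-parameter recovery, 500
spots per stoichiometry level (five 320x320 frames of 100 spots), 10,000
draws for lognormal MLE checks, and 500 MTs x 10 min for catastrophe-rate
recovery — large enough that Monte-Carlo error sits well inside the
stated recovery tolerances.

## Limitations

- Automatic flare-origin detection (radial threshold mt_radius + 1.5 nm
  against a caller-supplied axis) is a convenience for traces lacking the
  manual two-point convention; with gently curving flares it can sit a
  point or two distal of the manual origin. Manual origins take
  precedence when present.
- MT polarity and axis direction are caller-supplied metadata; nothing
  here determines them from images.
- Curvature is unsigned; inflection or rocking of a PF cannot be
  distinguished from sustained bending of the same magnitude.
- The kymograph module consumes traced segments, not images; tracing
  error is outside its error budget.
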