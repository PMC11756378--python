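# tipshape

Quantitative analysis of microtubule (MT) plus-end architecture and
tip-bound protein stoichiometry, for in vitro reconstitution studies that
combine cryo-electron tomography, single-molecule TIRF microscopy and
kymograph analysis — e.g. studies of centriolar cap proteins that bind MT
plus ends, block their growth and suppress protofilament flaring.

The package answers three questions about an MT end:

1. **How are the protofilaments (PFs) shaped?** From manually traced 3D
   contours of terminal PFs, it measures flare length (arc length from
   the point where a PF bends away from the MT cylinder), curvature
   (turn angle θ between consecutive segments of the uniformly resampled,
   quadratic-LOESS-smoothed trace, expressed as θ/Δs in deg/nm, fully in
   3D), terminal curvature near the distal tip, tip-aligned mean ± SEM
   curvature profiles with a linear fit, per-end averages over PFs with
   nonzero flare, Pearson curvature–length correlations, and the fraction
   of ends carrying a luminal capping density (pooled and per-grid
   mean ± SD).
2. **How many molecules sit at the tip?** Diffraction-limited spots are
   fitted with 2D Gaussians; single-fluorophore peak intensities are
   modelled as lognormal(µ, σ) with fitted mean exp(µ + σ²/2); a tip
   spot's molecule count is its amplitude divided by that reference, and
   oligomer state is the ratio of two fitted means (≈1 monomer,
   ≈2 dimer).
3. **What is the end doing over time?** Traced kymograph segments become
   growth / pause / shrinkage events (pause ⇔ |v| ≤ 0.05 µm/min and
   duration ≥ 15 s), catastrophe frequency = transitions into shrinkage
   per minute of growth+pause time, end categories (no pauses /
   occasional pauses / fully blocked), time-weighted growth-rate
   distributions, and FRAP recovery curves normalised to the pre-bleach
   mean.

A synthetic-data module generates all three input kinds with known ground
truth (flared ends of prescribed radius and noise, spot fields with N
fluorophores per spot, event series with prescribed rates), so every
estimator is validated by parameter recovery.

## Worked example

```bash
python analysis/01_simulate_fixtures.py --seed 1   # synthetic study bundles
python analysis/02_pf_flaring.py                   # PF geometry
python analysis/03_spot_stoichiometry.py           # molecule counting
python analysis/04_dynamics_frap.py                # dynamics + FRAP
```

prints (seed 1):

```
mean flare length: capped 16.0 nm vs uncapped 46.0 nm
mean curvature:    capped 2.30 vs uncapped 2.13 deg/nm
curvature-length correlation: r = -0.37 (p = 0.0077, n = 50)
dimer / monomer fitted-mean ratio: 2.01
molecules at simulated blocked tips: mean 5.8 (min 4.0, max 7.9)
control: time-weighted growth rate 1.967 um/min, catastrophe 0.199 /min, ...
slow: time-weighted growth rate 0.075 um/min, catastrophe 0.019 /min, ...
control grows 26x faster than the slow regime
FRAP recovery plateau: 0.58 of pre-bleach intensity
```

Reading the numbers: the capped condition was generated with 15-nm flares
and the uncapped with 45-nm flares, and the pipeline recovers both means
(smoothing and 1-nm point noise account for the ~1 nm excess) while
measuring the same ~2.2 deg/nm curvature (true value 2.29 for the 25-nm
generation radius) in both — shorter flares, unchanged curvature, the
signature of a cap that limits peeling rather than straightening PFs.
The six-fluorophore "blocked tip" field reads out 5.8 molecules against
the monomer standard, and simulated dimers read 2.01. The slow-growth
kymograph regime (0.075 µm/min, at the detection floor) is 26× slower
than the 2 µm/min control.

The same steps are scriptable via the CLI (`tipshape simulate flares`,
`tipshape pf stats`, `tipshape spots fit|calibrate|count`,
`tipshape kymo events|summary`, `tipshape report config.yaml`) — each
command is a thin wrapper over the library functions used above.

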