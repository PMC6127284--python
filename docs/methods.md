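# Methods

## The pulse-chase wave analysis

A photoconvertible tag fused to a receptor subunit lets a dendritic pool be
marked in place: everything inside the photoconversion ROI turns red at
*t* = 0 and is then followed as it spreads.  The analysis is deliberately a
bulk one — no single-particle tracking — because the labelled pool is dense
and the biologically informative quantities are population velocities.

The dendrite trace (an operator-supplied polyline with a local width) is
resampled at quarter-pixel steps; every pixel within half the local width
of the trace belongs to the ribbon and is assigned to the nearest arc
position.  Bin zero is the ROI footprint; successive bins of width 5 μm
are tiled outward from the two ROI edges.  Bin labels are the distance
from the ROI edge to the bin's **outer** boundary ("the 10-μm bin" spans
(5, 10] μm beyond the ROI); intervals are half-open with boundary pixels
assigned to the more proximal bin, which makes the tiling deterministic.
Bins whose outer boundary passes the end of the trace are flagged
truncated and never enter velocity estimation.

Per frame, a background level (mean over an off-cell region, or a
constant) is subtracted, bin intensities are summed, divided by bin area,
and divided by the bin-zero area density at *t* = 0:

    W(b, t) = [F(b, t) / A(b)] / [F(0, 0) / A(0)].

`W(0, 0) = 1` exactly; `W` is invariant to any global gain, and — absent
noise and absorption — `Σ_b A(b) W(b, t)` is conserved over time.
Background subtraction is applied before normalisation: it is the identity
on offset-free synthetic data and necessary on camera data for the ratio
to be meaningful.

### Velocity estimators

* **Crest (time-to-peak).**  For each requested near bin (defaults 10 and
  15 μm), the time-to-peak is the earliest timepoint attaining the bin's
  maximum within the analysis window (default 120 s of a 180-s
  acquisition; the window is a knob).  `v = label / t_peak`.  A bin whose
  maximum sits at the window boundary has no interior peak and is
  excluded.  The distance used is the bin label; with the default ROI
  half-width of 2.5 μm the ROI length equals the bin width, and for a
  rigid advecting slug the slug-centre-to-bin-centre distance is then
  exactly the label, so `label / t_peak` is unbiased up to frame
  quantisation.
* **Leading edge.**  For each far bin (defaults 25–40 μm), the noise scale
  σ is the robust SD (1.4826 × MAD) of the *t* = 0 values of all bins at
  or beyond 25 μm — bins the pool cannot have reached at *t* = 0.
  Appearance is the earliest *t* > 0 with `W > W(b, 0) + 3σ` for two
  consecutive frames (k = 3 is a knob; σ = 0 falls back to a 10⁻⁶
  absolute margin).  `v = label / t_appear`.  The two-frame requirement
  rejects single-frame noise blips at the cost of being blind to signals
  occupying a bin for less than two frame intervals.

Appearance times are quantised **up** to the next frame, so single-neuron
leading-edge velocities are biased slightly low at 15-s frames (≈ −5 to
−10% at 0.82 μm/s); halving the frame interval halves the bias.  The
crest estimator at 0.2 μm/s lands between frames for the 10-μm bin
(true peak 50 s → 45 or 60 s) and exactly on a frame for the 15-μm bin
(75 s), giving a small positive bias (≈ +5%).  Both biases are properties
of the published bin/frame geometry, not of this implementation.

The two-population summary pairs each neuron's crest and edge velocity and
applies a paired two-tailed t test (α = 0.05): two populations are
reported when the samples differ with the edge mean above the crest mean.
Directions are never pooled.

## The simulator

`simulate_pulse_chase` places `n_particles` uniformly in the ROI at
*t* = 0 and propagates them along the arc coordinate:

| pool | default fraction | dynamics |
|---|---|---|
| stationary | 0.30 | fixed |
| slow (distal/proximal) | 0.28 + 0.28 | advection at ±0.2 μm/s + Brownian, D = 0.05 μm²/s |
| fast (distal/proximal) | 0.07 + 0.07 | advection at ±0.82 μm/s after an exponential departure delay, mean 30 s |

The slow:fast split of the motile pool is 80:20.  The published assay
reports only the two velocities; the motile fraction, diffusion
coefficient and dispatch kinetics are not measurable from it, so these
defaults are package choices, fixed once.  The departure delay is the one
modelling commitment that matters: an instantaneous rigid fast slug would
occupy a 5-μm bin for only ≈ 12 s, less than one 15-s frame, making a
sustained two-frame appearance physically impossible; staggered dispatch
(vesicles loaded over time) keeps the leading edge at exactly v_fast while
bins remain occupied once reached, which is also what the published
bin-intensity time courses look like.  A per-particle fast-speed
dispersion knob exists (`fast_velocity_cv`) and defaults to 0; when used,
drawn speeds are re-centred so the pool mean is exact.

Rendering: particles are Gaussian PSF spots (σ = 0.15 μm) of 50 photons on
a straight 2-μm-wide ribbon (curved traces are supported on the analysis
side; geometry is irrelevant to the estimators once arc length is used),
pixel 0.1 μm, over a uniform background of 10 photons/pixel, with Poisson
shot noise when `noise_on`.  Particles crossing a dendrite tip are
absorbed and flagged.  Photoconversion is instantaneous and complete;
there is no bleaching or photophysics model.  Identical config + seed
gives bit-identical movies.

The per-particle ground truth (population, velocity, departure time,
advection-only trajectory) supports exact parameter-recovery tests; a
`depot` knob plants extra stationary fluorescence at a chosen arc offset
(spread ±2.5 μm) to create a single-bin group effect for power studies of
the paired per-bin test.

### What a green test does and does not establish

The generator emulates the statistical structure the estimators assume:
two advecting pools, shot noise, PSF blur, uniform background.  It does
not emulate dendrite tapering or branching, spines, focal drift,
bleaching, conversion crosstalk, or operator variability in ROI placement.
Parameter recovery on this world validates the estimator logic and its
noise robustness — not the biological interpretation of any particular
recording.

## 3D puncta, nanodomains, colocalization

Puncta segmentation mirrors isosurface-style commercial workflows:
automatic two-class (Otsu) or fixed threshold inside the dendrite mask,
26-connectivity, optional splitting of touching objects by marker-based
watershed seeded at local maxima of the Gaussian-smoothed volume
(σ = 0.08 μm, seed separation 0.2 μm), and a minimum object volume
(default 8 voxels).  All distances honour anisotropic voxel sizes.  The
three reported metrics — puncta density, total puncta volume, and mean
punctum volume — are each divided by the dendritic segment volume (the
mask volume), including the mean punctum volume, matching the per-segment
normalisation convention of the assay this reproduces.

Nanodomain centres are local maxima of the smoothed volume (σ = 0.06 μm)
above threshold, non-maximum-suppressed at 0.15 μm and refined to
sub-voxel positions by a local intensity-weighted centroid (grid
quantisation of ±half a voxel would otherwise dominate distances between
closely spaced nanodomains).  Clusters are single-linkage connected
components at a 0.3-μm linking distance — chosen just above the ~120-nm
lateral resolution at which the scaffold channel is resolved; every
profile records the distance used.  Complete-linkage is deliberately not
the default: "clusters of multiple puncta" are connected groupings.

Pearson's r is the voxel-wise correlation inside the mask; Manders' M1 is
the fraction of channel-A signal in voxels where channel B exceeds its
threshold (default per-channel Otsu, i.e. the thresholded tM1/tM2
variants; raw T = 0 and fixed-threshold variants are options), M2 the
converse.  Degenerate inputs (zero variance, zero total signal) yield NaN
with a warning rather than an exception, so batch pipelines can proceed.
A both-channels-supra-threshold overlap mask can be exported for display;
no statistic depends on it.  No Costes-style randomisation test is
included.

## Group statistics and locus enrichment

`group_compare` provides the comparisons used in this experimental
design: two-tailed t tests, one-way ANOVA with pairwise Bonferroni
post-tests, Kruskal–Wallis with Dunn's test (midranks, tie-corrected
variance, normal reference, Bonferroni adjustment across reported pairs —
the adjustment is a choice, as "Dunn's test" does not itself name one),
and two-way ANOVA (type-II, reporting main effects and interaction) via
statsmodels.  Two identical samples are reported as t = 0, p = 1 rather
than NaN.

`paired_wave_test` compares two groups of wave matrices per (direction,
bin): the across-neuron mean value is formed per timepoint per group and
the two mean series are compared by a paired two-tailed t test with
timepoints as the pairing dimension.  This treats timepoints as exchange-
able paired observations of one bin's trajectory, which is powerful for a
sustained shift and deliberately simple — it is the design used in the
bin-wise panels this package reproduces, not a longitudinal mixed model.

`locus_enrichment` reports two statistics because "enrichment of loci
containing at least one dysregulated gene" has no single canonical null
when loci differ in size.  The gene-level statistic is the upper-tail
hypergeometric probability of the observed DE/target-gene overlap (exact;
verified against exhaustive enumeration).  The locus-level statistic
counts loci with ≥ 1 DE gene and compares it with the null distribution
obtained by redrawing the DE set uniformly from the universe (default
10,000 permutations, seeded; `p = (1 + #{null ≥ obs}) / (n_perm + 1)`, so
p is never 0 and never below `1/(n_perm+1)`).  Neither statistic claims
to reproduce any particular published p value, whose null construction is
not recoverable.

The universe generator plants enrichment by weighted sampling without
replacement (weight = fold inside loci, 1 outside), so the DE count is
exact and the in-locus rate is the planted fold times background in
expectation; folds that would push the per-gene probability above 1
saturate with a warning.

## Numerical and degenerate-input choices

* Peak ties break to the earliest timepoint (a peak is first attained,
  then sustained).
* Bin-boundary pixels go to the more proximal bin; both conventions
  differ only by single-pixel rings and the normalisation divides areas
  out.
* `W(0,0) ≤ 0` (no photoconverted signal) is a hard error; an empty bin
  mask is a hard error; an all-excluded velocity estimate is a flagged
  NaN, not an error.
* Fewer than 3 usable neurons leaves the population count undefined
  (flagged) rather than forcing a decision.
* Robust SD uses 1.4826 × MAD throughout.

## Known limitations

* The simulator's dendrite is straight and of constant width; curved
  traces exercise the analysis geometry in tests, not the renderer.
* The leading-edge rule formalises what was an operator judgement in the
  workflows this package reproduces; k = 3 and the two-frame rule are
  stated choices, not a claim about how any published dataset was scored.
* Segmentation parameter defaults (Otsu, watershed on, 8-voxel minimum)
  stand in for unpublished commercial-tool settings; absolute puncta
  metrics depend on them, between-group contrasts much less so.
* The acceptance-level velocity recovery inherits ±5–10% frame-grid
  biases described above; they shrink with faster acquisition, not with
  more neurons.
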