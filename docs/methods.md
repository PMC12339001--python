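# Methods

This note documents the measurement definitions, model assumptions,
numerical choices and known limitations of `mitoquant`. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Image primitives

**Conventions.** Coordinates are 0-based with x = column, y = row. All
analyses are 2D (single optical sections or maximum-intensity
projections), matching how the quantified image data are acquired.
Areas are always reported in µm²; a pixel size must be supplied (TIFF
resolution tags or config) — there is no silent default.

**Gaussian "radius".** The smoothing radius parameter is mapped to the
kernel standard deviation in pixels (radius 2 → σ = 2 px). This matches
the parameter semantics of the originating analysis software and is the
single most consequential unit choice in the pipeline, hence stated
prominently here. Boundaries use edge replication, which conserves total
intensity to well under 0.5 % for interior-dominated images.

**Rolling-ball background.** Background is estimated as the grayscale
opening of the image by a flat disk of the given radius (default 5 px)
and subtracted with clipping at zero. The opening is always ≤ the image,
so the subtraction is non-negative before clipping. Under a 1-pixel spike
the background can be overestimated by (local slope × 1 px), because the
spike hides its own underlying value from the erosion; this bounds the
error of the "ramp + spike" case at one gray level per unit slope.

**Automatic thresholds.** Both the Yen maximum-correlation criterion and
the moment-preserving (Tsai) criterion operate on a 256-equal-width-bin
histogram spanning [min, max] of the image, regardless of source bit
depth. Foreground is *strictly above* the selected level; criterion ties
break toward the lowest qualifying level; a constant image raises a
degenerate-input error. The selection is implemented as a vectorized
search over all levels and is tested against an independently written
plain-loop exhaustive search, and (for Yen) against scikit-image to
within one bin (the two use different bin-center conventions).

**Particle analysis.** Connected components use 8-connectivity. The size
filter is strict (`area > min_area_um2`), with the default cut-off
0.15 µm², the average single-mitochondrion footprint from electron
microscopy morphometry; labels are renumbered contiguously after
filtering. Axis lengths come from the ellipse with matching second
central moments (full axes = 4·√eigenvalue of the coordinate
covariance), the convention under which a filled ellipse recovers its own
axes. Structuring disks use the "Euclidean distance ≤ r" discretization,
so binary dilation equals thresholding the Euclidean distance transform.

## Quantifications

**Accumulation ratio.** Ring = dilation of the organizer (nucleus or
spindle) mask by 10 px minus the mask; outside = cell mask minus the
dilated mask; the statistic is mean(ring)/mean(outside). "Intensity" is
interpreted as *mean per-pixel* intensity, making the ratio independent
of region sizes; the organizer interior is excluded from both regions.
Whether the original measurements background-subtracted first is
unknown; none is applied here.

**Angular non-uniformity.** The channel is Gaussian-smoothed (radius
2 px); pixels (optionally restricted to a cytoplasm mask) are binned by
polar angle about the spindle-mask centroid into six 60° sectors anchored
at the spindle long axis (orientation of the mask's equal-moment
ellipse); the statistic is the population SD of the six sector means.
The axis carries a 180° ambiguity, so sector means are meaningful as an
unordered set and the SD is the primary, order-free output. A perfectly
isotropic spindle mask has no defined axis; the tie breaks toward 0 rad
and the profile is flagged. Passing a cytoplasm mask matters in
practice: over a full rectangular frame the sector pixel populations are
systematically unequal (frame corners), which injects spurious
non-uniformity proportional to signal intensity.

**Partition measures.** symmetry index = greater/smaller (≥ 1),
inheritance ratio = smaller/greater (∈ (0,1]); both are order-invariant
and reciprocal. A zero total yields (+inf, 0) with a warning rather than
an error, so fully asymmetric simulated divisions are representable.
Cleavage-plane splitting assigns pixels by the signed side of the line;
pixels exactly on the line go to the positive side (documented
tie-break).

**ROS enrichment.** Mito channel → rolling-ball (5 px) → Gaussian
(2 px) → Moments threshold = "inside mitochondria"; outside = whole-
embryo mask minus inside; statistic = mean ROS inside / outside. When no
embryo mask is supplied it is derived as the convex hull of the Moments
threshold of the smoothed mito channel. Because the derived inside-mask
is wider than the true spot support (smoothing at σ = 2 px broadens
σ ≈ 0.6 px puncta), a planted enrichment is recovered monotonically but
attenuated — the tests assert monotonicity, not unbiasedness.

**Pixel correlation.** Pearson's r on per-pixel intensities within a
mask (≥ 10 px, both channels non-constant). Manders/overlap coefficients
are out of scope.

## Partition model

Each cluster is assigned independently to side A with probability p
(default 0.5, symmetric division; spatial bias is modeled only through
p). This independent-Bernoulli assignment is the minimal formalization
of partitioning a population of discrete carriers; it ignores spatial
correlation between neighboring clusters and any active positioning.
Masses are conserved exactly per replicate. For n ≤ 20 equal clusters an
exact binomial enumeration provides distribution and moments; the
Monte-Carlo path is tested against it at 3 standard errors. Mean
inheritance ratio is invariant to side relabeling, to p ↔ 1−p, and to
total-mass rescaling. Cluster sizes measured by `cluster_stats` (areas
in µm²) can be fed directly as masses, linking image analysis to model.

## Synthetic scenes

The generator emulates a mouse zygote imaged at 0.25 µm/px in a 512×512
field: an embryo disk of radius 40 µm, an organizer ellipse (10 × 6 µm,
a pronucleus- or metaphase-spindle-scale object) rendered in a second
channel, and mitochondrial puncta rendered as isotropic Gaussian spots
with σ = punctum_radius/2 (diffraction-limited approximation; default
punctum footprint ≈ 0.3 µm²). Spots are evaluated analytically at pixel
centers, so profiles are exact irrespective of sub-pixel position.

Placement controls, all with planted truth recorded:

- `perinuclear_enrichment f` — punctum density is f-fold higher within a
  shell around the organizer. Shell membership uses the Euclidean
  distance transform of the organizer *pixel mask* (default width
  2.5 µm = the 10-px analysis ring at default pixel size), i.e. exactly
  the geometry a ring built by mask dilation measures; with a continuum
  shell definition the recovered ratio is biased low by the half-pixel
  rim mismatch. Residual ≈ 5 % attenuation remains from PSF spill across
  the ring boundaries — a real property of any finite-resolution
  measurement — which the 10 % recovery tolerance absorbs.
- `angular_kappa κ` — punctum angles about the organizer centroid follow
  an equal mixture of von Mises distributions centered on both ends of
  the organizer long axis (concentration about an *axis*, not a
  direction); κ = 0 is uniform.
- `n_clumps` — puncta gather into clump-centered Gaussians
  (spread default 0.3 µm, contact scale, so each clump renders as one
  connected object; clump centers keep ≥ 10× spread apart so clumps
  never fuse). `n_clumps = 0` gives dispersed puncta with a hard-core
  minimum separation (default 1 µm) so that counting tests detection,
  not deblending.
- `partition_fraction` — two-cell scenes rescale the two sides of a
  vertical cleavage line so side A carries exactly the requested
  fraction of the noise-free total.

Noise is applied last: background offset/gradient, Poisson shot noise
(via a gain in ADU/photon), then Gaussian read noise, then clipping at
zero. Defaults (gain 0.25, read SD 2 ADU, offset 100 ADU) emulate a
modest confocal acquisition; `SceneParams.noise_free()` switches all of
it off for planted-truth tests. All randomness derives from one seed via
`numpy.random.SeedSequence` spawning (geometry, mito noise, organizer
noise, in that order), so channels are independently reproducible and
scenes are bit-identical across runs.

What the generator does **not** emulate: realistic PSF shape (Airy
rings, spherical aberration), depth attenuation, autofluorescence
texture, organelle shapes beyond points/clumps, or 4D time-lapse. A
green planted-truth test therefore establishes that the measurement
recovers the stated statistical structure, not that it is robust to
every real-microscopy artifact.

## Tolerances and degenerate inputs

Recovery tolerances used in tests: cluster count ±2 of 200 planted;
mean cluster area within ±50 % of the planted 0.3 µm² footprint (the
measured area of a Gaussian spot depends on where the automatic
threshold cuts the profile — the contour at the planted radius sits at
e⁻² of peak, so a factor-2 band on area corresponds to ≈ ±1 σ of cut
depth); ellipse axes and aspect ratios within 5 %; accumulation ratio
within 10 % of the planted enrichment (3-seed means, 8000 puncta for
statistical power); angular SD strictly monotone in κ in the mean over
20 replicates. Degenerate inputs raise typed errors: constant images for
thresholding, empty ring/outside regions, isotropic spindle masks
(flagged, not fatal), coincident track endpoints. CLI exit codes: 2 for
parameter errors, 3 for degenerate inputs.
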