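# Methods

`condensate-metrics` quantifies liquid–liquid phase separation (LLPS) of
protein/vesicle condensates from three kinds of evidence: fluorescence
droplet images, segmented vesicle sphere clouds from cryo-electron
tomograms, and per-residue NMR peak lists.  This note records the models,
the defaults and their rationale, and the known limitations.  Every number
quoted here is produced by the test suite or `scripts/acceptance.py`.

## Droplet imaging

**Thresholding.**  The "default" threshold is iterative intermeans (the
isodata family): on a 256-bin histogram spanning the image's min–max range,
iterate `t ← (mean_below(t) + mean_above(t)) / 2` to its fixed point,
starting from the global mean.  Because the bins span the data range, the
resulting mask is invariant under affine intensity rescaling up to binning.
Different tools' isodata dialects differ by small offsets; the bin count
(256) and the fixed-point rule are therefore part of this package's
documented contract, and the unit tests compare the histogram result
against an exact pixel-space fixed-point iteration (agreement within one
bin width).  A constant image has no threshold and raises.

**Segmentation.**  Droplets are 8-connected components of the binary mask,
filtered by area (`min_area_px`, default 4 — the size filter of particle
analysis must be tuned per dataset, so the default is deliberately
permissive) and by circularity `4πA/P²` within `[0.1, 1.0]` (the
conventional particle-analysis window that rejects debris and edges while
keeping slightly aspherical droplets).  The perimeter estimator is the
weighted boundary-pixel count (orthogonal-neighbour border pixels weight 1,
diagonal-only √2, mixed (1+√2)/2), computed with `skimage.measure.perimeter`
and replicated by an independent per-pixel loop oracle in the tests.  Note
this estimator overestimates circle perimeters by ~4% asymptotically, so
rasterized disks report circularities near 0.92–1.0 (clamped at 1.0), not
exactly 1; the filter window accommodates this.  Coordinates are 0-based,
pixel-centre, row-major.

**Statistics.**  The index of dispersion (IoD) is the sample variance
(n−1) of pixel intensities over the mean, computed per square ROI tile.
Tiles are `round(side_um·1000/pixel_size_nm)` pixels on a side — 128 px for
the 61.63 µm / 481.5 nm and 20.54 µm / 160.5 nm geometry pairs — laid out
row-major with partial edge tiles discarded.  For Poisson-limited counts a
droplet-free field has IoD ≈ 1, while droplets push it into the hundreds,
which is what makes the statistic a robust phase-separation reporter.  The
partition coefficient is the mean intensity over all droplet pixels divided
by the mean over all background pixels; no dark-level subtraction is
applied by default (an optional constant offset can be subtracted upstream)
because a correction protocol cannot be assumed.

## Phase mapping

A condition is called phase-separated when its **median** ROI IoD exceeds a
reference cutoff; dispersed when below; undetermined inside a configurable
margin (default 0, so only exact ties are undetermined).  The default
cutoff is the 99th percentile of the IoD samples of a matched no-droplet
control, which anchors the decision to the same optics and noise floor
rather than to an arbitrary absolute number.  The transition threshold is
the monotone frontier along the chosen concentration axis: the smallest
tested concentration from which every higher tested concentration also
separates.  Non-monotone label patterns log a warning and report the
smallest consistent frontier; thresholds are reported at grid resolution
since no interpolation model is justified.

Because the median is the classifier input, a valid droplet image must
have droplet signal in at least half its ROI tiles; the synthetic grid
experiment uses 12 droplets per 256 px frame (16 tiles of 64 px) for this
reason.

## Vesicle cloud statistics

Gaps are surface-to-surface: `gap(i,j) = ‖c_i − c_j‖ − r_i − r_j` in nm.
Two modes exist because the enumeration behind a published distance count
is often ambiguous (e.g. more distances than vesicles rules out plain
per-vesicle nearest neighbours): `nearest_neighbour` (default; one minimum
gap per vesicle) and `all_pairs` within a cutoff (default 20 nm, the scale
of the largest observed inter-vesicle distances).  Negative gaps flag
overlapping segmented spheres — expected in manual segmentations — and are
retained in the mean unless `exclude_overlaps` is set, since silent
exclusion would bias it.  SEM is the n−1 standard deviation over √n.  No
boundary/edge correction is applied by default.  All statistics depend only
on pairwise and centroid-relative distances and are rigid-motion invariant
to numerical precision (tested to 1e−9 nm).

The radial density profile divides the cloud into equal-width spherical
shells from a centre (default: centroid of sphere centres) to the farthest
centre and reports count per shell volume.  The outermost shell of even a
uniform packing is geometrically depleted (whole vesicles must fit inside
the region), so trend tests use interior shells.

## NMR analyses

**Intensity ratios.**  Ratios are matched by residue id (assignments are
assumed), with uncertainty propagated from each peak's signal-to-noise:
`σ = (I_n/I_d)·√((σ_n/I_n)² + (σ_d/I_d)²)`; two identical tables give
ratio 1 with σ = √2/SNR.  A peak in *either* spectrum below
`noise_multiple × noise` (default 3) marks the residue "broadened beyond
detection" and suppresses the ratio — in a titration this is the signature
of tight binding in slow exchange, and the flag is applied symmetrically
because the attenuated peak is usually in the perturbed (numerator)
spectrum.  Residues present in only one table are reported as missing, not
dropped.

**Relaxation.**  Decays are fit to `I(t) = A·e^(−Rt)` by unweighted least
squares (optional 1/σ² weights), initialised from a log-linear regression
of the positive intensities; the rate uncertainty comes from the fit
covariance.  TRACT is reduced to its analysis layer: two exponential fits
and `η_xy = (R_anti − R_trosy)/2` with quadrature-combined uncertainty —
extraction of rotational correlation times is out of scope.  The two-point
PRE rate is `Γ₂ = ln(I_dia/I_para)/Δt` with Δt = 7 ms by default;
non-positive intensities yield `None` with a reason code instead of a NaN.

## Synthetic generators

The generators define the conditions under which the pipeline is
validated; all randomness flows from one `numpy.random.Generator` per call
and identical parameters + seed are bit-identical.

* **Droplet images** — two-level fields (background 50 counts, droplets at
  `background × partition_true`) with non-overlapping disks placed by
  rejection sampling (cap 1000 tries per droplet, ≥1 px surface
  separation so ground-truth masks are unambiguous), then isotropic
  Gaussian PSF blur (default σ = 1 px) and Poisson shot noise.  Defaults:
  256 px frames at 481.5 nm/px, 5 droplets of 12 px radius,
  `partition_true` = 10 — a 10-fold enrichment at the scale where the
  full pipeline should recover it within 15%.  Blur conserves total
  intensity (reflect boundary, droplets interior) to ~1e−6 relative.  The
  generator does not model real confocal optics (no Airy PSF, no
  z-dimension), vignetting, or background gradients; passing recovery
  tests therefore demonstrates estimator correctness, not robustness to
  every real-microscope artefact.
* **Vesicle packings** — lognormal radii parameterised by arithmetic mean
  9.10 nm and sd 1.0 nm (the observed intracondensate vesicle scale);
  positions uniform in a spherical region with a per-placement gap draw
  (default exponential, mean 5 nm) enforced as the minimum surface
  separation to all previously placed spheres.  A conservative feasibility
  bound (gap-inflated packing fraction ≤ 0.3) rejects impossible requests
  up front; 2000 attempts per sphere bound the sequential search.  Because
  placement is sequential, the realized nearest-neighbour gap distribution
  sits above the draw distribution at moderate density (≈8.5 nm realized
  mean at 2000 vesicles in a 300 nm region); analyses are therefore always
  validated against realized, oracle-measured statistics, never against
  the draw parameters.  `edge_depleted` mode ramps the acceptance
  probability to zero across an outer shell to emulate the density
  fall-off toward the phase border.
* **NMR** — exact mono-exponentials plus additive Gaussian noise, and
  paired peak tables with a prescribed per-residue ratio profile and
  Gaussian noise of sd `base/SNR` (recorded as the per-peak noise
  estimate).

## Problem sizes and numerical choices

Validation runs use 16×16 masks (1000 cases) for the segmentation oracle,
20 images for partition recovery, 10 seeds × 4-point grids for threshold
recovery, 200–2000 vesicles for gap oracles (with 1718 for the radius
sampling check, matching the scale of a full tomogram segmentation), and
50 seeds for relaxation recovery — sizes at which the stochastic checks
have comfortable statistical power.  Ties and degenerate inputs:
histogram thresholding raises on constant images; IoD requires ≥2 pixels
and positive mean; partition requires a non-empty, non-full mask; gap
statistics require ≥2 spheres; a single-vesicle radial profile spans the
vesicle's own radius; exponential fits require ≥3 points and non-constant
data and report the initialisation on failure.

## Limitations

* No absolute IoD cutoff is published for the dispersed/separated call;
  the reference-percentile rule is this package's design and should be
  re-anchored per instrument via a no-droplet control.
* The perimeter/circularity dialect is fixed but not identical to any
  specific legacy tool; filters near the 0.1 circularity edge may differ
  between tools for thin objects.
* Raw experimental data for the original study are not publicly deposited,
  so recovery is demonstrated on the synthetic generators above; the
  numeric agreement of, e.g., a recovered 0.5 µM threshold or 9.1 nm mean
  radius reflects the generator conditions, not a re-analysis of the
  original images or tomograms.
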