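# Methods

This note documents the models and numerical choices behind
`plumaquant`, what the synthetic-data generator does and does not
emulate, and the known limitations of each stage.

## Coarse-grained anisotropy by Fourier transform

Each interrogation box (default 25 × 25 µm, 50% overlap; boxes are
dropped, never truncated, at the frame edge) is processed as:

1. subtract the box mean (an unremoved DC spike would dominate the
   binarised set and bias the ellipse toward isotropy);
2. multiply by a 2D Hann window (apodisation against boundary
   singularities in the FT);
3. 2D FFT, modulus, zero frequency centred;
4. binarise by keeping pixels at or above the nearest-rank 95th
   percentile of the modulus (ties retained — bit-reproducible);
5. second-moment matrix of the retained pixel coordinates about the
   zero-frequency origin, uniform weights;
6. eigendecompose; amplitude = ¼ ln(λ₁/λ₂) = ½ ln(L_maj/L_min);
7. real-space orientation = eigenvector of λ₂ (the spectrum compresses
   along the real-space elongation axis), reported in [0, π)
   counter-clockwise from the AP (row) axis.

Degenerate boxes (zero signal after mean subtraction, or fewer than 3
non-collinear retained pixels) carry amplitude 0, a NaN angle and a
flag.  Amplitude and angle are invariant under affine intensity
rescaling of the box.  Region averages use the arithmetic mean of
amplitudes ("mean bar length") and, for direction, the orientation of
the amplitude-weighted mean nematic tensor Σ aᵢ(cos 2θᵢ, sin 2θᵢ);
when that tensor's norm falls below 1e−9 of the amplitude sum
(e.g. two equal boxes at 0° and 90°) the direction is undefined.

**Operating regime.**  The top-5% binarisation retains 0.05 N² pixels
of an N-px box.  Two finite-size effects bound the usable texture
grain:

* *Isotropy null (positive bias).*  When the spectrum is much larger
  than the retained set, the retained pixels are sparse speckle maxima
  and eigenvalue repulsion inflates the amplitude.  The bias shrinks as
  the spectral envelope becomes comparable to the retained area: with a
  grain of 3 px (σ of the correlation kernel) and 64-px boxes the null
  measures ≈ 0.04, inside the ±0.05 band the estimator is specified to
  hold; with a 1.5-px grain it would be ≈ 0.07.
* *High-aspect recovery (dilution).*  Stretching compresses the
  spectrum by ρ along one axis; once the envelope's above-floor area
  falls below the retained count, the threshold descends into the
  noise/leakage floor and the measured amplitude collapses.  Larger
  boxes relax this: at 128-px boxes with a 2-px grain, the amplitude of
  stretched textures matches ½ ln ρ within ~5% for ρ up to 3 and the
  Hann-lobe broadening of the narrow spectral axis costs < 2%.

The test fixtures therefore probe the null with a 3-px grain at 64-px
boxes and the closed form with a 2-px grain at 128-px boxes — each
inside the regime where the corresponding analytic statement holds.
Real stained-tissue images are broadband (sharp membranes, filaments),
so their spectra fill Fourier space far better than the narrow-band
Gaussian model and sit comfortably inside the operating regime at the
default 25-µm boxes.

## Synthetic data

The generator supplies every fixture the pipeline is tested on; all
generators are pure functions of their spec including the seed
(bit-identical reruns).

* **Texture** — Gaussian white noise filtered by an anisotropic
  Gaussian kernel (sd `correlation_length_um` across the grain,
  ρ× that along it), scaled to mean 100 ± `texture_contrast`, plus
  optional white noise.  Chosen because its FT anisotropy has the
  closed form ½ ln ρ.  A zero-contrast scene renders a black
  background for pure-blob fixtures.  What it does *not* emulate:
  broadband cellular detail, intensity inhomogeneity, out-of-focus
  light — so passing tests calibrate the estimator, not its robustness
  to real-world artefacts.
* **Point patterns** — rows draw consecutive gaps from a normal law
  (mean `mean_spacing_um`, sd = CV × mean) truncated below at 10% of
  the mean by resampling, keeping gaps positive while the CV stays the
  single fidelity knob; hexagonal arrays jitter a perfect triangular
  lattice isotropically with σ = CV·a/√2, the small-jitter calibration
  for which nearest-neighbour distances attain the target CV.  The
  realised CV (from the actually sampled geometry) is returned as
  ground truth.
* **Blobs** — isotropic Gaussians (sd = `blob_radius_um`/2) added to
  the texture.  Ground-truth area applies the detector's own
  binarisation rule (half the mean positive value) to the isolated
  blob, so the `sub_threshold` flag predicts rejection by the
  minimum-area filter on pure-blob scenes.
* **Movies** — clean frame k+1 is clean frame k advected by the planted
  flow (semi-Lagrangian backward warp, bilinear, reflective padding);
  emitted frames add fresh Gaussian noise, so a `none` flow gives
  frames identical up to noise.  Flows: uniform drift; whole-field
  random walk (per-frame Gaussian step — a kinematic stand-in for
  undirected tissue motility); radial sink inflow v = −s·(x−c) toward
  the nearest centre (stand-in for convergent condensation, exact
  solution x(t) = c + (x₀−c)e^(−st)).  Ground truth: the analytic flow
  sampled at PIV box centres, and exact blob trajectories.  No
  mechanistic (reaction–diffusion / chemotaxis) model is simulated.

## Detection and pattern statistics

Detection keeps the `threshold_quantile` brightest pixels
(nearest-rank), Gaussian-smooths the thresholded image (σ default
10 px; the smoothing order follows the tracking variant of the
original recipe), binarises at half the mean of the retained nonzero
intensities (keeps blob footprints stable under smoothing), labels
8-connected components and applies the inclusive minimum-area filter
(default 10,000 px, the scale used on the movies the recipe was
designed for — override in µm² via the pixel size for other
magnifications).  Component centres are centroids weighted by the
smoothed intensity in excess of the binarisation level: on textured
backgrounds the binarised footprint includes a dim halo whose shape
fluctuates with the texture, and excess weighting anchors the centre
to the condensation core (≈ 1 px planted-centre error at 5:1
blob-to-texture contrast, vs ≈ 3 px for the binary centroid).

Spacing statistics use the sample (n−1) standard deviation throughout.
The Delaunay variant triangulates with Qhull after lexicographic
sorting of the input (making co-circular tie-breaks independent of
input order) and excludes every edge with an endpoint on the convex
hull *boundary* — including collinear points lying on a straight hull
edge, which Qhull does not list as vertices; on a perfect lattice patch
this exclusion is what makes the statistic exactly 0.

**Limitation — rim slivers.**  Points one layer inside a jittered
boundary can form near-degenerate sliver triangles whose long edges
(up to several lattice spacings) survive the single-layer hull
exclusion and inflate the statistic: on a 400-point jittered hexagonal
patch at CV 0.03 the full statistic reads ≈ 0.29 while trimming one
extra boundary layer recovers 0.030 vs a realised 0.030.  The row
statistic and the oracle-equivalence of the triangulation are
unaffected; for array data the statistic is best read on large
patches, where interior edges dominate, or after trimming an extra
layer.

The ROI for density counting is half-open (low edges in, high edges
out), so tiled ROIs count every centre exactly once.  Explant
retractation uses the shoelace area of simple polygons;
self-intersecting outlines are rejected.

## Time-lapse analysis

* **Registration** — per-pair integer phase correlation, accumulated
  and applied against frame 0 with edge replication.  A pair whose
  correlation peak is < 1.5× the runner-up (outside the peak's 3×3
  vicinity) is flagged low-confidence.
* **Region detection** — operates on the per-box temporal mean
  amplitude over the whole movie.  Ties: smallest starting column,
  row-major box order.  The 3×3 enlargements are centred on each
  4-box set's centroid row, forced onto the segment's middle column,
  and row-clamped into the grid.
* **Smoothing / alignment** — centred moving average (default 30
  frames) with symmetric truncation at the ends (preserves linear
  ramps exactly); NaNs are linearly interpolated on the evenly spaced
  frame grid first.  t_ref is user-supplied; an optional heuristic
  (first frame 2 baseline-sd below the P-region's pre-drop mean,
  sustained 3 frames) is provided but off by default.  Cross-movie
  aggregation averages on the intersection of aligned supports.
* **PIV** — both frames median-filtered (disk radius 2 px); 32-px
  windows, 50% overlap; zero-padded FFT cross-correlation normalised
  per lag by the windows' energies over the overlap (true NCC).  The
  normalisation matters: plain circular correlation weights each lag
  by its overlap and systematically pulls the peak toward zero on
  smooth textures, whereas the NCC peak of a purely translated pattern
  is its exact displacement (Cauchy–Schwarz).  Search is limited to a
  quarter window; subpixel refinement is a 3-point Gaussian fit per
  axis; vectors deviating from their 3×3 neighbourhood median by more
  than 2 px (either component) are replaced by that median and flagged
  (replacement-with-flag, rather than deletion, keeps region averages
  defined).  Conversion: px/frame × µm/px × 60/interval-min.
  The texture grain must be resolved but well below a quarter window;
  the 2-px-grain fixtures recover integer shifts exactly, 0.5-px
  shifts to ≈ 0.002 px in the field mean, and planted uniform flows to
  ≈ 1%.
* **Divergence** — ∂u/∂x + ∂v/∂y by `np.gradient` on the box grid
  (central differences inside, one-sided at edges; exact for linear
  fields).  Negative values = contraction/convergence.
* **Tracking** — per-frame detection, greedy nearest-neighbour linking
  on the AP coordinate only within a gate (default 1.5× the mean
  equivalent blob radius).  Unmatched detections open tracks; a track
  whose nearest in-gate detection was claimed by a nearer track ends
  there with a fusion event recorded on the survivor, so the open-track
  count drops by exactly 1 per fusion.  AP-only cost is a documented
  limitation for strongly oblique motion.

## Conventions and defaults

| Parameter | Default | Meaning |
| --- | --- | --- |
| `pixel_size_um` | 0.5 | µm per pixel |
| `box_size_um` | 25 | interrogation-box side (anisotropy) |
| `overlap_fraction` | 0.5 | box overlap |
| `threshold_quantile` | 0.30 | brightest fraction kept by detection |
| `gaussian_sigma_px` | 10 | detection smoothing (0 = off) |
| `min_area_px` | 10,000 | inclusive component-size filter |
| `frame_interval_min` | 5 | movie frame spacing |
| PIV `window_px` | 32 | interrogation window |
| `window_frames` | 30 | moving-average width (2 h 30 min) |

Axis 0 (rows) is the antero-posterior axis by default (configurable);
angles are nematic, in [0, π) from AP; pixel indices are 0-based with
pixel centres at integers and rows increasing downward.  All physical
outputs are µm, mm² and µm/h; pixel values appear only in audit
columns.  The spectrum statistic is the modulus (not the power — the
binarised set is identical either way since squaring is monotone, but
any future weighted variant would differ); window and percentile are
configurable where the underlying recipe left them open.

Problem sizes in the test suite and acceptance script (512-px null
frames, 20 seeds × 5×5 boxes for the stretch calibration, 100 point
sets for the oracle, 20 scenes for region detection, 10-frame
tracking movies) were chosen as the smallest sizes at which the
statistical claims are stable; the whole suite runs in well under a
minute of compute.
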