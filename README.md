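# plumaquant

Image-quantification toolkit for feather-primordia patterning in
developing bird skin.

During feather patterning, dermal cells condense into regularly spaced
primordia — a "dotted pattern" that arises row by row (chicken, quail,
zebra finch) or as a 2D array (emu, ostrich, penguin).  Two measurable
quantities track this process: the **regularity of primordia spacing**
(pattern fidelity) and the **coarse-grained anisotropy of cell shape**
in the dermis, which rises in competent skin before condensation.
`plumaquant` implements the full measurement chain for both, plus the
dynamic analysis of time-lapse movies of cultured skin explants — and a
synthetic-data generator that plants known ground truth so every stage
is testable without microscopy data.

## What it measures

**Cell-shape anisotropy, without segmentation.**  The image is tiled
into square interrogation boxes (25 × 25 µm, 50% overlap).  Each box is
mean-subtracted, Hann-windowed and Fourier transformed; the spectrum
modulus is binarised by keeping its 5% brightest pixels, which fills an
ellipse whose second-moment (inertia) matrix is diagonalised.  With
eigenvalues λ₁ ≥ λ₂,

&nbsp;&nbsp;&nbsp;&nbsp;*a* = ½ ln (L_maj / L_min) = ¼ ln (λ₁ / λ₂),

a dimensionless amplitude that is 0 for isotropic texture; the
real-space elongation axis is the minor axis of the spectrum ellipse (a
nematic orientation, defined modulo 180°).  For a texture affinely
stretched by a factor ρ the amplitude has the closed form ½ ln ρ — the
package's central calibration oracle.

**Pattern fidelity.**  Spacing variability = sd(neighbour distances) /
mean(neighbour distances).  Neighbours are consecutive centres in the
first formed row, or Delaunay-triangulation edges for arrays (edges
touching the convex-hull boundary are excluded).  Also: primordia
density per mm², component areas, and explant surface-area retractation
from polygon outlines.

**Primordia detection.**  Threshold-based: keep the 30% brightest
pixels, Gaussian-smooth, binarise, label 8-connected components, and
keep those of at least `min_area_px` pixels (inclusive).

**Time-lapse analysis.**  Translation drift registration (phase
correlation); automatic region detection (the competent segment is the
3 adjacent grid columns of maximal mean anisotropy; primordium /
inter-primordium regions are the 4 boxes of minimal / maximal mean
amplitude, enlarged to 3 × 3 blocks); moving-average smoothing (30
frames = 2 h 30 min at 5-min intervals) aligned on a reference time
point t_ref; particle image velocimetry (normalised FFT
cross-correlation, 3-point Gaussian subpixel fit, 3 × 3 median outlier
replacement) giving motility in µm/h; divergence of the velocity field
(negative = convergent condensation); and antero-posterior tracking of
primordia with fusion-event detection.

## Worked example

Spacing variability of a synthetic first row with planted jitter:

```python
from plumaquant import PatternSpec, generate_point_pattern, row_spacing_variability

centers, realized = generate_point_pattern(
    PatternSpec(mode="row", n_primordia=200, mean_spacing_um=100.0,
                spacing_cv=0.2, seed=3)
)
stats = row_spacing_variability(centers)
print(f"realized {realized:.4f}, measured {stats.spacing_variability:.4f}")
print(f"mean spacing {stats.mean_um:.1f} um, sd {stats.sd_um:.1f} um")
```

prints

```
realized 0.2050, measured 0.2050
mean spacing 100.9 um, sd 20.7 um
```

— the generator drew 199 gaps from a normal law with CV 0.2 (the
realisation landed at 0.205) and the measured statistic recovers it
exactly, since both reduce to sd/mean of the same gaps.

The anisotropy estimator against its closed form, from the shell: an
isotropic texture stretched ×2 should measure ½ ln 2 ≈ 0.347 at angle
0°.

```bash
$ plumaquant --pixel-size-um 0.5 anisotropy stretched.tif --box-size-um 64
5x5 boxes; mean amplitude 0.3548; mean direction 0.5 deg
```

The measured 0.355 is within 2.5% of the theoretical 0.347, and the
orientation is recovered to half a degree.  Other subcommands:
`simulate` (synthetic scenes, movies and ground-truth CSVs), `pattern`
(detection + spacing statistics), `timelapse` (regions, motility,
divergence, tracks), `retract` (explant outlines → area change).

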