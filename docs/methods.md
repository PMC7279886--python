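# Methods

This note records the models, conventions and numerical choices behind
`mcbead`, in the order the pipeline runs.

## Coordinate conventions

Stacks are `(C, Z, Y, X)` arrays with voxel centres at
`index * voxel_size` (0-indexed); all physical coordinates are
`(z, y, x)` vectors in µm, so anisotropic spacings are handled by
construction. On the sphere, θ is the polar angle from +z in (0, π) and
φ the azimuth in [0, 2π), periodic.

## Sphere fitting

Surface candidates are all membrane-channel voxels at or above the
`1 − percentile` intensity quantile (default percentile 0.005, i.e. the
upper 0.5 %; ties at the threshold included). The fit solves the
linearised sphere equation |p|² = 2c·p + d by least squares (Coope's
algebraic method) in physical µm, which is exact on noise-free samples
and translation-equivariant. The RMS of the signed normal residuals
|p − c| − R is reported as a diagnostic; a one-step geometric
(Levenberg–Marquardt) refinement of exactly that cost is available via
`fit_sphere(refine=True)` but off by default — on synthetic shells the
two agree to well under 0.05 voxel. Rank-deficient configurations
(coplanar/collinear points, < 4 points) raise.

## Surface mesh and narrow band

The particle mesh is cell-centred in θ (1.5°, 4.5°, …) and cell-edged in
φ (0°, 3°, …) at 3° default resolution (any divisor of both 180 and 360
is accepted). Cell areas use the exact formula
R²Δφ(cos θ_lo − cos θ_hi), including at the poles, so the areas
telescope to 4πR² to machine precision — domain areas and the
whole-sphere partition inherit this exactness.

The narrow band replicates each particle radially at offsets
{−5, …, +5} voxels with 1-voxel spacing. The band is symmetric about the
fitted radius so the radial maximum projection captures shell signal on
both sides of the fit (robust to small fit bias); with anisotropic
voxels the radial step is the smallest voxel edge.

## Particle–mesh transfer

Volume→particle interpolation uses the separable M4′ cubic kernel
(support ±2 voxels per axis, evaluated in voxel units per axis), which
is a partition of unity and reproduces linear fields exactly; both
properties are asserted in tests. Out-of-volume band positions are
clamped to the boundary with a warning (an all-outside band raises).

Particle→voxel scatter is a normalised (Shepard) sum. Because the 3°
mesh is sparser than the voxel grid (~2.6 voxels between particles at
the equator), the negative outer lobes of M4′ can make the Shepard
denominator vanish or change sign; the scatter therefore uses the
non-negative cubic B-spline of the same support. Voxels receiving zero
total weight are set to 0 and flagged. The interpolate→scatter round
trip on smooth fields stays below 2 % relative error inside the band.

## Mollweide maps

Maps use the standard equal-area Mollweide projection. The forward map
solves 2t + sin 2t = π sin(lat) by Newton iteration (tolerance 1e−7,
≤ 50 iterations, closed form at the poles); rendering inverts the
projection per pixel (closed form) and fills from the nearest mesh cell.
Pixels outside the ellipse are NaN; a JSON sidecar records the
lat/lon→pixel transform.

## Rolling-ball background correction

Background is the grayscale opening of the lat–lon raster with a disk
footprint whose radius is the physical ball radius (default 2 µm)
divided by the equatorial cell arc R·Δφ. Two topology details matter:

- the azimuthal axis is padded periodically;
- the polar axis is padded *across the pole*: row −1 of the raster is
  row 0 rotated by 180° in φ. With edge-replication padding instead, a
  domain sitting near a pole is mistaken for a wide background plateau
  and subtracted away; the spherical padding fixes this.

Both pads extend 2× the footprint radius (the full reach of
erosion-then-dilation). A ball radius below one raster cell degrades to
a warned no-op. The footprint is flat (a disk), i.e. the background is a
morphological opening rather than a sliding ball of matched intensity
units; for the shallow backgrounds of bead surfaces the difference is
negligible and the flat variant is parameter-free.

## Two-phase segmentation

Domains are segmented by minimising the piecewise-constant two-phase
energy

    E(u) = Σ u (c₁ − f)² + (1 − u)(c₀ − f)² + λ TV(u),  u ∈ [0, 1]

on the min–max-normalised, `oversampling`-times bilinearly refined
raster (periodic in φ). The levels c₀, c₁ are re-estimated exactly
(u-weighted means) in an outer loop; the u-subproblem, which is convex
and globally solvable, is handled by a Chambolle–Pock primal–dual scheme
(dual ball of radius 1, steps τ = σ = 1/(2λ√ndim) so that
τσ‖λ∇‖² = 1) warm-started across outer iterations; u is initialised by
thresholding the normalised raster at 0.5. The energy trace is asserted
non-increasing: if an inexact inner solve fails to improve on the warm
start it is retried with more iterations and, failing that, the previous
indicator is kept and the solve stops. The TV weight scales with the
refinement factor so the continuum energy is resolution-independent.

The relaxed indicator is thresholded at 0.5; components are labelled
with 8-connectivity (26 in 3D), merged across the φ seam, and filtered:

- components with mean normalised intensity below `min_object_intensity`
  (default 0.3) are discarded;
- components covering more than `max_object_area_fraction` (default
  0.25) of the raster are discarded. A near-global "object" is the
  degenerate solution the model produces on structure-free input, where
  min–max normalisation stretches noise over [0, 1]; this guard is what
  makes flat or noise-only surfaces — including beads whose only
  structure is a low-dye membrane inhomogeneity — report zero domains.

Defaults (regularization 0.35, minimum object intensity 0.3, 4-fold
oversampling) follow the published analysis settings. Two routes exist:
the default fast route segments the corrected surface raster directly;
the fidelity route scatters band intensities back to a clean 3D pixel
image and segments in 3D with the same solver (26-connectivity, no
oversampling), with domain meshes triangulated by marching cubes and
particles assigned by a generalized-winding-number point-in-mesh test.
Note the segmentation input convention: the model expects the
*background-corrected* field; on raw fields the min–max normalisation
compresses the object/background contrast and dim domains may merge into
the background phase.

## Quantification conventions

- Domain area = sum of exact cell areas of its particles (µm²).
- Equivalent diameter = √area. This convention reproduces every printed
  area/diameter pair of the reference summary tables (e.g. √1.74 → 1.32,
  √2.52 → 1.59) and is therefore adopted as the tables' definition; a
  circular-equivalent diameter 2√(area/π) is available behind a flag.
- "Mean intensity/bead" and the in/out-of-domain means are computed on
  the radially projected *raw* surface field (before rolling-ball
  subtraction), matching the arbitrary-unit scale of the reference
  tables; the corrected field is exported alongside.
- Condition tables report mean domains/bead as the exact ratio of
  totals; the asymmetric area spread "central −a/+b" is reported as
  central minus the 5th percentile and 95th percentile minus central
  (the statistic behind the printed spreads is not defined in the
  source; percentiles are this package's choice and are configurable).
- Per-domain intensities average particles within a domain first, then
  across domains.
- Table export rounds half-even to 2 decimals.

## Colocalization, profiles, tracking, FRAP

nMDP is computed per particle from the two protein channels of the same
bead; it is 1 at a joint channel maximum, 0 where either channel equals
its mean, and invariant to affine rescaling of either channel (tested to
1e−9). Constant channels raise (zero denominator).

The equatorial profile samples an annulus of width 10 pixels centred on
the fitted radius in the z-slice through the bead centre (the manual
FIJI-style analysis), reporting per-degree raw protein and membrane
intensities and their pixelwise protein/DiD ratio (defined where
DiD > 0). Group comparisons use the classic pooled-variance unpaired
t-test (Welch behind a flag).

Tracking links per-frame domain records greedily by nearest geodesic
centroid distance under a 1 µm cap (domain counts are ~5/bead, so the
Hungarian algorithm would change nothing); there is no gap closing — a
domain that disappears and reappears starts a new trajectory. FRAP
recovery normalises post-bleach trajectory intensities to the pre-bleach
mean and reports the mean of the last 3 frames as plateau, plus the
fraction of post-bleach domains whose centroid lies within the cap of a
pre-bleach centroid ("same-location" recovery).

## Synthetic data

The generator emulates the study system: a spherical membrane shell of
radius R (default 5 µm; 0.1 µm isotropic voxels in a 160³ stack) with a
Gaussian radial profile of width `shell_sigma` (default 0.15 µm)
standing in for the axial PSF; N spherical-cap domains (default five of
1.74 µm², the reference mean) with in-cap protein intensity exactly
`baseline_out × enrichment` on the shell (default 3×, the low end of the
reported per-condition enrichments); optional co-enriched channel B;
dark membrane patches (reduced dye, protein unchanged) emulating the
bilayer inhomogeneities that must not be called domains; additive
Gaussian noise then optional Poisson resampling (order fixed). Domain
centres are drawn uniformly in area with a geodesic `min_separation`
(default 2.5 µm, reflecting that reported domains rarely touch) by
rejection sampling, erroring after 10 000 tries. All randomness flows
from one seed through named substreams (placement, noise, per-frame), so
identical parameters are bit-identical. The recovery suite uses
`noise_gaussian_sigma = baseline/10`, i.e. SNR 10 against the
membrane-proportional baseline signal.

Time-lapse sequences keep domain geometry fixed and scale the domain
contrast by a per-frame growth profile (effective enrichment
1 + (enrichment − 1)·profile_t); a photobleach multiplies channel A by
`bleach_factor` at the bleach frame and recovers exponentially (time
constant `recovery_tau` frames) toward `recovery_plateau` at the same
locations, emulating recovery driven by exchange with the soluble pool.

What the generator does not model: realistic confocal PSFs (only the
radial shell blur), lipid-phase behaviour, domain nucleation/motion
dynamics, bead-to-bead membrane variability, or camera offsets. Passing
the recovery suite therefore demonstrates correctness of the geometry,
transfer, correction, segmentation and measurement chain under
controlled noise — not performance on every real acquisition artefact.

## Problem sizes and determinism

Unit tests run on 64³ stacks (R = 2.2 µm beads); the recovery suite uses
twenty 160³ beads with five domains each, the geometry of the study
system. Every operation downstream of the generator is deterministic
given its inputs; pipeline runs write a manifest (package and library
versions, config hash, seed) sufficient to reproduce any output
byte-for-byte.

## Known limitations

- The lat–lon raster oversamples the poles; segmentation and rolling
  ball operate in cell space, so physical-scale guarantees are weakest
  in the two polar rows (the across-pole padding removes the worst
  failure mode).
- The rolling-ball footprint is a flat disk, not an intensity-matched
  ball.
- Components are merged across the φ seam but not across the poles; a
  domain centred exactly on a pole may split into two labels in rare
  configurations.
- `min_object_intensity` is interpreted against the min–max-normalised
  range of the corrected field; the original tool's internal scaling is
  not public, so this is a documented assumption.
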