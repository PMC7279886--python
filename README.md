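# mcbead

Quantification of µm-scale protein domains on the surface of
membrane-coated beads (MCBs) from 3D confocal stacks.

Membrane-coated silica beads — ~10 µm microspheres carrying a supported
lipid bilayer — are a standard spherical model membrane for in vitro
reconstitution of peripheral membrane-protein organisation, e.g. the
patterning of the small GTPase Rab5 into discrete membrane domains by its
GEF/effector machinery. Quantifying those domains requires mapping a 3D
multi-channel stack (protein channels at 488/561 nm, membrane dye DiD at
660 nm) onto the bead's spherical surface and measuring segmented
structures in geodesic units. `mcbead` implements that pipeline end to
end, together with a synthetic bead-image generator with exact ground
truth, so every stage is testable without microscopy data.

## Pipeline

1. **Sphere fit** — the brightest 0.5 % of membrane-channel voxels are
   taken as surface points and the bead is fitted by linear least squares
   on the algebraic sphere equation |p|² = 2c·p + d (centre c, radius
   R = √(d + |c|²)), with the RMS of the normal residuals |p − c| − R as
   diagnostic.
2. **Surface resampling** — particles on a 3° × 3° latitude–longitude
   mesh (60 × 120 = 7200 particles, exact cell areas
   R²Δφ(cos θ_lo − cos θ_hi)) are replicated radially into a narrow band
   of ±5 voxels at 1-voxel spacing; volume intensities are interpolated
   to the band with the moment-conserving M4′ cubic kernel and
   maximum-projected radially.
3. **Background correction** — a rolling-ball (grayscale opening) filter
   of 2 µm radius removes uneven background in the bead tangent space.
4. **Segmentation** — domains are segmented with a convex-relaxed
   two-phase piecewise-constant model (boundary-length regularization
   0.35, minimum object intensity 0.3 of the normalised range, 4-fold
   sub-cell oversampling), solved globally by a primal–dual method.
5. **Quantification** — per-domain geodesic area (sum of exact cell
   areas), equivalent diameter √area, per-bead and per-condition
   statistics (domains/bead, mean ± SD intensities inside/outside
   domains) in the standard summary-table schema.
6. **Colocalization & dynamics** — per-particle normalized mean
   deviation product nMDP = (Aᵢ−Ā)(Bᵢ−B̄)/((A_max−Ā)(B_max−B̄)),
   equatorial ring profiles with pixelwise DiD normalisation, unpaired
   t-tests, greedy geodesic domain tracking across time-lapse frames and
   FRAP recovery analysis. Whole-surface fields are rendered as
   equal-area Mollweide maps.

## Worked example

```python
from mcbead import SynthParams, generate_bead_stack, analyze_bead

params = SynthParams(n_domains=5, noise_gaussian_sigma=10.0,
                     n_dark_patches=2, rng_seed=1)
volume, truth = generate_bead_stack(params)   # 160^3 stack, R = 5 um bead
result = analyze_bead(volume)

print(f"domains: {result.stats.n_domains}")
print(f"total domain area: {result.stats.total_domain_area_um2:.2f} um^2 "
      f"(painted: {sum(c.area for c in truth.domains):.2f})")
print(f"in/out intensity ratio: "
      f"{result.stats.mean_intensity_domains / result.stats.mean_intensity_outside:.2f}")
```

prints

```
domains: 5
total domain area: 8.61 um^2 (painted: 8.70)
in/out intensity ratio: 2.96
```

i.e. the pipeline recovers all five simulated 1.74 µm² domains, their
summed geodesic area within 1 %, and the simulated 3× enrichment of
protein signal inside domains within 2 %, at a membrane signal-to-noise
ratio of 10. The same chain is exposed on the command line
(`mcbead simulate`, `mcbead fit-sphere`, `mcbead project`,
`mcbead segment`, `mcbead run`).

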