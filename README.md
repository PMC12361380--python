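# ooquant

Quantification pipeline for multi-channel confocal imaging of human
cumulus–oocyte complexes (COCs): organelle activity readouts and spatial
organelle-distribution profiling in immature (GV) and mature (MII) oocytes,
with the surrounding somatic cumulus cells as an internal reference.

Human oocytes are large (~115 µm) spherical cells whose lysosomes,
proteasomes and mitochondria redistribute during maturation: organelles
cluster around the nucleus in GV oocytes, leaving an organelle-free zone
below the cortex, and disperse (mitochondria) or stay centrally clustered
(lysosomes) in MII eggs. `ooquant` turns calibrated image stacks of such
cells into reproducible numbers:

- **Geometry & segmentation** — size-based separation of the single large
  oocyte from the ~10 µm cumulus cells, equatorial best-fit ellipse
  (diameter readout = major axis), TMRE-based viability filtering of
  cumulus cells.
- **Radial profiling** — reslicing along 360 rays at 1° steps from the
  fitted centre, average projection, equatorial-band averaging, per-curve
  min–max normalization, and cohort averaging (mean ± SD at each distance).
- **Breakpoint regression** — the spatial distribution summary. A
  continuous two-segment linear model is fitted to each mean
  intensity-versus-distance curve,

  `y = a + b₁·x + (b₂ − b₁)·(x − ψ)₊`,

  by iterative linearisation: at a working breakpoint ψ₀, regress y on
  {1, x, (x − ψ₀)₊, −1[x > ψ₀]} and update ψ by the ratio of the last two
  coefficients, with a local exact-RSS polish at convergence. The breakpoint
  ψ (µm) gets a delta-method standard error and a 95% Wald interval;
  conditions are compared by CI overlap. An exhaustive grid-search
  estimator serves as an independent oracle.
- **Intensity statistics** — whole-oocyte means from maximal-Z projections,
  per-donor normalization to a reference-group median (GV oocytes or
  cumulus cells), per-slice oocyte-vs-cumulus comparisons restricted to
  slices containing both compartments, paired before/after treatment
  ratios, and unpaired Welch t tests.
- **Membrane & aggregates** — plasma-membrane peak intensity from the
  radial profile (lysosomal exocytosis readout), rim-excluded cytoplasmic
  mean, and detection/counting of bright refractile bodies (enlarged,
  aggregate-containing lysosomes) with per-body marker positivity.
- **Synthetic COCs** — a ground-truth scene generator (stage-dependent
  radial organelle densities, Gaussian PSF, Poisson + read noise, donor
  effects, cumulus ring, planted bodies and breakpoints) so that every
  stage of the pipeline is testable without donated-oocyte data.

## Worked example

```python
import ooquant as oq

# GV-like complex with a 30 µm perinuclear organelle cluster and a planted
# oocyte:cumulus mean-intensity ratio of 0.5 (coarse 1.5 µm voxels).
truth = oq.gv_like_scene(seed=1, pixel_size_um=1.5, psf_sigma_um=1.2,
                         oocyte_to_cumulus_ratio=0.5)
stack, resolved = oq.simulate_oocyte_stack(truth)

regions = oq.segment_cells(stack, "lysotracker")
oocyte = next(r for r in regions if r.cell_type == "oocyte")
print(f"segmented {sum(r.cell_type == 'cumulus' for r in regions)} cumulus "
      f"cells, 1 oocyte of diameter {oq.oocyte_diameter(oocyte):.1f} um")

profile = oq.normalize_profile(
    oq.extract_radial_profile(stack, oocyte, "lysotracker"))
fit = oq.fit_segmented(profile.distances, profile.normalized)
print(f"breakpoint psi = {fit.psi:.2f} um "
      f"(95% CI {fit.ci95[0]:.2f}-{fit.ci95[1]:.2f})")

ratio = oq.oocyte_vs_cumulus(stack, regions, "lysotracker")
print(f"oocyte/cumulus mean-intensity ratio: "
      f"{ratio['oocyte'] / ratio['cumulus']:.2f} "
      f"(planted: 0.50, from {ratio['n_slices']} shared z-slices)")
```

prints

```
segmented 10 cumulus cells, 1 oocyte of diameter 115.6 um
breakpoint psi = 16.93 um (95% CI 13.74-20.12)
oocyte/cumulus mean-intensity ratio: 0.50 (planted: 0.50, from 5 shared z-slices)
```

The diameter and compartment ratio recover the planted truth. The
breakpoint summarises where the radial curve changes slope: for this
clustered GV-like cell the fitted kink sits between the dark nuclear region
and the cluster plateau; MII-like cells with dispersed organelles break
much further out, so GV and MII cohorts separate cleanly by their
breakpoint CIs.

A thin CLI mirrors the library:
`ooquant simulate | segment | profile | fit-breakpoint | count-bodies`.

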