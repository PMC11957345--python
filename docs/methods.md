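# Methods

## The measurement problem

Myelin blisters — focal detachments of the myelin sheath, enriched in the
normal-appearing white matter of MS donors — appear in THG z-stacks as
near-spherical dark cavities wrapped in a bright myelin wall. The pipeline
turns raw 8-bit frame sequences into a density of such objects per mm³ of
imaged tissue and compares groups (MS vs non-MS; [Na⁺] steps 125 → 133 →
140 mM as a within-donor factor; ALLN pre-incubation as an intervention
arm).

## THG signal model (`optics`)

For a Gaussian beam focused into a medium spanning `z1…z2`, the generated
third-harmonic intensity is

    I_3ω = (3ω / (2 n_ω c))² |χ⁽³⁾|² I_ω³ · |J|²,
    J = ∫_{z1}^{z2} e^{iΔk z} / (1 + 2iz/b)² dz,
    Δk = n_3ω·3ω/c − 3 n_ω·ω/c = (6π/λ)(n_3ω − n_ω).

All lengths are µm and `c = 1`, so intensities are arbitrary units; the
geometric ratios (bulk vs interface, slab scaling, |χ³|² and I_ω³ laws) are
exact. `J` is evaluated by adaptive quadrature split at the focus; infinite
limits are truncated at |2z/b| = 10⁴, where the 1/z² tail bound is below
1e-8 of the half-space value. Two analytic anchors are enforced by tests:
the infinite homogeneous medium at Δk = 0 gives J = 0 (Gouy cancellation —
the reason THG is interface contrast), and the half-space gives |J| = b/2.

Resolution is estimated as in the instrument characterization: an intensity
profile across a sharp edge is differentiated by central differences into a
line-spread function and fitted with offset + amplitude Gaussian by least
squares; FWHM = 2√(2 ln 2)·σ. A direct half-maximum interpolation is
available as `method="halfmax"`. The instrument's measured widths, 0.4 µm
lateral and 1.3 µm axial, are module constants reused as the synthetic
renderer's PSF. The estimator refuses profiles whose LSF peak is below 3×
the tail noise.

## Synthetic white matter (`synthetic`)

The generator emulates what the detection chain actually sees, not the
physics of image formation (no wave-optics rendering):

- **Axons**: straight tubes, orientation within ±30° of one lateral axis
  (tract alignment), Poisson count at 150 axons per (100 µm)² of
  cross-section; sheath outer radius N(1.2, 0.2) µm, wall thickness
  N(0.5, 0.1) µm. Sheath voxels render bright (0.90), axoplasm intermediate
  (0.45), extracellular background dark (0.15) on a [0, 1] scale.
- **Swellings**: Poisson(density × volume) cavities centred on randomly
  chosen sheaths; the *cavity* radius is the sampled size (N(1.8, 0.4) µm,
  clipped to 1–4 µm) rendered dark (0.05) inside a bright 0.8 µm myelin
  wall. Defining the planted radius as the cavity radius makes ground truth
  directly comparable to what hysteresis detection measures and keeps every
  planted object above the 1 µm minimum-diameter filter. A fixed-count mode
  exists for exact-recovery tests. The MS and non-MS presets carry the
  published group densities (3.17×10⁵ and 0.64×10⁵ per mm³) with their
  printed ± spreads (interpreted as SD by default; a switch reads them as
  SEM, since the source does not say).
- **Distractors**: dark cell-body holes (5×10⁴ per mm³, N(3.0, 0.8) µm) and
  small bright lipid bodies (2×10⁴ per mm³), both carved only out of
  background so they never sever a sheath.
- **Depth attenuation**: multiplicative exp(−z/ℓ) with ℓ_WM = 60 µm <
  ℓ_GM = 120 µm — the qualitative ordering seen in tissue (values are
  conventions, configurable).
- **Noise**: Gaussian-approximated shot noise (variance = 0.005 × mean,
  i.e. a ~200-photon full scale) plus additive read noise (sd 0.01),
  clipped and quantized to 8 bits.
- **Time lapse**: swelling radii grow linearly; the whole scene drifts
  laterally at a constant velocity, rendered analytically at exact
  sub-pixel offsets; noise is independent per frame. Ground truth records
  per-timepoint centers, radii, label volumes, densities and applied
  drifts.

What this does *not* emulate: curved/branching axons, partial-volume
texture of real neuropil, vasculature, spatially varying scattering, and
lumen/cavity intensity overlap. Passing recovery tests therefore shows the
chain is correct and self-consistent at realistic contrast, size and noise
scales — not that the classifier generalizes to arbitrary tissue.

## Processing chain (`preprocess`, `classify`, `detect`)

Registration estimates per-timepoint translation by phase-normalized
cross-correlation of maximum-intensity z-projections against timepoint 0,
refined to 0.1 px by Fourier upsampling, and corrects by bilinear sub-pixel
interpolation with replicated edges (plain cross-correlation is biased low
by overlap truncation — measurably so on planted drifts — hence the phase
normalization). Timepoint selection takes the nearest acquisition to
30/90/150/160 min, ties toward earlier.

Inversion (255 − v) makes non-myelin bright. The median filter is a
radius-2 disk applied per z-slice with reflected borders (the toolchain
convention for "2 px"; a 3D ball variant is exposed). CLAHE is implemented
exactly as specified — per-slice tiles (default 64 px), 256-bin histograms
clipped at clip_limit × tile_pixels/bins (default 0.01) with uniform
redistribution, per-tile equalization mappings blended bilinearly between
tile centers — because library implementations differ in tiling and
interpolation conventions and the tests pin these semantics to a
hand-computed oracle. 2D-per-slice processing is assumed throughout (the
axial PSF is 3× the lateral one, so slices are the natural unit).

The pixel classifier is a 100-tree random forest (bootstrap, √d features
per split, mandatory seed) over a 25-channel bank: Gaussian-smoothed
intensity, gradient magnitude, Laplacian of Gaussian, and the two 2D
Hessian eigenvalues at scales {0.7, 1.0, 1.6, 3.5, 5.0} px. Training
annotations are sparse voxel scribbles; for synthetic scenes they are
sampled from the ground-truth labels (sheath/axoplasm/lipid → "signal",
background/cavity/hole → "non-myelin"), standing in for the interactive
annotation step. The output is the mean tree probability of "non-myelin".

Detection thresholds the probability map with hysteresis: 26-connected
components of {p ≥ 0.5} that contain a core voxel {p ≥ 0.85}. Components
are measured in physical units; surface area comes from a marching-cubes
mesh at the 0.5 isolevel with the acquisition's voxel spacing, giving
sphericity ψ = π^(1/3)(6V)^(2/3)/A. Accepted swellings satisfy
equivalent diameter ∈ [1, 15] µm and ψ ≥ 0.6; the sprawling
extracellular-space component and elongated lumen fragments fail one or
both. Density = accepted count / (fov_y × fov_x × n_z × Δz). Objects
touching borders are kept by default; `exclude_border_px` can suppress
border seeding for drift-robustness studies. Note the mesh slightly
under-estimates the area of voxel-thin structures (diamond cross-section),
so very short 1-voxel filaments score ψ ≈ 0.64; real rejected structures
are far longer and score well below the 0.6 rule.

## Statistics (`stats`)

`t_sf`/`f_sf` accept fractional degrees of freedom (regularized incomplete
beta). The mixed-design ANOVA decomposes donors × levels with a between
factor: between-subject SS splits into group and donor-within-group;
within-subject SS into level, group × level and residual. The
Greenhouse–Geisser ε comes from the pooled within-group covariance S of
the level scores,

    ε = k²(s̄_d − s̄)² / ((k−1)(ΣΣ s_ij² − 2k Σ r_i² + k² s̄²)),

clipped to [1/(k−1), 1]; both the within main effect and the interaction
are reported with dfs ε(k−1) and ε(k−1)(N−g). ε = 1 exactly under compound
symmetry. The correction raises p in the F ≥ 1 regime that matters for
inference; for F ≲ 1 shrinking both dfs can lower p slightly, so
"corrected ≥ uncorrected" is only asserted for clearly non-null F. All
p-values are two-tailed; no multiplicity correction is applied (matching
the analysis this reproduces). The published baseline df of 5 for n = 5 vs
6 matches neither pooled (df 9) nor Welch (≈4.3) construction; both
variants are provided (default pooled, consistent with the df = 18 ALLN
comparison, which pools donors × timepoints) and the ambiguity is simply
documented.

## Problem sizes and reproducibility

The recovery experiment simulates one 100×100×20 µm volume per donor
(250×250×50 voxels at 0.4 µm), 5 MS + 6 non-MS donors, trains one
classifier on a separate MS-preset scene (400 annotations per class) and
applies it to all donors — the train-once workflow of interactive tools.
This size keeps a full run within minutes per volume on one CPU while
holding ~60 (MS) and ~13 (non-MS) planted objects per volume, enough for
group means to be dominated by detection fidelity rather than Poisson
noise. Unit tests use 40×40×10 µm scenes for speed. Every stochastic stage
takes an explicit seed; identical configs reproduce outputs bit-for-bit.

## Known limitations

- Two-class pixel classification cannot distinguish dark round cell bodies
  from blister cavities by intensity alone; the generator's holes merge
  with the background component (as real holes merge with extracellular
  space), so they are rejected by the roundness/size rules rather than by
  class. Heavily myelin-free fields would need a third class.
- Registration is translation-only; rotation or tissue deformation is out
  of scope.
- Densities use the full imaged volume as denominator (no tissue masking).
- The optics module models the axial Gouy integral, not 3D image
  formation; the measured 0.4/1.3 µm widths include instrument aberrations
  and are inputs, not predictions.
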