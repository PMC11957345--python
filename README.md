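# thgswell

Label-free quantification of myelin swellings in third-harmonic-generation
(THG) microscopy z-stacks of human white matter.

THG microscopy images myelin without dyes: three excitation photons (here at
1050 nm) combine into one photon at a third of the wavelength, a process
that vanishes in homogeneous media because of the Gouy phase slip across the
focus and therefore lights up interfaces — above all the lipid-rich myelin
sheaths. In multiple sclerosis, normal-appearing white matter carries focal
detachments of the sheath from its axon ("myelin blisters" or swellings),
and their density per mm³ is a quantitative readout of subtle myelin
pathology. This package implements the full analysis chain for such
acquisitions:

1. **I/O** — 8-bit grayscale BMP frame sequences and multi-page TIFF stacks
   with acquisition geometry (FOV, pixel grid, z-step, frame period), plus
   per-frame histogram normalization (`thgswell.io`);
2. **Preprocessing** — phase-correlation drift registration, analysis
   timepoint selection (30/90/150/160 min), intensity inversion, 2 px
   median filtering, contrast-limited adaptive histogram equalization
   (`thgswell.preprocess`);
3. **Probability mapping** — a sparsely annotated random-forest pixel
   classifier over a multiscale 2D filter bank that yields a per-voxel
   "non-myelin" probability (`thgswell.classify`);
4. **Detection** — hysteresis thresholding of the probability map
   (core 0.85, final 0.5, 26-connectivity), size filtering, and a roundness
   rule based on mesh sphericity ψ = π^(1/3)(6V)^(2/3)/A ≥ 0.6; accepted
   objects are counted into a density per mm³ (`thgswell.detect`);
5. **Statistics** — two-sample t-tests, one-way ANOVA, and mixed
   repeated-measures ANOVA over [Na⁺] levels with the Greenhouse–Geisser
   correction (fractional degrees of freedom) (`thgswell.stats`);
6. **Optics** — the focused-beam THG intensity model
   I ∝ |∫ e^{iΔkz}/(1+2iz/b)² dz|² with Δk = (6π/λ)(n₃ω − nω), and the
   edge-spread-function resolution estimator (ESF → LSF → Gaussian-fit
   FWHM) (`thgswell.optics`);
7. **Synthetic data** — a white-matter scene generator (bright tubular
   sheaths, dark lumens and cell holes, lipid bodies, planted near-spherical
   swellings, depth attenuation, shot/read noise, stage drift) with exact
   voxel-level ground truth, so the whole pipeline is testable without
   tissue data (`thgswell.synthetic`).

## Worked example

Simulate one 40×40×10 µm white-matter volume at the MS-preset swelling
density, train the pixel classifier on synthetic sparse annotations, and
run the full detection chain:

```python
from thgswell.io import AcquisitionGeometry
from thgswell.synthetic import MS_PRESET, simulate_timelapse
from thgswell.pipeline import (PipelineConfig, train_classifier_on_truth,
                               quantify_stack)

geometry = AcquisitionGeometry(fov_um=40.0, grid_px=100, z_step_um=0.4)
stack, truth = simulate_timelapse(MS_PRESET, geometry, 25, [0.0], seed=7)
model = train_classifier_on_truth(stack, truth, seed=8, n_per_class=200)
cfg = PipelineConfig(seed=0, fov_um=40.0, grid_px=100, z_step_um=0.4, n_z=25)
sset = quantify_stack(stack, model, cfg, timepoints=[0])[0]
print(f"planted density : {truth.true_density_per_mm3[0]:.3g} per mm^3")
print(f"detected density: {sset.density_per_mm3:.3g} per mm^3 "
      f"({len(sset.accepted)} accepted of {len(sset.objects)} candidates)")
```

prints

```
planted density : 3.75e+05 per mm^3
detected density: 3.12e+05 per mm^3 (5 accepted of 6 candidates)
```

i.e. five of the six planted blisters in this small volume are recovered as
round non-myelin objects (the sixth sits against the volume border); the
rejected candidate is the sprawling extracellular-space component. The
analytic statistics reproduce the published p-values, e.g.
`t_sf(1.921, 6)` → `0.1031` and `f_sf(2.978, 1.196, 7.173)` → `0.1248`.

A command-line interface mirrors the library (`thgswell simulate`,
`preprocess`, `classify`, `detect`, `stats`, `run`, `optics`,
`resolution`); see `thgswell --help`.

## Layout

```
src/thgswell/     io, synthetic, optics, preprocess, classify, detect,
                  stats, pipeline, cli
tests/            pytest suite (unit, property and acceptance tests)
docs/methods.md   model, parameter and design notes
scripts/          acceptance.py
```
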