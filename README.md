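# nucleostrain

Probe-free chromatin deformation analysis for live-cell fluorescence
microscopy.

When a scanned IR laser imposes a localized temperature gradient on a
living cell, intra-nuclear chromatin is displaced by up to ~2 µm within
seconds and relaxes back when the stimulus ends. Because every chromatin
pixel carries a fluorescent reporter (e.g. mCherry-H2b), the chromatin
itself is the probe: dense displacement fields can be computed directly
from the image texture, without beads or tracer particles. `nucleostrain`
implements the full analysis chain for such recordings, for cell
biologists and biophysicists who want strain-resolved chromatin mechanics
from a standard spinning-disk time lapse:

- **thermometry** — dye-intensity → temperature conversion (mCherry loses
  ~1.3 %/°C), smooth spatial profile fits and analytic, noise-robust
  gradient estimates;
- **piv** — multi-pass windowed cross-correlation against the undeformed
  t = 0 frame (32 → 16 px windows, 75 % overlap, 4 px final grid, 3-point
  Gaussian sub-pixel peak, global/local/SNR vector filters);
- **strain** — hydrostatic ε_h = (∂u/∂x + ∂v/∂y)/2 and engineering shear
  ε_s = ∂u/∂y + ∂v/∂x maps from the vector grid, upsampled to pixel
  resolution;
- **compartments** — nucleus segmentation, 6 px lamina-rim exclusion,
  seven equi-volumetric chromatin-density classes C1…C7, nucleolus masks
  and 0.5 µm perinucleolar shells PC1–PC3, CHC extraction;
- **kinetics** — image-difference series, feature/CHC tracking,
  kymographs, nuclear-border rigidity profiles, fiber-strain estimates,
  and a statsmodels-style Kelvin-Voigt model
  (`KelvinVoigtModel(series).fit()` → results with `summary()`/`plot()`):
  creep ε(t) = (1/E)(1 − e^(−t/τ_c)), recovery ε(t₁)e^(−t/τ_r), τ = η/E;
- **stats_report** — compartment-resolved absolute/total strain tables,
  shell displacement tables, one-way ANOVA + Tukey HSD, binned t-tests;
- **phantom** — a synthetic nucleus generator with *analytic* displacement
  and strain ground truth (Kelvin-Voigt time course, exponential spatial
  decay, immobile/mobile nucleoli, rigid CHC, static border, camera
  noise), used to validate every stage.

See `docs/methods.md` for the model details and numerical choices.

## Worked example

Analyze a rendered phantom end to end (a real recording would be loaded
with `ImageStack.from_tiff`):

```python
import numpy as np
from nucleostrain import PhantomSpec, RunConfig, render_sequence, run_pipeline

spec = PhantomSpec(image_shape=(128, 128), nucleus_radius_um=6.5,
                   amplitude_um=1.0, seed=4)
frames = [0, 20, 40, 60, 79] + list(range(80, 120)) + list(range(121, 240, 7))
stack, truth = render_sequence(spec, frame_indices=frames)

result = run_pipeline(RunConfig(output_dir="demo_out"), stack=stack)
print(result.strain_table.round(4).to_string(index=False))
kv = result.kv_params
print(f"tau_c = {kv.tau_c:.3f} s   tau_r = {kv.tau_r:.3f} s   "
      f"plateau = {kv.creep_amplitude:.3f} um")
```

prints

```
 nucleus compartment  n_pixels  abs_hydrostatic  total_hydrostatic  abs_shear  mean_displacement_um
       0          C1       982           0.0301            -0.0301     0.0125                0.3513
       0          C2       982           0.0333            -0.0333     0.0132                0.3638
       0          C3       982           0.0353            -0.0353     0.0125                0.3669
       0          C4       981           0.0370            -0.0370     0.0139                0.3854
       0          C5       982           0.0364            -0.0363     0.0129                0.3712
       0          C6       982           0.0371            -0.0371     0.0125                0.3810
       0          C7       981           0.0355            -0.0355     0.0122                0.3771
       0         NLL         0              NaN                NaN        NaN                   NaN
tau_c = 0.734 s   tau_r = 0.927 s   plateau = 0.377 um
```

Reading it: the interior was split into seven equal-count density bins
(~982 px each); at peak deformation each bin experienced ~3–4 % absolute
hydrostatic strain (strains are relative, 1 = 100 %). Total and absolute
coincide in sign here because this phantom's exponential field compresses
everywhere; volume-preserving fields instead give totals near zero while
absolutes stay finite. No stain channel was provided, so the nucleolus row
is empty and shell statistics are skipped with a logged notice. The
Kelvin-Voigt fit of the mean PIV displacement recovers the phantom's
generating time constants (0.74 s creep, 0.92 s relaxation) to ~1 %.

A CLI mirrors the library: `nucleostrain phantom`, `nucleostrain run
--config run.toml`, `nucleostrain thermo-calibrate`, `nucleostrain
thermo-profile`, `nucleostrain kv-fit`.

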