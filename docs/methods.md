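# Methods

`nucleostrain` quantifies how chromatin deforms inside living nuclei when a
localized temperature gradient pushes it around. The experimental recordings
it targets follow a fixed protocol: fluorescence stacks at 4 frames/s for
60 s — 20 s baseline, 10 s of line-scanned IR stimulation, 30 s recovery —
with a chromatin reporter (e.g. mCherry-H2b) and optionally a nucleolar
live stain, at 0.1233 µm/pixel. Every analysis stage is validated against a
synthetic phantom whose displacement field is known in closed form.

## Thermometry

Temperature-sensitive dyes lose intensity with heating; for mCherry the
relative quantum efficiency drops ~1.3 %/°C (the package default,
overridable). Calibration fits intensity vs temperature by ordinary least
squares and reports the fractional slope relative to the intensity at the
reference temperature; conversion is ΔT = (1 − I·c/I_ref)/slope, with `c` a
single multiplicative thermophoretic correction supplied through
configuration (dye migration in a gradient changes concentration, not
quantum yield; its magnitude is setup-specific, so it is a config parameter
with default 1). Calibrations spanning < 0.5 °C are rejected as
ill-conditioned.

Spatial profiles perpendicular to the heating line are fitted with an
offset plus two-sided exponential decay, `T(x) = T0 + A·exp(−|x−x0|/ℓ)`;
a cubic smoothing spline is the fallback, chosen by AIC. Gradients are the
analytic derivative of the fit — differentiating raw, noisy temperatures
would amplify noise hopelessly. At the profile kink (x = x0) the gradient
is evaluated on the decaying branch. Chamber profiles are averaged over a
20 µm window (a typical nuclear diameter) so chamber and in-nucleus
thermometry compare directly. A utility reports the thermal-expansion bound
α·ΔT (α = 3.5×10⁻⁴/°C for water): at the typical 2 °C heating, thermally
driven volumetric strain stays below 0.1 %, orders of magnitude below the
measured chromatin strains.

## PIV

Displacement fields are computed by multi-pass windowed cross-correlation
against the *undeformed t = 0 frame* (cumulative referencing; frame-to-frame
chaining would accumulate drift). The default schedule is a 32 px pass
followed by a 16 px pass, both at 75 % overlap, giving a final vector
spacing of 16×(1−0.75) = 4 px; the first pass seeds integer window offsets
for the second, which correlates only the residual. The 32 px window /
4 px final grid combination is only attainable at 75 % overlap if the final
pass halves the window — that reconciling interpretation is built in.

The correlation core zero-means both patches and takes the full FFT
cross-correlation, restricted to shifts within half a window. The integer
peak is refined by a 3-point Gaussian fit applied to *overlap-normalized*
correlation values: the full correlation tapers linearly with patch overlap
at larger lags, and fitting the raw values biases sub-pixel estimates
toward integers (pixel locking; on our phantoms up to 0.14 px at half-pixel
shifts, reduced to < 0.02 px by the normalization). Peak detection itself
uses the unnormalized surface, which is more robust because the taper
suppresses spurious far peaks. A parabolic fit substitutes when a
neighboring correlation value is non-positive.

Vector validation combines three tests: peak-to-second-peak ratio ≥ 1.3
(second peak outside the 3×3 neighborhood of the first); a global filter
rejecting components deviating more than 3 standard deviations from the
field mean (skipped when the spread is < 1e-9 px, i.e. numerical noise);
and a local normalized-median test on the 3×3 neighborhood with threshold
2.5 and a 0.1 px floor on the median absolute deviation. Rejected vectors
are replaced by the median of valid neighbors (iterated) but stay flagged.
Windows with less than half their footprint inside the analysis mask are
invalidated outright. On noise-free sub-pixel-shift phantoms the pipeline
achieves |bias| < 0.05 px and RMSE < 0.15 px; on rendered deformation
phantoms (1 µm amplitude) the field RMSE is ≈ 0.08 px.

## Strain

With `u, v` the displacement components on the regular PIV grid and L_char
the node spacing (the characteristic initial length), strains are central
differences of node-to-node displacement normalized by L_char — i.e. the
standard dimensionless infinitesimal strains:

    ε_hydro = (∂u/∂x + ∂v/∂y) / 2        ε_shear = ∂u/∂y + ∂v/∂x

The hydrostatic strain halves the sum (mean normal strain); the shear is
the engineering (unhalved) sum — the literal reading of the defining
formulas, flagged here because the tensor convention would halve it too.
Edges use one-sided differences. Strain maps are bilinearly interpolated to
pixel resolution, with nearest-node extrapolation between the grid hull and
the nucleus mask. No smoothing is applied by default. *Absolute* statistics
average |ε| (extension and compression add up); *total* statistics average
the signed ε (they cancel; a volume-preserving deformation gives ≈ 0).

## Compartments

The nucleus is segmented by Otsu threshold, morphological closing, hole
filling and largest-component selection. A 6 px (~0.74 µm) rim inside the
border is eroded away (Euclidean disc element) because displacements near
the stiff lamina are suppressed and would dilute interior statistics.
Interior pixels are ranked by chromatin intensity and split into seven
equal-count classes C1 (dimmest) … C7 (densest); ties break by stable pixel
order, so the labelling is deterministic and bin sizes differ by at most
one pixel. Nucleolus pixels are excluded *before* binning — nucleoli are
chromatin-void and analyzed as their own region (NLL).

Nucleoli are Otsu-thresholded within the nucleus on the stain channel
(components < 0.5 µm² discarded; several nucleoli allowed). Perinucleolar
shells PC1–PC3 are 4 px (~0.49 µm at the default pixel size) annuli of the
Euclidean distance transform from the nucleolus; distances are offset by a
quarter pixel because the effective boundary of a curved pixelated contour
lies, on average over orientations, beyond the outermost foreground pixel
centres — without the offset, annulus areas on disc phantoms bias ~7 % low.
The central heterochromatin cluster (CHC) of inverted nuclei is the
connected component above the 85th intensity percentile closest to the
nucleus centroid (centrality weighted by component size), cleaned by a
small opening/closing and hole filling, and finally opened with a 3 px disc
to shave off attached bright speckles. The 85th percentile is a convention
of this implementation, exposed as a parameter.

## Kinetics

The mean absolute image difference |I_t − I_0| over a mask is the global
deformation readout (the absolute value is essential: signed differences
cancel). Scalar creep/recovery traces are summarized by a Kelvin-Voigt
model — spring E and dashpot η in parallel, τ = η/E:

    creep (t ≥ t_on):  ε(t) = (1/E)·(1 − e^{−(t−t_on)/τ_c})
    recovery (t > t_off):  ε(t) = ε(t_off)·e^{−(t−t_off)/τ_r}

The baseline (mean of the 20 s pre-stimulus window) is subtracted first.
The model is exposed statsmodels-style: `KelvinVoigtModel(series).fit()`
returns a `KelvinVoigtResults` with estimates, curvature-based standard
errors, `summary()` and `plot()`. The fit estimates (1/E, τ_c, τ_r) jointly
by nonlinear least squares over both segments, with the recovery amplitude
tied to the creep endpoint ε(t_off) exactly as the model equations demand;
τ_c and τ_r remain independent parameters (creep and relaxation times
differ in practice). A 3×3 multi-start grid over initial time constants
(0.1, 1, 10 s) guards against local minima. Traces whose fitted amplitude
is within twice the baseline noise are flagged flat. Recovery accuracy at
5 % plateau noise and 4 fps: pooled median relative error of the recovered
time constants < 5 % for τ ∈ [0.2, 5] s. At τ = 0.2 s individually the
creep-side error is resolution-limited (~10 % median): with 0.25 s sampling
the rise is essentially one sample, and the Cramér-Rao bound already
exceeds 5 % there — no estimator does better at these conditions.

Feature tracking thresholds dark (chromatin voids) or bright (CHC)
features per frame, takes connected components with intensity-weighted
centroids and second-moment ellipse axes, and links frames by nearest
neighbor with a 1 µm gate (feature density is low; a probabilistic tracker
would be over-engineering). Ambiguous links warn and take the nearest
candidate. Kymographs sample intensity along a fixed line (bilinear) per
frame. Border profiles cast rays from the t = 0 nucleus centroid and locate
the outermost mask crossing with sub-pixel interpolation, reporting
r(θ, t) and its maximal deviation from t = 0. Fiber strain for the CHC is
ΔL/L₀ with L₀ = 3 µm (the rest length of the radial fibers) and ΔL the
centroid displacement measured from stimulus onset.

## Statistics

Per-compartment tables combine the per-pixel strain and displacement maps
with the labels at the peak-deformation frame (the last stimulation frame,
t_on + 10 s). Row invariants: |total| ≤ absolute per compartment, and the
pixel-count-weighted mean of compartment totals equals the whole-region
total exactly. Group comparisons use one-way ANOVA (SciPy) with Tukey HSD
post-hoc (statsmodels, Tukey-Kramer, so equal n is not required) and a
two-tailed unpaired t-test for the pooled light (C1–C3) vs dense (C4–C7)
comparison. Identical groups report F = 0, p = 1 rather than NaN. Boxplot
summaries use the 25–75 percentile with whiskers spanning the data after
removing points more than 3 standard deviations from the group mean.

## The phantom

The phantom provides exact ground truth for every stage. Its texture is
Gaussian-filtered white noise with the autocorrelation FWHM matched to a
0.5 µm grain (chromatin-like speckle, and a good particle-image size for
PIV), normalized to mean 100 / contrast 30 over a disc nucleus on a dark
background. Defaults mirror the acquisition protocol: 240 frames at 4 fps,
t_on = 20 s, t_off = 30 s, 0.1233 µm/px, peak displacement 2 µm.

The displacement field points away from a stimulus line with magnitude
A·e^{−d/λ}·g(t), where d is the distance to the line, λ = 5 µm a decay
length chosen to span the observed range of per-nucleus displacement
heterogeneity (the decay of displacement with distance is not
characterized quantitatively in the source data; the exponential is a
convention that keeps strain analytic), and g(t) the Kelvin-Voigt
creep/recovery time course (defaults τ_c = 0.74 s, τ_r = 0.92 s). Local
modifiers, each with closed-form derivatives so the ground-truth strain is
analytic (product rule over piecewise-linear radial ramps):

- **Immobile nucleolus** — the field vanishes inside the disc and ramps
  linearly back to the far field over a 1.5 µm coupling length, the scale
  over which coherent "network" motion is observed around static nucleoli.
  A *mobile* nucleolus leaves the field untouched (it advects with
  chromatin).
- **Rigid CHC** — inside the disc the field is the spatially constant
  translation of the disc centre (zero internal strain by construction);
  outside, it blends linearly into the far field over a 1.5 µm ramp. The
  ramp is not cosmetic: a discontinuous rigid translation makes the forward
  map non-injective (the moving disc overruns its surroundings), and
  backward warping would then silently render a static cluster.
- **Static border** (optional) — the field is damped linearly to zero over
  a ramp inside the nuclear radius, emulating lamina anchoring; used for
  border-rigidity validation.

Frames are rendered by backward warping: the source of each output pixel
solves src + u(src) = x by fixed-point iteration (10 iterations; converges
because displacement gradients are < 1), then samples the t = 0 texture
with cubic splines, edge-clamped, with a warning if sources leave the
frame. Forward splatting was rejected because it leaves holes. Camera
noise is seeded i.i.d. Gaussian read noise (default off; σ configurable),
with optional Poisson shot noise — the actual camera statistics of the
source recordings are unreported, so Gaussian-only is the default. The CHC
appears as a coherently bright body (texture fluctuation damped to 30 %,
edge anti-aliased over one pixel): a condensed cluster is not speckle on
top of speckle, and a hard binary edge would alias under sub-pixel warps.
The nucleolus appears as a dark pocket (15 % contrast).

What the phantom does *not* emulate: optical PSF and out-of-focus light,
photobleaching, 3D motion, spontaneous coherent chromatin motion in the
baseline, and intensity changes from the temperature sensitivity of the
reporter itself. Passing phantom suites therefore demonstrates the
correctness and accuracy of the *measurement pipeline* under known
deformation, not the biological conclusions drawn from real recordings.

## Problem sizes used in validation

Test phantoms are 128–256 px with a handful of rendered frames sampling
baseline, creep and recovery, and pipeline round trips use ~60 frames —
sizes chosen so the full validation suite completes in a couple of minutes
while every claim (grid geometry, sub-pixel accuracy, strain oracles,
time-constant recovery, region orderings) is exercised at full parameter
defaults. The Kelvin-Voigt recovery sweep runs 100 noisy traces per time
constant at the protocol's native 240-sample resolution.

## Known limitations

- PIV near the nucleus border is masked out rather than corrected; windows
  straddling the border would mix static background into the correlation.
- The local-median filter floor (0.1 px) and SNR threshold (1.3) are MatPIV
  conventions, not fitted quantities; both are configuration parameters.
- The two-sided exponential temperature profile is a low-parameter
  convenience; profiles with asymmetric decay lengths fall back to the
  spline.
- Strain is infinitesimal; at the observed ≤ 15 % strains the neglected
  finite-strain terms are second order (~2 %).
- The equal-count binning is degenerate under heavy intensity ties
  (flagged with a warning); continuous-valued fluorescence makes this a
  non-issue in practice.
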