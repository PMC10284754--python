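# Methods

## The measurement problem

Quantitative SPECT of ¹⁷⁷Lu yields voxel images calibrated in activity
concentration (kBq/ml). For objects whose diameter is not much larger than
the system resolution, the apparent concentration in any volume of interest
is biased: signal spills out of small hot objects, and, when surrounding
tissue is also active, background signal spills in. `luquant` quantifies
how well three VOI-based measurement methods recover the true
concentration of hot spheres under varying sphere-to-background ratios, and
implements a threshold-VOI partial-volume correction (PVC).

## Phantom model

The phantom follows the NEMA IEC body-phantom geometry: six fillable
spheres of inner diameter 10, 13, 17, 22, 28 and 37 mm (volumes 0.52–26.52
ml), arranged on a 114.4 mm circle in one transverse plane, in a large
background compartment (nominally 10.2 L). Default fill concentration is
514 kBq/ml; a phantom series is derived by setting the background to
fill/ratio for ratios ∞ (cold background, label `P_inf`), 9.5, 5.0 and
2.7. The true concentration map is rasterized on an isotropic grid
(default 4.8 mm voxels, 128 × 128 × 80) with supersampled partial-volume
fractions at sphere boundaries; per-sphere rasterized activity converges to
C·πd³/6 with increasing supersampling (verified against the analytic
volume; convergence is asserted over 4× supersampling steps because the
midpoint-rule error oscillates between adjacent doublings).

## Reconstruction emulation

The tomography itself (projection, attenuation, scatter, collimator
modelling, OSEM/Bayesian iteration) is out of scope; the analysis consumes
reconstructed concentration maps, so only their statistical structure is
emulated:

- **sharp** — isotropic Gaussian blur of FWHM `psf_fwhm` plus an optional
  edge-ringing term implemented as a Laplacian-of-Gaussian response,
  emulating the Gibbs-type overshoot of resolution-recovery
  reconstructions. The LoG form adds nothing in flat regions and raises
  values just inside object edges, so the center of a large uniform sphere
  sits in a relative depression (the "valley"/"tunnel" artifact). Only the
  sign of this artifact is asserted anywhere, never its magnitude. A
  difference-of-Gaussians (unsharp-mask) formulation was tried first and
  rejected: with a wide outer kernel it boosts the whole sphere interior
  rather than carving a central depression.
- **smoothed** — as sharp without ringing, followed by a 10 mm Gaussian
  post-filter.
- **edge_preserving** — emulates a Bayesian reconstruction with an
  anatomical (Bowsher-type) prior by averaging a blurred noisy base image
  within each ground-truth region (each sphere; background), leaving sharp
  edges, then rescaling so the voxel-value total matches the base image
  (the total-count calibration used for non-quantitative reconstructions).

Noise is Poisson on expected counts, `value × noise_scale / max(truth)`
per voxel, rather than projection-domain noise: voxel-level count
statistics are what the VOI analysis sees, and the exact noise correlations
of iterative reconstruction are out of scope. Blur and ringing preserve the
global sum up to boundary truncation (< 1 % for the default geometry).

Defaults, chosen once as the study conditions: `psf_fwhm` = 12 mm (typical
effective resolution of ¹⁷⁷Lu imaging with medium-energy collimators; the
acquisition protocol being emulated does not publish one), post-filter
10 mm, `ringing_amplitude` 0.5 (sign-only artifact), `noise_scale` 200
expected counts per fill voxel (a few percent voxel noise, representative
of a well-exposed quantitative scan). Replicates default to 3 for `P_inf`
and 2 for `P_2.7`, mirroring repeated scans of those conditions; replicate
seeds are derived from the base seed via `numpy` seed sequences.

## VOIs and statistics

Spherical VOIs carry fractional voxel weights (supersampled inside
fractions): at 4.8 mm voxels and 10 mm spheres, binary membership is far
too coarse. Threshold-grown VOIs are binary, since they are defined on
voxels: the 26-connected component above `fraction × reference` containing
the seed (the hottest voxel inside VOI_dia), intersected with a 75 mm
bounding sphere. A component touching the bounding surface (any voxel
center within one voxel diagonal of the bound radius) is flagged as not
evaluable — the growth was stopped by the cap, not the threshold. The peak
value is the maximum 1 cm³-sphere average (sphere diameter ≈ 12.41 mm) over
candidate centers at voxel centers inside the search region; the averaging
sphere may extend beyond the region (convention recorded here; at 4.8 mm
voxels a continuous center search is not warranted). Peak is undefined for
regions below 1 cm³ (the ø10 sphere's VOI_dia).

The background mean is measured in a large region at least 25 mm clear of
every sphere surface and 15 mm from the grid faces (the physical study
used a ~4 L VOI away from the spheres; its exact placement is not
published, so clearance margins are the free choice here).

## Fitted models and PVC

**Recovery curve.** RC(d) = 1/(1 + (α/d)^β) is fitted by trust-region
nonlinear least squares (`scipy.optimize.least_squares`), initialized at
α = median diameter, β = 2. RC data are activity(VOI_dia) /
activity(VOI_dia+15), the latter measured on the matching background-free
image (mean over its replicates). All six spheres enter the fit by
default. Noise-free model-generated data are recovered to ≤ 1e−6 relative
error; under 1 % multiplicative noise the median |α̂ − α| stays below 1 mm
over 100 seeds.

**Volume growth.** V_VOI(V) = V₀ + c·V·(1 − e^(−V/V₁)) is fitted with the
constraint 0 < c ≤ 1 to the five largest spheres of the background-free
phantom, per reconstruction and threshold method (the ø10 sphere is
excluded; for peak-based thresholds it has no peak value at all).
Initialization: V₀ = min(V_VOI), c = 1, V₁ = median(V). With no data in
the large-V asymptote, c typically converges onto its boundary; fits within
1e−3 of 1 are reported as boundary-constrained. All-equal V_VOI input is
rejected as non-identifiable. Inversion uses a 10 000-point log-spaced
lookup table from 0.01 ml to 4× the largest fitted volume with linear
interpolation; only round-trip consistency (bounded by table resolution) is
guaranteed, and the table range/size is recorded in the serialized model.

**Correction.** v = V(V_VOI)/V_VOI, d′ = (v·6V_VOI/π)^{1/3} (the ml→mm³
factor of 1000 lives inside `effective_diameter` and has a dedicated unit
test), C = C_VOI/RC(d′). Measurements with V_VOI < V₀ are marked excluded
rather than corrected. On noiseless post-filtered images the full chain
reduces the absolute bias of the threshold-VOI mean for spheres ≥ 22 mm.

## Pipeline conventions

- All ratios are kept as fractions internally; percent appears only in
  reports.
- Rows that cannot be evaluated (bounding-sphere hit, undefined peak,
  V_VOI < V₀, degenerate fits) are retained with `bounded`/`excluded`
  flags and an error note, never dropped — the reports must show exactly
  which sphere/method/background combinations fail.
- On unblurred truth images every RC is exactly 1, which the RC fit rejects
  by contract (RC must lie strictly in (0, 1)); the pipeline records the
  model as absent and flags PVC rows, so the degenerate configuration still
  completes.
- "Solitary" in the selection criteria is an input flag, not derived from
  images.
- Selection criteria use strict inequalities: large VOI — solitary and
  d > 15 mm; small VOI — d > 30 mm and ratio > 2; threshold — d > 30 mm
  and ratio > 3. Both the 40 % and 50 % error levels appear in the error
  arithmetic helpers (`triangular_sd_from_max_error`, `true_value_bounds`)
  rather than being hard-coded anywhere.
- Determinism: a config plus base seed fixes every noise realization;
  reruns produce byte-identical CSV/JSON outputs.

## What the synthetic data does and does not show

The generator reproduces the features the analysis depends on — partial
volume loss governed by blur, background spill-in, threshold-VOI shrinkage
and growth, count noise, the edge-ringing sign, and piecewise-constant
edge-preserving behavior. It does not reproduce scanner-specific
properties: correlated OSEM noise textures, attenuation/scatter residuals,
misregistration between SPECT and anatomy, dead-time effects, or the true
(unpublished) resolution of any particular protocol. Passing tests
therefore validate the measurement and correction machinery under
controlled conditions, not the absolute accuracy of any scanner protocol;
fitted (α, β) values from the synthetic images depend directly on the
chosen `psf_fwhm` and are asserted only for qualitative behavior, never
against published magnitudes.

Problem sizes in the test suite are chosen for fast, deterministic runs:
most unit tests use a 64 × 64 × 40 grid, the bias-reduction chain runs on
the full default grid without noise, and the determinism check sweeps a
two-phantom, one-variant configuration; the default full sweep (four
phantoms × three variants with replicates) completes in well under a
minute on one core.

## Known limitations

- With a 12 mm PSF, the large-VOI method under-covers small spheres
  (≈ −16 % for ø13): a +7.5 mm radial margin captures essentially all
  counts only for effective resolutions around 6–8 mm FWHM. The
  measurement is validated against an independent Monte-Carlo displacement
  oracle instead of a fixed accuracy band.
- The calibration-factor analysis computes CF and SBVR curves only;
  applying them as a correction to lesion activity is deliberately not
  implemented.
- Patient dosimetry — time–activity fitting, absorbed-dose conversion,
  non-spherical geometries — is out of scope.
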