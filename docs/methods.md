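# Methods

This note documents the models, conventions and defaults of `dynpet`, the
design choices made where several reasonable options existed, and what the
simulation studies do and do not demonstrate.

## Kinetic models

**Irreversible 2TCM.** Free and trapped compartments with rates `K1`
(mL/min/cm³ in), `k2`, `k3` (1/min); no efflux from the trapped pool
(`k4 = 0`, appropriate for FDG over one hour). The measured voxel signal is
`C = (1−vb)·C_T + vb·Cb`, `C_T = [K1/(k2+k3)]·(k3 + k2·e^{−(k2+k3)t}) ⊗ Cp`.
The forward model is evaluated on a uniform 1-s internal grid with an exact
exponential-integrator update (the exponential convolution is solved in
closed form per step for a piecewise-linear input), so discretization does
not confound parameter-recovery tests; the unit test against a stiff ODE
integrator agrees to ~1e−8 relative. Kinetic time is minutes internally;
frame schedules are stored in seconds and converted at the boundary.

**Patlak analysis.** `x = ∫₀ᵗ Cp/Cp(t)`, `y = C(t)/Cp(t)` at frame
mid-times, straight-line fit for mid-times ≥ `t*`. Integration is by
trapezoid on the input function's own time base (a 1-s base for analytic
inputs, frame mid-times with a prepended origin for image-derived curves).

**The (1−vb) identity.** The graphical slope of the measured voxel signal
is `(1−vb)·Ki`: the blood-volume fraction dilutes the tissue response. The
packaged reference table's Patlak influx column equals `(1−vb)` times its
2TCM macro-`Ki` column for every tissue (after printed rounding), so the
two columns are two views of one parameter set. Consequently the harness
computes Patlak ground truth by applying its own closed-form fit to
noise-free tissue curves rather than reusing the 2TCM values.

**SUV.** `SUV = C·W/(D·2^{−t/T})`, `T = 110` min, density 1 g/mL;
standardized study conditions are `W = 60` kg and `D = 4` MBq/kg. The decay
factor is applied physically as `2^{−t/T}` (an equivalent published form
writes the exponent with an extra ln 2; the physical convention is used
here and the difference documented rather than reproduced).

## Input function

A tri-exponential bolus
`Cp(t) = (A1·t − A2 − A3)e^{−l1 t} + A2 e^{−l2 t} + A3 e^{−l3 t}` with
defaults `A1 = 329`, `A2 = 8.0`, `A3 = 8.6` kBq/mL and `l1 = 4.1339`,
`l2 = 0.25`, `l3 = 0.01043` /min. These give a peak of ≈ 40 kBq/mL at
≈ 0.3 min (the scale of a 4 MBq/kg injection in 60 kg) and a 60-min tail of
≈ 12 % of peak. The intermediate clearance `l2` is set fast enough that the
graphical-analysis transform is linear within the default fit window: the
module contract requires the Patlak slope of noise-free tissue curves to
reach the macro influx constant within 2 % at `t* = 20` min for every
packaged tissue, which slower textbook values of `l2` (≈ 0.12 /min) violate
(the intermediate plasma component is then still clearing through the
20–60 min window, biasing the windowed slope by up to ≈ 4.5 % for
slow-uptake tissues). Whole blood equals plasma by default (FDG); a
blood/plasma ratio is exposed.

## Frame schedule

The default dynamic protocol is 41 contiguous frames over one hour:
12×10 s, 12×20 s, 4×60 s, 5×120 s, 8×300 s. Ground-truth TACs are
duration-averaged over each frame (not point-sampled), matching histogrammed
acquisition.

## Phantom

A deterministic, stylized thorax on a configurable grid (default
128×128×16, desk studies use 48×48×4 or 64×64×8; minimum 48×48×4): body
outline with a fat rim and muscle interior, two lungs, heart, liver,
spleen, spine + sternum (bone), a descending-aorta cylinder (arterial pool)
and a vena-cava cylinder (venous pool), extruded along z; two spherical-ish
lung tumors, each a center core inside a border shell, with the core's z
extent strictly inside the shell's. Blood-pool diameters are set to
clinical vessel calibres *in pixel units* (aorta ≈ 8 px, cava ≈ 7 px on a
48-px thorax) so the pools survive the reconstruction point spread the way
real vessels do at clinical voxel sizes; with substantially smaller pools
the blood voxels are partial-volume mixtures and their fitted kinetics
become unidentifiable. Every label carries the packaged kinetic parameters;
blood labels carry the whole-blood input curve directly. Attenuation is
piecewise constant by tissue class (air 0, lung 0.03, soft tissue 0.096,
bone 0.17 cm⁻¹ at 511 keV) and is known exactly to the reconstruction.

TACs are voxel-homogeneous within a label (assumed; spatial modulation
within organs is not simulated).

## Projection, counts and reconstruction

The scanner is a 2-D parallel-beam system per slice (48 view angles over
180°, radial bins equal to the image side; slices independent). The
projector is an explicit sparse matrix — rotate with bilinear interpolation,
sum along detector columns — and reconstruction uses its exact transpose,
so forward/back projection are an adjoint pair and noise-free MLEM
converges to ≈ 1 % NRMSE on a band-limited disc (a hard-edged disc is not
representable on the grid; its remaining error is confined to the rim).

Expected trues per frame = attenuated line integrals × frame duration ×
physical decay at the frame mid-time × a scanner sensitivity factor.
Ground-truth images are decay-corrected; decay is applied to counts and
re-corrected after reconstruction. Expected randoms are spatially uniform
at 30 % of mean trues (the distributional choice is a stand-in; only the
rate is meaningful). The absolute count level is a free parameter
calibrated so the last (300-s) frame averages a target number of expected
trues per bin — package default 20 (a deliberately photon-poor desk
regime); the CNR study below uses 400. The long-axial-FOV configuration
multiplies trues and randoms by 3.5 and reconstructs with 19 OSEM subsets
(vs 28), reflecting the sensitivity and protocol differences between the
two emulated systems; time-of-flight is not modeled (an optional extra
sensitivity multiplier, default 1.0, stands in).

Poisson noise is drawn per (replicate, frame, slice) from
`SeedSequence(master_seed, spawn_key=(replicate, frame, slice))`, making
replicates independent, order-insensitive and byte-reproducible.

OSEM assigns angle `i` to subset `i mod N` and processes subsets in index
order; randoms enter the forward model additively; the multiplicative
update preserves non-negativity; zero-sensitivity voxels are zeroed and
reported. More iterations sharpen structures and raise voxel variance
(checked: ≥ 90 % of foreground voxels have higher replicate variance at 6
than at 2 iterations).

## Voxel-wise fitting

* Foreground: voxels whose time-integrated activity exceeds 1 % of the
  volume maximum; air is marked `masked`.
* Patlak: closed-form weighted least squares, vectorized over the volume
  (a 64×64×8×41 volume fits in well under a second); default `t* = 20` min
  — beyond five equilibration time constants for every packaged tissue
  (`k2+k3 ≥ 0.25` /min).
* 2TCM: per-voxel bounded trust-region least squares with an analytic
  Jacobian (the α-derivative of the exponential convolution is itself an
  exponential convolution). Bounds `K1 ∈ [0,2]`, `k2, k3 ∈ [0,5]`,
  `vb ∈ [0,1]`; deterministic start (0.05, 0.2, 0.03, 0.05) with one
  fallback restart; non-convergence marks the voxel `failed` (NaN sentinel)
  and never aborts the volume. `Ki` is derived voxel-wise by the macro
  formula (exact identity with the `K1,k2,k3` volumes).
* Weighting: uniform by default (reproducible, convention-free). The noisy
  simulation studies use frame-duration weights — the variance of a
  histogrammed frame scales inversely with its duration, and with uniform
  weights the 10-s early frames dominate the residual and destabilize the
  fits at desk-scale count levels.
* IDIF: per-frame mean over the arterial mask eroded by one voxel
  (fallback to the uneroded mask, with a warning record, if erosion empties
  it), tabulated at frame mid-times with a prepended origin.
* Determinism: identical inputs and settings give bit-identical maps.

## Evaluation conventions

* Per-label percent bias: `|⟨estimate⟩ − truth|/truth × 100` with `⟨·⟩` the
  mean across replicates (bias of the mean); the accompanying SD is the
  sample SD (N−1) of the per-replicate percent biases.
* Voxel-wise mean/SD volumes across replicates use the population SD (N).
* NBias = bias of the replicate mean; NSD = sample SD of the replicate
  label means divided by *truth* (symmetric with NBias), both in percent.
* CNR = `|mean(tissue ROI) − mean(background ROI)|/SD(background ROI)` on
  the replicate-mean map, background = venous blood pool. Whole-study
  tables use the eroded structure label as tissue ROI; the dedicated CNR
  study uses small 32-voxel core ROIs (deepest voxels by distance
  transform), which matches the small-ROI analysis design the reference
  tables come from and keeps many-replicate studies tractable.
* Cross-configuration aggregate: per (structure, parameter) cell,
  `100·(bias_LAFOV − bias_SAFOV)/bias_SAFOV`; the summary is the median
  over the 22 Patlak or 55 2TCM cells, rounded to integer percent for
  reporting. On the packaged tables this yields −56 % (Patlak, 2 it),
  −3 % (Patlak, 6 it) and −27 % (2TCM, 6 it) in agreement with the
  published summaries, and −42 % for 2TCM at 2 iterations where the
  published summary states −37 %; no per-cell reading of the published
  tables reproduces −37, so the package reports the recomputed value and
  flags the inconsistency.
* The packaged reference tables (kinetic parameters; per-structure biases
  at 2 and 6 iterations) are CSVs verified against SHA-256 checksums at
  load, so aggregation results cannot drift through transcription.

## Study sizes

Desk-scale defaults: 48×48×4 or 64×64×8 grids, 48 view angles, 4–24
replicates; the dedicated CNR study runs the short-FOV configuration at 6
OSEM iterations, 400 expected trues/bin in the last frame, 12 replicates,
duration-weighted fits. A full 41-frame, 4-slice, 12-replicate simulation
with small-ROI 2TCM fitting completes in a few minutes on one CPU.

## What the studies show — and known limitations

The harness demonstrates, against exact ground truth: noise-free
identifiability (every packaged tissue recovered within 1 % in all 2TCM
parameters; Patlak slope within 2 % of the macro influx constant),
reconstruction-noise propagation into parametric maps, the
variance-vs-iterations trade-off, the sensitivity advantage of the
long-FOV configuration (label-SD of SUV lower for all 11 structures), and
a strong CNR advantage of Patlak `Ki`/`vb` and 2TCM `vb` maps over SUV
(≈ 85 % of those ratio cells exceed 1 in the desk study).

It does not reproduce, and is not expected to reproduce:

* absolute bias magnitudes of the reference tables (they depend on
  patient-derived count levels and full 3-D scanner geometry that are not
  public);
* the single qualitative cell "tumor k3 has the highest kinetic-to-SUV CNR
  ratio". At desk scale this fails for a structural reason: in the venous
  background the trapping rate is unidentifiable (blood voxels constrain
  only `vb`; fitted `k3` scatters across its bounds), so the background SD
  of every `k3` map stays of order 1 and tumor `k3` CNR saturates around
  1, while `vb`/`Ki` map CNRs reach 10–50. Probing 2–6 iterations, 20–2000
  trues/bin, 4–24 replicates and small vs whole-label ROIs does not change
  the ordering. Reproducing the cell plausibly requires full-scale
  resolution and count densities at which blood-voxel fits collapse to
  `vb ≈ 1` with frozen `k3`.

Further simplifications: 2-D geometry per slice (no 3-D ray tracing), no
scatter, detector normalization, dead time, TOF kernels or respiratory/
cardiac motion; reversible 2TCM (`k4`), input-function delay/dispersion and
metabolite correction are out of scope.
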