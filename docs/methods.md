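# Methods

## The physical model

A yeast monolayer grows in a shallow dead-end chamber (defaults 800 × 50 ×
4.5 µm, 4 µm cells, ~2500-cell capacity) that is open to a perfused nutrient
channel at one end. Depth `y` runs from the opening (`y = 0`) to the dead end
(`y = L`). Glucose is held at the external concentration `C0` at the colony
front, diffuses through the packed cell layer with coefficient
`D = 100 µm²/s`, and is consumed by the cells, so a steady gradient forms:

```
D C''(y) = q(C),   C(front) = C0,   C'(L) = 0,   C ≥ 0.
```

Uptake `q` is volumetric (per unit colony volume) and either zero-order
(`q = q_max` wherever glucose is present) or Monod
(`q = q_max C/(k_q + C)`). Cells grow at the Monod rate
`µ(C) = µ_max C/(k_µ + C)` with `µ_max = ln 2 / 90 min ≈ 0.46 h⁻¹`. Because
every dividing cell pushes the column of cells above it toward the opening,
the local speed is the cumulative downstream growth

```
v(y) = ∫_y^L µ(C(z)) dz ,
```

zero at the dead end and maximal at the front; the front advances at
`v(front)`, bounded by the saturating value `µ_max·L ≈ 368 µm/h` when the
whole chamber grows. An optional scalar `growth_cap ∈ (0, 1]` uniformly
scales growth to represent media in which another nutrient (amino acids)
co-limits growth.

Chamber filling is simulated quasi-statically: the diffusion time
`L²/D ≈ 1.8 h` is comparable to one doubling, but the *gradient-forming*
region is much shorter (`H ≈ 100–500 µm`, equilibration minutes), so at each
time step the steady gradient is re-solved on the occupied region and the
front moved by `v(front)·dt`. The terminal front velocity is read as the
mean over the trailing 10% of samples, which is the plateau reading in the
H-limited regime; in the fully saturated limit the front accelerates until
it exits and only the final sample attains `µ_max·L`.

### Parameter calibration

`q_max` is the one genuinely free physical parameter. The dimensional
estimate `H ~ sqrt(D C0/q0)` with the literature-scale `q0 ≈ 1 mM/s` gives
~100 µm at 2% w/vol — a known underestimate of the observed growing-layer
size, because the effective uptake falls with concentration and with the
cells' metabolic state. We calibrate `q_max = 0.11 mM/s` (with `k_q = 1 mM`,
`k_µ = 0.5 mM`) once, so that at 2% w/vol the depth at which the gradient
crosses the 0.016% w/vol reporter landmark is ~460 µm and the kinematic
motion boundary ~560 µm (the two experimental estimates of the penetration
depth are 400–500 µm), and at 8% w/vol glucose floods the chamber
(`C(L) ≈ 95 mM`), which reproduces the observed front-velocity plateau above
4% and the uniformly high HXT1 expression at 8%.

### Numerics

The boundary-value problem is discretised with second-order central
differences (zero-flux at the dead end via a mirrored ghost node) and the
nonlinear uptake handled by a damped Picard iteration (`damping 0.8`) in
which the uptake is linearised as `q(C_old)/C_old · C`; this keeps the
operator an M-matrix, hence the iterates non-negative, and converges when
the maximum update falls below 1e-8 mM (cap 10⁵ sweeps, failure raises with
the residual). Zero-order uptake is regularised with a linear ramp below
1e-6 mM so the rate vanishes with the concentration; without it the free
boundary makes the fixed point chatter. Diffusive influx at the front
(second-order one-sided difference) balances integrated uptake to well
under 1% at 200+ grid points.

Two distinct "penetration depth" notions are exposed deliberately:
`GlucoseProfile.stall_depth_um(threshold)` (first grid point below a
concentration threshold, default 1e-6 mM — sensitive to the long Monod tail)
and the kinematic `SyntheticScenario.stall_depth_um` (shallowest depth where
the local speed drops below 1 µm/h, i.e. visibly static over an imaging
session). The motion map measures the latter.

## Reporter calibration

Batch dose–response curves are parametric in concentration: monotone
responses are Hill functions (equivalently logistic in log-concentration);
peaked responses are the normalised product of a rising and a falling Hill
term with a shared steepness, which places the maximum exactly at the
geometric mean of the two half-points — parametrised directly by `peak_mM`
and a log-width. Fluorescence units are arbitrary; the default panel's
amplitudes are order-1 and synthetic. HXT7, HXK1 and HXK2 peak at 0.89 mM
(0.016% w/vol); HXT1 and PDC1 rise with glucose; HXT5 and SDH2 fall; MIG1's
curve is a near-binary nuclear-localisation probability. HXT1's half-point
(1 mM) is set near glucose exhaustion so that its in-colony landscape is
inversely correlated with HXT7's, as observed; the HXT2–4/HXT6 parameters
are placeholders (their batch data exist only graphically) and nothing
downstream depends on them.

Fitting (`DoseResponseModel.fit()`) is least squares in log-concentration
via `scipy.optimize.curve_fit`, with the 0% ladder point floored at 1e-4 mM;
results carry parameter standard errors from the covariance and the RMSE.
Branch inversion brackets the root in log-concentration with Brent's method,
giving eval∘invert roundtrips at ~1e-12 relative; requests outside a
branch's response range raise a range error naming the valid interval.

## Synthetic data

The generators are pure functions of (inputs, seed) and emulate, in order:
FACS tables over the log2 dilution ladder 8% → 0.0078125% plus 0% (12 rows;
central value = replicate mean of the response times lognormal noise of
given CV, mean exactly 1); fluorescence landscapes (gradient composed with
the reporter curve, binned at 10 µm, 9 replicates averaged — the replicate
count mirrors typical channel-averaging); time-lapse stacks (Gaussian blobs
of FWHM one cell diameter at 2 µm/px, 6 min frames, advected by the velocity
field, frozen beyond the kinematic stall depth, background at 10% and
additive Gaussian pixel noise at 5% of the blob peak); tracks
(stratified-uniform start depths — packed cells tile the chamber, so iid
starts would be unrealistically clumpy — integrated with a midpoint rule and
optional positional jitter); and per-cell MIG1 nuclear flags (Bernoulli with
probability given by the MIG1 curve at the local concentration).

GFP perdurance is modelled as a spatial exponential memory: beyond the
kinematic stall depth the landscape decays over `perdurance_um`
(default 100 µm) from its stall-depth value instead of tracking the local
concentration, never dipping below the instantaneous response, so
`perdurance_um = 0` disables the effect. The value is a synthetic free
parameter, not an estimate of GFP turnover; vacuolar re-localisation of the
tagged protein and budding morphology are not modelled. What the synthetic
data deliberately lack — segmentation errors, photobleaching, uneven
illumination beyond the band-pass scale, cell-size variability, and
biological reporter noise beyond a single CV — bounds what passing tests
show about real images: they validate the estimators and the inference
pipeline, not robustness to every imaging artefact.

## Extraction

The FFT band-pass suppresses structures larger than 40 px (shading) and
smaller than 5 px (noise) with a fourth-order super-Gaussian rolloff in
radial spatial frequency. The fourth-order profile keeps the passband flat
(in-band sinusoids pass at >95%, so the filter is nearly idempotent) while
rolling off steeply outside; the DC component is retained, so a constant
image maps to itself. Otsu thresholding delegates to
`skimage.filters.threshold_otsu` on a 256-bin histogram; front detection
closes the binary mask (3×3) to bridge texture gaps, then takes the
shallowest row whose foreground occupancy across the width exceeds 50%, both
exposed parameters. Front velocities are centred finite differences of the
per-frame positions, clipped at zero. The motion map is the per-pixel
temporal standard deviation; its depth profile crosses
`background + 0.1 × dynamic range` at the penetration depth (sustained for
all deeper rows). Track speeds are per-step depth displacements assigned to
the bin of the step midpoint (16 bins), binned front velocities use 10 bins,
and the MIG1 nuclear fraction uses 25 µm bins with the 0.5 crossing linearly
interpolated between bin centres. Binned means of non-negative quantities
are clipped at zero. The depth axis (rows-increasing = deeper) is declared,
never auto-detected.

## Gradient reconstruction

Fluorescence landscapes and batch curves live in different intensity units;
an affine map `m(F) = aF + b` is fixed by two anchors: the front intensity
`F0` — extrapolated linearly to `y = 0`, where the concentration is `C0` by
construction — maps to `G(C0)`, and for peaked reporters the landscape
maximum (sub-bin refined by a quadratic through the three bins around the
smoothed argmax) maps to the batch maximum `G(C_peak)`. Inverting
`m(F(y))` on the high-concentration branch yields `C(y)` from the front to
the peak position; deeper bins are below the invertible landmark (0.016%
w/vol) and are marked invalid rather than extrapolated. For
monotone-increasing reporters (HXT1) the deep landscape minimum anchors to
the curve's basal end (the lower edge of the calibrated range): in a colony
the deep region is glucose-exhausted, and anchoring it instead to the 0.89
mM landmark injects an intensity offset that the ill-conditioned inverse
amplifies to >10% concentration error mid-range. Mapped intensities that
leave the branch are clamped to the branch endpoint and counted. The
returned profile starts with an exact `(0, C0)` sample.

Inversion conditioning varies along the chamber: near the front the peaked
response is nearly flat in concentration (the high-glucose tail falls as
`1/C^h`), so small intensity errors inflate there; errors are smallest in
the mid-gradient. This is intrinsic to reporter-based inference, not an
implementation artefact.

Landscape features are the expression peaks (quadratic sub-bin refinement,
ties toward the opening, edge maxima flagged `boundary_peak`) and the
low/high transitions (four-parameter logistic in position, midpoint
parameter, quality = RMSE over dynamic range; landscapes whose dynamic range
or fitted plateau separation is within twice the median per-bin spread raise
a no-transition error). The phase I/II boundary is the pooled median of
feature positions — robust to one outlying reporter — with their standard
deviation reported as the boundary width. Landscape alignment min-max
normalises each landscape (a constant landscape maps to zeros) and
resamples linearly onto a common grid.

## Interface

A pydantic-validated config (unknown keys rejected, all violations listed at
once) drives `run_end_to_end`: synth → extract → calibrate → reconstruct →
classify, writing CSV/TIFF/YAML artifacts and a versioned `summary.json`.
All randomness derives from the single config seed; equal configs give
byte-identical outputs. The summary's reconstruction error metric inverts
with the reference batch curve so it isolates inversion fidelity; the
calibration fit is performed and its quality (RMSE, location parameter vs
reference) reported alongside. With `c0_percent = 0` the pipeline completes
with a "no growth, no features" summary and exit code 0.

## Problem sizes

Default analyses use 400 grid points for the gradient, 80 landscape bins,
9 landscape replicates, 2500 cells and 15–25 frames per stack at 2 µm/px,
120–200 tracks, and 20 seeded scenarios for the noisy recovery study; these
sizes keep every closed loop comfortably converged while the full test suite
and the acceptance script each run in seconds.

## Known limitations

One-dimensional transport only (no cell mechanics, pressure, or
recirculation); a single limiting nutrient with a scalar cap for co-limiting
amino acids; uptake per colony volume with literature-free Monod constants
calibrated as described; perdurance as a phenomenological spatial memory;
greedy nearest-neighbour linking for tracks rather than a LAP tracker (the
2-cell-diameter step cap requires frame intervals short enough that cells
move less than that per frame, and the greedy assignment biases the fastest
bins ~15% low); and arbitrary-unit fluorescence throughout (no absolute
cross-instrument calibration or bleaching correction).
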