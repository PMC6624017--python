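# gradientscape

Nutrient gradients and gene-expression landscapes in confined yeast
monolayers.

A monolayer of budding yeast growing in a shallow dead-end microfluidic
chamber (800 × 50 × 4.5 µm, up to ~2500 cells) feeds on glucose diffusing in
from the chamber opening. Uptake by the cells closest to the opening
exhausts the supply, a steady concentration gradient forms, and the colony
self-organises into a fermentative, actively dividing region near the
nutrient source and a starved, arrested region at depth. The depth of the
divide is visible in three independent ways: where cells stop moving, where
glucose-regulated reporters (the HXT transporters, HXK1/2, MIG1, PDC1, SDH2)
peak or switch, and where the reconstructed glucose profile crosses the
reporters' low-glucose landmark.

This package is for quantitative microbiologists and biophysicists working
with such systems. It provides:

- **core model** — the 1-D diffusion–uptake–growth model
  `D C″(y) = q(C)` with Monod uptake `q = q_max C/(k_q + C)` and growth
  `µ = µ_max C/(k_µ + C)`; the growth-driven velocity field
  `v(y) = ∫_y^L µ(C) dz`; quasi-static chamber-filling simulation with front
  velocity `V_F` bounded by `µL`;
- **reporter calibration** — Hill-type batch dose–response curves `G(C)`
  fitted to FACS dilution-ladder tables, invertible per monotone branch;
- **gradient reconstruction** — the affine anchor mapping of in-colony
  fluorescence landscapes `F(y)` onto `G(C)` (front ↔ `C0`, landscape peak ↔
  batch maximum) and inversion to `C(y)` down to the 0.016% w/vol landmark;
  landscape features (peaks, logistic transitions) and the phase I/II
  boundary as their pooled median;
- **image/track extraction** — FFT band-pass, Otsu front detection and front
  velocities, temporal-std motion maps with penetration depth, binned track
  velocities, MIG1 nuclear-fraction profiles;
- **synthetic data** — seeded generators for every input (FACS tables,
  landscapes, time-lapse stacks, tracks, nuclear flags) with known ground
  truth, enabling closed-loop validation of the whole pipeline.

See `docs/methods.md` for the model, its assumptions, and every numerical
and calibration choice.

## Worked example

```python
import numpy as np
from gradientscape import MonolayerModel, percent_to_millimolar
from gradientscape.synth import SyntheticScenario, generate_fluorescence_landscape
from gradientscape.reconstruction import reconstruct_gradient, find_peak_position

# the physical model at 2% w/vol glucose (111 mM)
model = MonolayerModel(c0_mM=percent_to_millimolar(2.0))
profile = model.solve_gradient()          # steady C(y)
field = model.velocity_profile(profile)   # v(y), um/h

# a synthetic HXT7 landscape at the same conditions, and its inversion
sc = SyntheticScenario(seed=1)
ls = generate_fluorescence_landscape(sc, "HXT7")
print(f"HXT7 peak at {find_peak_position(ls).position_um:.0f} um")
rec = reconstruct_gradient(ls, sc.panel["HXT7"])
print(rec.summary())
mask = rec.valid_mask
truth = sc.glucose_profile.interpolate(rec.positions_um[mask])
err = np.median(np.abs(rec.concentrations_mM[mask] - truth) / truth)
print(f"median relative error vs generating gradient: {err:.1%}")
```

prints

```
HXT7 peak at 461 um
Glucose gradient reconstruction (HXT7)
------------------------------------------------
external glucose C0: 111 mM
valid region: 0 - 469 um (48 bins)
clamped bins: 0
anchor front: F=0.05188 a.u. -> G=0.05141 a.u.
anchor peak: F=1.048 a.u. -> G=1.05 a.u.
concentration range: 1 - 111 mM
median relative error vs generating gradient: 1.6%
```

The HXT7 expression peak sits ~460 µm deep at 2% w/vol — the depth at which
the model gradient crosses the reporter's 0.016% w/vol (0.89 mM) batch
landmark — and inverting the noisy landscape through the batch curve
recovers the generating gradient to a couple of percent over the valid
region (front to peak; deeper positions are below the invertible landmark
and flagged invalid).

The same pipeline runs end to end from the shell:

```bash
gradientscape run --seed 42 -o out/        # synth -> extract -> calibrate
                                           # -> reconstruct -> classify
gradientscape simulate --c0-percent 2.0    # chamber-filling front dynamics
gradientscape extract motion stack.tif --pixel-size-um 2.0
```

`out/summary.json` collects the feature positions, the phase boundary, the
motion penetration depth and the reconstruction error against the generating
truth; two runs with the same seed are byte-identical.

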