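# ocevel

Wave-based optical coherence elastography (OCE) estimates the stiffness
of skin and tissue-mimicking phantoms by imaging a travelling surface
acoustic wave (SAW) with phase-sensitive OCT and measuring its speed.
`ocevel` implements that velocity stack end to end for people building
or validating OCE processing pipelines:

- **`ocevel.synthetic`** — a raw-data simulator: wrapped speckle-phase
  volumes (depth × lateral × time) carrying SAW packets launched by a
  2 kHz square-wave actuator at a known ("oracle") velocity, with
  attenuation, phase noise and motion artifacts.
- **`ocevel.preprocess`** — cropping to the region of interest and the
  affine phase normalisation φ/π·0.5 + 0.5 onto [0, 1].
- **`ocevel.wavefield`** — consecutive-A-line phase differences to
  axial displacement (d = Δφ·λ/4πn), then f–k directional filtering,
  zero-phase 2 kHz low-pass, (1, 11, 5) median filtering and
  per-particle normalisation.
- **`ocevel.tof`** — conventional time-of-flight velocity estimation:
  main-peak tracking and robust least-squares slope fitting per depth
  layer (V = Δx/Δt), up to 300 layers.
- **`ocevel.vpnet` / `ocevel.train_eval`** — VP-Net, a lightweight CNN
  (convolution–batchnorm–ReLU stages with depthwise-separable blocks
  and squeeze-and-excitation gates, S/B/L size variants) that regresses
  the SAW velocity directly from a single normalised raw phase slice;
  Adam/MAE training with early stopping, grouped MSE/MAE evaluation,
  and regression Grad-CAM driven by the predicted velocity. Runs on a
  small built-in numpy layer engine with explicit backprop — no deep
  learning framework required.
- **`ocevel.elasticity`** — Young's modulus under the Rayleigh
  surface-wave model, E = 2ρ(1+ν)³/(0.87+1.12ν)²·V² ≈ 3.35·V² kPa for
  skin (ρ = 1.02 g/cm³, ν = 0.5).
- **`ocevel.workbench` + the `oce` CLI** — HDF5 volume I/O,
  checkpoints, provenance-hashed CSV artifacts, and subcommands
  `simulate | preprocess | wavefield | groundtruth | train | predict |
  gradcam | elasticity | model | pipeline`.

## Worked example

Simulate a 5 m/s acquisition, extract the wave field, estimate the
velocity by time of flight, and convert to a modulus:

```python
from ocevel import (ScanGeometry, SimConfig, simulate_volume,
                    displacement_pipeline, profile_volume,
                    velocity_to_modulus, SKIN_COEFFICIENT_KPA)

geo = ScanGeometry()                     # 4.7/21.7 um px, 92 kHz, 1310 nm
cfg = SimConfig(velocity_mps=5.0, depth_px=12, lateral_px=256,
                time_px=320, noise_sigma_rad=0.2, n_pulses=1, seed=7)
vol = simulate_volume(cfg, geo)          # wrapped phase, oracle v = 5 m/s
slices, tags = displacement_pipeline(vol.phase, geo)
profile = profile_volume(slices, geo)
mean_v, std_v = profile.summary
print(f"TOF velocity over {len(profile.converged())} layers: "
      f"{mean_v:.3f} +/- {std_v:.3f} m/s")
print(f"modulus: {velocity_to_modulus(mean_v, coefficient=SKIN_COEFFICIENT_KPA):.1f} kPa")
```

prints

```
TOF velocity over 12 layers: 5.011 +/- 0.007 m/s
modulus: 84.1 kPa
```

i.e. the estimator recovers the simulated 5 m/s within 0.3% on every
depth layer, and the Rayleigh conversion (3.35·V²) turns it into a
bulk Young's modulus in kPa.  The same conversion applied to a
published palm cohort mean of 6.78 m/s gives 154 kPa.

The CLI mirrors the same flow:

```sh
oce simulate --config sim.yaml --out vol.h5 --seed 3
oce wavefield --in vol.h5 --out disp.h5
oce groundtruth --in disp.h5 --out labels.csv
oce model summary --variant B
```

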