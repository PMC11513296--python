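# Methods

## The problem

Wave-based optical coherence elastography (OCE) measures tissue
stiffness by launching a surface acoustic wave (SAW) with a small
actuator and imaging its propagation with phase-sensitive OCT.  The
wave's lateral speed V (m/s) relates to the Young's modulus E of the
medium through the Rayleigh surface-wave model; for skin the working
relation is E[kPa] = 3.35 V².  The package implements the full velocity
stack: a synthetic raw-data generator with known wave speed, the
conventional time-of-flight (TOF) estimator used to produce ground
truth, a lightweight CNN (VP-Net) that regresses velocity directly from
single raw phase slices, and the elasticity conversion.

## Synthetic acquisitions

Real raw OCE volumes of skin and phantoms are not publicly deposited,
so every stage is validated against a simulator with an exact oracle.

The simulated acquisition mirrors an M-B protocol: a volume indexed
(depth, lateral, time) of wrapped interferometric phase, default
512×512×512, axial pitch 4.7 µm, lateral pitch 21.7 µm, A-line rate
92 kHz, source wavelength 1310 nm.  A square-wave drive at 2 kHz (duty
cycle 60%) launches one SAW packet per rising edge.  Each packet is a
Gaussian-windowed cosine peaked exactly at its arrival time, so the
space–time argmax ridge of a noiseless field has slope 1/v(x) in
physical units; piecewise media (a stiff lesion inside softer skin)
integrate 1/v along the path so the ridge is continuous and changes
slope at the boundary.

Numerical choices that matter:

- **Packet width.** Envelope σ = 0.25 ms at a 1 kHz centre frequency.
  Consecutive-A-line phase differences measure the *temporal
  derivative* of displacement, so both the packet and its derivative
  must survive the 2 kHz low-pass of the wave-extraction chain; a
  narrower envelope puts derivative energy above the cutoff and the
  filter destroys the trackable ridge.
- **Onset delay.** The first rising edge is delayed by 3σ so the packet
  of the lateral position nearest the actuator lies fully inside the
  window and its (earlier-peaking) derivative is not truncated.
- **Phase encoding.** phase = wrap(φ₀ + c·d + ε + m(t)) with a static
  speckle offset φ₀ ~ U(−π, π) per (depth, lateral) column, i.i.d.
  Gaussian phase noise ε (default σ = 0.2 rad), an optional bulk-motion
  term (slow drift ≤ π, or ≤ 2 step jumps), and c scaled so the peak
  modulation equals `amplitude_rad` (default 1.5 rad; the physical SAW
  amplitude is not published, and 1.5 rad is a typical near-actuator
  modulation for this class of system).  Everything is reproducible
  from one integer seed.

What the generator does *not* emulate: OCT intensity speckle and
depth-dependent SNR, viscoelastic dispersion (velocity is frequency
independent here), guided/Scholte modes, and reflected waves (the
directional filter is therefore validated on analytic plane waves).
Passing tests show the processing chain is correct under this model;
they do not certify performance on real tissue.

## Wave extraction and time-of-flight estimation

Fixed processing order per volume: consecutive-A-line phase difference
(wrapped into [−π, π]) → axial displacement d = Δφ·λ/(4πn) with
n = 1.38 → f–k directional filter → zero-phase 4th-order Butterworth
low-pass at 2 kHz → 3-D median filter, kernel (1, 11, 5) in (depth,
lateral, time) → per-particle normalisation (each lateral column
divided by its temporal maximum; columns with max ≤ 1e−12 are flagged
dead).  The median kernel is 11 lateral × 5 time within each depth
layer (depth extent 1), preserving depth-local velocity; a depth
extent can be configured when cross-layer smoothing is wanted.

**Directional filter.** The 2-D FFT over (lateral, time) separates
propagation directions by the sign pairing of spatial and temporal
frequency; rejected-quadrant coefficients are zeroed and the real part
of the inverse transform returned (a projection, hence idempotent).
Two numerical guards matter:

- Nyquist rows/columns pair with themselves under conjugation and are
  kept (masking half of them would break Hermitian symmetry).
- A ±3-bin spatial-frequency *guard band* around DC is kept in both
  directions.  At SAW wavelengths comparable to or longer than the
  lateral aperture (e.g. 16 m/s at 1 kHz gives λ ≈ 16 mm against a
  ≈ 7 mm aperture) direction is not resolvable, and hard-masking the
  near-DC window leakage of a legitimate forward wave skews its
  wavefront — measured as up to +44% TOF bias at 16 m/s without the
  guard, < 0.7% with it.  Backward waves with resolvable wavelengths
  are still suppressed by > 60 dB.

**Edge trim.** Zero-phase filtering leaves transients at the first/last
time samples that can exceed the wave peak under noise; the pipeline
zeroes min(nt/6, fs/2f_c) samples at each end before normalisation so
argmax tracking cannot land on them.

**TOF fit.** The main peak is the temporal argmax of the normalised
displacement per lateral position (ties break to the earliest sample —
first arrival).  When the excitation repeats, the search is confined to
one inter-pulse interval (46 samples at the default rates) after the
earliest detected arrival, preventing ridge aliasing between packets.
Velocity is the inverse slope of a least-squares fit of peak time on
lateral distance, fit in index units and converted once through the
scan geometry (1 sample/px ⇔ 1.9964 m/s at defaults).  The fit is
refined iteratively: residuals beyond 3× the median absolute deviation
are discarded and the line refit until the relative slope change drops
below 1e−6 or 300 iterations.  Non-positive slopes yield non-converged
estimates with a diagnostic.  Depth profiling processes at most 300
layers from the surface down; a lateral window restricts fitting to a
lesion region.

## VP-Net

Input: one 320×320 (lateral × time) raw phase slice mapped affinely
from [−π, π] to [0, 1] (φ/π·0.5 + 0.5).  Output: one non-negative
velocity (inference clamps at zero).  The stack is
CBR1(11×11, stride 4) → CBR2(3×3, 1) → CBR3(7×7, 2) → separable + SE →
CBR4(7×7, 2) → separable + SE → CBR5(3×3, 1) → separable + SE → global
average pooling → 1 linear unit, where CBR is convolution → batch norm
→ ReLU, a separable block is depthwise 3×3 + pointwise 1×1 (channels
preserved, each with BN+ReLU), and SE is a squeeze-and-excitation gate
with a C/4 bottleneck.  Each separable+SE pair follows the CBR block
whose channel count it matches — the only placement consistent with
channel preservation and the published filter schedules.  Variants:
S = {16,16,16,32,64}/{16,32,64}, B = {16,16,32,64,128}/{32,64,128},
L = {32,32,64,128,256}/{64,128,256}; parameters and multiply–adds
order strictly S < B < L.

No deep-learning framework is used: the package carries a small NHWC
layer engine (im2col convolution, depthwise convolution, batch norm,
SE gating, Adam) with explicit backward passes, each verified against
central-difference gradients to ~1e−10 in the test suite.  Engine
conventions: "same" padding everywhere (keeps the stated stride
arithmetic 320→80→40→20 exact), He-normal initialisation from a fixed
seed, no conv biases (BN follows), BN ε = 1e−3 and running-statistics
momentum 0.9 (responsive at CPU-scale step counts), Adam ε = 1e−7.

Training: Adam at 1e−3, batch 32, MAE loss
(squared error destabilises this regression), early stopping when
validation MAE has not improved for 30 epochs, best-epoch weights
restored (ties to the earlier epoch).  Train/validation/test splits are
partitioned by acquisition id; the split and evaluation guards assert
disjointness.

**Grad-CAM for regression.** The differentiated quantity is the
predicted velocity itself.  Channel weights are spatial means of
∂v̂/∂A over the probed activation; the map is ReLU(Σ w_k A_k),
bilinearly upsampled and min–max normalised for the overlay.  Probes
address either a CBR block ('cbr1'…'cbr5') or a convolution index
('conv1', 'conv3', …) counted over standard convolutions including
pointwise but not depthwise layers — under that enumeration
conv1/3/5/7 are exactly the CBR1/CBR3/CBR4/CBR5 convolutions.

## Desk-scale study conditions

CPU-scale checks train VP-Net-S on 48×48 slices.  These sample the
*same physical field of view* as the full-scale 320×320 crop at 320/48
coarser lateral pitch (145 µm/px) and A-line rate (13.8 kHz): the wave
pattern per slice is preserved, the pixel count is 44× smaller, and the
ridge slope in pixels per sample — hence the velocity mapping — is
unchanged.  The training corpus draws one velocity per acquisition
uniformly from 2–16 m/s (the published phantom + skin range) with
phase noise σ = 0.3 rad.

Crops are deterministic (trigger-locked), as in the real system: the
actuator drive is synchronous with the scan and the preprocessing
window is a fixed constant, so wave arrival times are reproducible
across acquisitions.  This anchor matters: with randomised crop
offsets the absolute arrival-time cue disappears, and at this data
scale the network falls back to memorising per-acquisition speckle
(validation error stays at the mean-predictor level), while a coherent
classical estimator — which needs no anchor — still recovers the
velocity.  The deterministic window restores the cue the network
actually exploits, and held-out error then drops well below 1 m/s.

## Elasticity conversion

E = 2ρ(1+ν)³/(0.87+1.12ν)² · V², E in kPa for V in m/s with ρ in
kg/m³.  At skin defaults (ρ = 1020 kg/m³, ν = 0.5) the exact
coefficient is 3.367; the OCE literature quotes and applies 3.35, which
the package exposes as a named constant and uses for worked examples so
published moduli reproduce exactly (3.35·6.78² → 154 kPa).  Cohort
moduli are reported either from the mean velocity (default; std
propagated through the quadratic) or per slice then summarised — the
two differ for dispersed cohorts because E is nonlinear in V, so the
mode is always recorded next to the numbers.

## Known limitations

- The directional filter cannot reject counter-propagating waves whose
  wavelength exceeds roughly a third of the lateral aperture (the guard
  band passes both directions there).
- TOF accuracy at high velocity is aperture-limited: at 16 m/s the
  wavefront crosses the 320-px window in ~20 samples, so single-sample
  ridge distortions approach the 2% error budget.  In particular the
  (1, 11, 5) median filter interacts with a lateral amplitude gradient:
  with 0.1/mm lateral attenuation the 15–16 m/s estimates acquire a
  +2–3% bias (the chain without the median stays below 1%).  Oracle-
  equivalence checks therefore use attenuation-free homogeneous media;
  velocity estimates in strongly attenuating media should be read with
  this bias in mind.
- The simulator's speckle gauge (an i.i.d. uniform phase offset per
  column) is the hardest part of the learning problem; see the scaled
  learning analysis in this note and the acceptance suite.
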