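# Methods

This note records the models behind `opmsim`, the defaults and why they
were chosen, what the synthetic data does and does not emulate, and the
numerical choices a user should know before trusting or extending the
package.

## Sensor model

A triaxial OPM is modelled per sensor in its local frame (X, Y tangential,
Z radial). In **open loop**, each axis reads

    m_axis = G(|B_dc|) · B_axis + c · B_b,i · B_b,j / γ ,

where γ is the half-width of the zero-field resonance,
G(|B|) = γ² / (γ² + |B|²) is the Lorentzian gain suppression of the
zero-field resonance, B_dc is the quasi-static field (first-order low-pass
of the total field at 1 Hz, so the MEG-band signal does not suppress its
own gain), and the bilinear term is the cross-axis projection error
(CAPE): the product of the two *orthogonal* slow components (i, j ≠ axis)
scaled by a dimensionless coefficient c. Samples where any true axis field
exceeds the ±1.5 nT dynamic range are clamped and flagged "railed" rather
than set to NaN, so downstream segment counting still works.

The full spin dynamics of a real cell follow the Bloch equations; the
Lorentzian form is the standard zero-field-resonance approximation and
reproduces the qualitative behaviour that matters here (gain falling
monotonically with background, halving exactly at |B| = γ). The true
linewidth and CAPE magnitude of commercial triaxial sensors are not
public: the defaults γ = 10 nT and c = 0.1 are placeholders of the right
order, and quantities that depend on them (e.g. the open-loop sweep error)
are validated only through monotonicity and ordering properties, never
against a numeric target.

In **closed loop**, on-board coils null the cell field by negative
feedback; with the default ideal loop the output equals the true field
exactly for any field within the ±50 nT coil range, and samples beyond it
are flagged out-of-range. An optional finite loop bandwidth low-passes the
compensation field (single pole) and reads the residual through the
small-signal open-loop response; it converges to the ideal loop as the
bandwidth grows. Sensor noise is white at 15 fT/√Hz (per-sample std
= density · √(fs/2)); no 1/f shoulder is modelled because only a
band-median density is specified for the real sensors.

## Forward models

The phantom is a closed single-turn triangular coil (isosceles, 5 mm base,
45 mm height, area 1.125e-4 m²) evaluated with the exact finite-segment
Biot–Savart formula; a quadrature oracle and the far-field point-dipole
limit (m = I·A) verify it in the tests. The coil is attached like a sensor
casing in the helmet: centroid 45 mm radially inward of a designated slot,
normal along the local radial direction. This reproduces the few-hundred
picotesla scale at the best-coupled channel for a 1 mA drive.

Neural sources are current dipoles in a homogeneous conducting sphere
(centre at the origin, radius 8 cm), evaluated with the Sarvas closed
form. The sphere is a deliberate stand-in: it is the minimal standard
conductor for MEG and sufficient for synthetic validation; realistic
(BEM/FEM) conductors and co-registration are out of scope. Consequences
used by the code: radial dipoles are externally silent, so lead fields are
built for two tangential orientations only (Gram–Schmidt against the
global x-axis, y-axis fallback at the pole), and a dipole at the exact
sphere centre produces no external field at all — such voxels get zero
beamformer weights and an invalid mark rather than an error.

The synthetic helmet places sensors on a golden-angle lattice covering the
upper three quarters of a sphere of radius head_radius + standoff
(default 0.09 + 0.015 m); the seed fixes the azimuthal registration.
It is a stand-in for the 3D-printed helmet geometry, which is not
published; only quasi-uniformity, triad orthonormality and determinism are
relied on.

## Synthetic sessions

The generator's defaults are the study conditions of the protocols it
emulates:

- **Visuo-motor paradigm**: 60 circle trials (1 s stimulus), 120 face
  trials (0.5 s), 25 catch trials (0.8 s), pseudo-random order, each
  followed by a rest of 1.25 s jittered uniformly by ±0.2 s. The printed
  total of 396 s is reproduced in expectation only if catch trials share
  the jittered rest, so they do (the source protocol leaves this
  unstated). The jitter distribution is likewise unstated; uniform is
  assumed.
- **Phantom linearity**: the printed amplitude list has nine values but
  the stated count is 8 × 8 = 64 measurements; eight levels are used by
  default (0.08 mA dropped, configurable).
- **Background sweep**: "0 to 8 nT in 81 steps of 0.1 nT" is read as 81
  levels inclusive of both ends, since 81 × 5 bursts = 405 matches the
  stated measurement count. The background is uniform and vertical; each
  burst is 2 s of 17 Hz (exactly 34 cycles) followed by 1 s off.
- **Sitting-to-standing**: 8-s trials with alternating stand/sit cues;
  during the first 4 s each sensor sees a smooth (Hann) background
  excursion of peak 2 nT along a per-sensor random direction drawn once
  per session, and bilateral sensorimotor dipoles desynchronise in the
  beta band (depth 0.4 by default). The per-sensor directions are a
  modelling choice: the field a moving helmet actually experiences is
  unknown and direction-dependent. The default 20 trials keeps a
  desk-scale session (~160 s) while leaving enough averaging for the
  beta contrast; the trial count of the original task is not stated.

Oscillatory sources are band-passed Gaussian noise with a multiplicative
trigger-locked envelope (raised edges, 0.1–0.25 s); evoked sources are
Gaussian-windowed sinusoids (σ = 40 ms) peaking at a 170 ms latency.
These are minimal processes with the assumed spectral structure. What the
generator does **not** emulate: cortical geometry and source extent,
correlated environmental interference, movement artefacts beyond the
uniform transient, gain-calibration drift, cross-talk between on-board
coils, reaction-time variability. Passing tests therefore demonstrate the
correctness and internal consistency of the analysis chain under the
assumed physics — not performance on real data.

## Analysis choices

- **Filters**: zero-phase (forward–backward) IIR; 2nd-order notches at
  50/100/150 Hz (Q = 30) and a 4th-order Butterworth band-pass 1–150 Hz.
  Only the bands are prescribed by the emulated pipeline; the realisation
  is ours.
- **Bad-channel/-trial rejection**: the original workflow used visual
  inspection; reproducibility requires automation, so channels are
  rejected at band-averaged (3–100 Hz) noise density above median +
  5·MAD (or below a dead floor of 1 fT/√Hz), trials at peak amplitude
  above median + 6·MAD. Thresholds are declared, not inferred.
- **HFC**: orthogonal projection I − N(NᵀN)⁻¹Nᵀ with N the 3-column
  orientation matrix — homogeneous components only, no gradients. The
  projector is idempotent and annihilates any uniform field exactly;
  with the default helmet a central dipole topography retains ≳95% of
  its norm.
- **Covariance**: band-passed, mean-removed, all trials concatenated;
  regularised by adding 1% of the maximum eigenvalue to the diagonal.
- **Beamformer**: scalar LCMV; the tangential orientation minimises
  lᵀC⁻¹l (maximising output power) via the closed-form 2×2 eigenproblem;
  weight sign is fixed by the orientation's first non-zero component so
  repeated runs agree in polarity.
- **Pseudo-T**: (P_a − P_c)/(P_a + P_c). The emulated pipeline does not
  print its normalisation; this form is bounded, needs no separate noise
  estimate, and is antisymmetric in the windows. Voxels with zero total
  power are flagged invalid.
- **Pseudo-Z**: |trial-averaged beamformed amplitude at one latency|
  divided by √(wᵀΣw) with Σ = (0.01·λ_max)·I, the regularisation-scaled
  identity noise model; the emulated pipeline's noise estimator is
  likewise unpublished.
- **TFS**: 5-Hz-wide bands stepped by 2.5 Hz spanning 1–150 Hz (band set
  configurable; the original band set is unpublished); envelope per band
  and trial, trial-averaged, baseline-corrected as relative *amplitude*
  change (a power option exists — the emulated description mixes the two
  terms). 0.25 s reflection padding precedes each Hilbert transform;
  conclusions should not rest on the padded edges. Bands with zero
  control-window power are flagged invalid, not infinite.
- **Burst amplitudes**: 2 s windows hold exactly 34 cycles of 17 Hz, so
  the amplitude is the exact-bin DFT magnitude scaled by 2/N (a pure
  sinusoid of amplitude A reports A; the convention is recorded in the
  sidecar). Background error is the *absolute* percent deviation from the
  channel's zero-background mean — the reported mean ± sd of the emulated
  experiment is positive, so the unsigned reading is the default and a
  signed option exists. Errors are pooled over channels, bursts and
  non-zero levels (rather than averaged per level first); the top-10
  channels are selected once, from zero-background closed-loop
  amplitudes, and reused for the open-loop condition.

## Numerical and testing notes

- Windows are half-open [t0, t1), 0-based, floor-rounded to samples —
  stated once, used everywhere (segmentation, power windows, latencies).
- Determinism: every stochastic stage takes an explicit seed;
  identical seed + config give bit-identical recordings and byte-identical
  TSV outputs. Burst counts depend only on the protocol, never the seed.
- Tests run on reduced arrays (8–16 sensors) and targeted 4-mm region-of-
  interest grids; the protocols, windows, bands and regularisation are the
  full-scale defaults throughout. The acceptance script uses the full
  64-sensor helmet.
- Null-fluctuation checks assert distributional statistics (RMS, band
  means, pooled percentiles) rather than pointwise extremes, which grow
  with the number of bands × samples examined.
- The open-loop sweep error (strongly dependent on the unpublished γ, c
  and the exact helmet geometry) is checked only for monotone growth with
  the background range; the closed-loop error is checked against its
  noise-limited bound.

## Known limitations

Single-sphere conductor and point dipoles; helmet geometry is synthetic;
the open-loop model is a one-parameter resonance, not a Bloch-equation
solution; noise is white and uncorrelated across channels; no
co-registration error, no EEG, no realistic movement trajectories. These
bound what can be concluded from this package to the methodology itself.
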