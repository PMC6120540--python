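# Methods

This note documents the models, numerical choices and limitations of
`dscflair`.  Empirical statements below are all reproduced by the test
suite or by `scripts/acceptance.py`.

## Base sequence and power model

The readout is a 3D-FSE train of 192 hard pulses of 0.8 ms: a 90°
excitation (phase 90°, CPMG convention with refocusing about x) followed by
191 refocusing pulses with 3 ms echo spacing, TR 8 s, TI 2250 ms, centre of
k-space at echo 100.  The vendor's initial flip-angle ramp is not public;
we model it as a geometric descent from 140° reaching the constant 50° at
pulse 14, which aligns the ramp with the 13 individually shimmed pulses of
the reduced parameterization.  Both the ramp shape and its length are
configuration parameters; none of the power or homogeneity conclusions
depend on the exact ramp because the ramp pulses carry 13 of 192 pulses'
power and the signal reaches its pseudo-steady state within a few pulses.

Hard pulses have peak amplitude `b = flip_rad / (γ·duration)` and
`t_RMS = duration`.  Per-channel average power is
`Σ_j |w_jk b_j|² t_RMS,j A / TR` and per-pulse peak power `|w_jk b_j|² A`
with `A = 0.35 W/µT²`.  The preparation module is transmitted in quadrature
and contributes a constant 0.34 W (4-pulse T2-prep; 0.15 W for the 2-pulse
variant) of average power per channel, which is subtracted from the 1 W
average budget available to the readout optimization.  Whether that offset
is per channel or summed is not documented for the original system; it is
implemented per channel (the conservative reading) and configurable.

## EPG engine

The echo train is simulated in the extended-phase-graph basis
(F⁺_n, F⁻_n, Z_n) with the standard RF mixing matrix, order-shifting
crusher operator and relaxation with recovery of Z₀.  Each echo period is
two half-periods of relaxation + dephasing around the refocusing pulse; the
echo is |F₀| after the second half-period.  Choices:

- **Truncation.** Orders are kept up to K = N_p by default.  Amplitude can
  only climb one order per shift and each non-refocused passage is damped
  by cos²(α/2) ≤ 0.82 at 50°, so amplitude that would return from beyond
  K = 192 is < 1e-10; the engine agrees with a 1024-isochromat Bloch
  ensemble to better than 1e-6 (in practice ~1e-15).  During optimization
  only, K is truncated (default 48) for speed; final predictions and all
  metrics use the full-order engine.
- **Magnitude echoes.** The optimized quantity is |F₀|: echo phase is
  receiver-corrected in practice and a complex-valued comparison would
  penalize harmless global phase.  The forward model is phase-equivariant,
  which the tests assert.
- **Instantaneous pulses.** Readout pulses (0.8 ms) are treated as
  instantaneous rotations; B0 off-resonance is excluded from the readout
  model because these pulses are broadband (>1 kHz) relative to realistic
  off-resonance, while relaxation is applied over the full echo spacing.
- **z₀.** The longitudinal magnetization entering the train defaults to 1
  so the readout model is testable in isolation; the FLAIR chain passes the
  preparation-derived value per tissue.

The independent validation oracle is a Bloch simulation of a uniformly
dephasing isochromat ensemble (Rodrigues rotations on magnetization
vectors, 2π of crusher dephasing per half period).  It shares no state
representation with the EPG engine and converges to it as the ensemble
grows; a single isochromat demonstrably does not reproduce the EPG signal.

## Magnetization preparation

T2-prep (hard 90° tip-down, 2 or 4 adiabatic hyperbolic-secant refocusing
pulses at CPMG spacings, hard −90° tip-up, transverse magnetization then
spoiled) converts the CSF/brain T2 difference (2 s vs 50 ms) into a
longitudinal difference before the adiabatic inversion, letting brain
tissue recover from near zero while CSF is nulled at TI.  Pulse parameters:
refocusing sech 9 ms / 15 µT / 706 Hz, inversion 17.1 ms / 15 µT / 700 Hz.

Numerical choices: sech truncation β·duration/2 = 5.3 (edge amplitude ≈1%
of peak, the standard full-passage parameterization); frequency modulation
realised as phase modulation in the fixed rotating frame; piecewise-
constant Rodrigues integration at dt = 5 µs (halving dt changes the
inversion result by <1e-4, asserted); relaxation interleaved per step.
Hard 90° pulses are instantaneous (their durations are not public) and
scale with the local B1.  The T2-prep total duration is likewise not
public; default 100 ms, configurable.  MLEV phase cycling of the
refocusing pulses is not modelled; even so the 2-pulse module shows the
larger off-resonance sensitivity of CSF Mz at low B1 (measured as total
variation over a ±300 Hz sweep), which is the mechanism behind the
fringe-like CSF artefacts of the 2-pulse variant.

A full FLAIR period chains T2-prep → inversion → TI recovery (TI measured
from the inversion-pulse centre to the excitation) → EPG readout (the Z₀
trajectory of the engine, so the train's saturation of longitudinal
magnetization is modelled) → free recovery to the end of TR.  Steady state
is reached when one further period changes the pre-inversion Mz by less
than the tolerance (1%); the reported period count is the number of periods
needed to reach that reproducible state.  At nominal fields CSF converges
in 2 periods with Mz ≈ +0.013 entering the readout (nulled), brain tissue
at ≈ +0.75.

## Shim optimization

Variables are the real and imaginary parts of the reduced shim matrix
(16×8 complex = 256 real).  The cost is the C-weighted squared deviation of
predicted echo magnitudes from the target; its gradient is computed by an
adjoint (reverse) sweep of the EPG recursion — every forward operator is
real-linear on the stacked states, so the adjoint applies the conjugate
transposes in reverse order while accumulating per-pulse sensitivities of
the RF mixing matrix to flip and phase.  The adjoint gradient matches
central finite differences to ~1e-10 relative error (asserted on a toy
problem) and costs two forward passes instead of 512, which is what makes
desk-scale optimization practical.  Finite differences remain available as
the verification oracle.

The echo weighting ramps linearly from 0 at the first echo to 1 at echo
100 and back to 0 — a pure linear ramp with maximum at the centre of
k-space.  A nonzero floor is configurable but defaults to 0: because the
early-train echo amplitudes are an order of magnitude larger than the
centre echo, any appreciable floor lets the early echoes dominate the
absolute-deviation cost and the optimizer then trades centre-echo
homogeneity (the quantity imaging cares about) for early-echo fidelity.

Constraints are convex quadratics in the reduced weights (per-channel
average power with the preparation offset subtracted, and per-row peak
power caps); they are handled natively by scipy's interior-point style
`trust-constr` solver with analytic Jacobians.  The start is all entries
0.6 (scaled quadrature, comfortably feasible; automatically rescaled if a
tight budget makes it infeasible).  The returned weights are projected to
strict feasibility (scaling any offending row/column down) and the solution
never exceeds the initialization cost.  Termination: 120 iterations default
or solver tolerances (xtol 1e-10).  Determinism: the whole pipeline is
deterministic given the inputs; repeated runs are bitwise identical.

For speed the optimization thins the masked voxels to at most
`max_opt_voxels` (default 250, evenly strided); predictions and metrics
always use the full mask.  Subsampling below ~150 voxels risks overfitting
the 128 complex degrees of freedom to the subset, visible as degraded
full-mask CoV — the default keeps roughly a 2:1 voxel-to-DOF margin.

The static baseline is magnitude least squares via variable exchange:
alternating phase-target updates with a convex constrained least-squares
solve (SLSQP) under the per-channel amplitude caps that the power limits
reduce to for a pulse-independent shim.  The magnitude target defaults to
the mean quadrature combination over the mask (the original target level is
not documented).  Universal solutions concatenate the (thinned) sensitivity
matrices of a training cohort and run the identical optimization.

## Synthetic fields

The generator emulates the statistical structure of measured 8-channel 7T
head data, not the electromagnetics: Gaussian-lobed channel amplitudes
around azimuthal ports with propagation-like phase advance, a
constructive-interference envelope that peaks at the head centre, smooth
per-channel perturbations, and an ellipsoidal single-component mask.  The
inferior-posterior "cerebellum-like" dropout is a destructive-interference
null — channel phases twisted apart inside a smooth bump, calibrated by
bisection so the in-mask minimum of the quadrature magnitude is exactly
`dropout_depth` (default 0.35) of the centroid value.  Modelling the
dropout as interference rather than common-mode attenuation matters: a
common-mode loss is unrecoverable by any shim, whereas interference nulls
are recoverable by re-phasing, which is the regime real arrays are in.
B0 maps are low-order polynomials plus one or two localized blobs near the
inferior-frontal boundary, clamped to ±300 Hz.  Cohorts vary head size
(±10%), channel gains (±15%) and dropout depth per subject with seeds
derived from the base seed.

What passing tests on these fields do **not** show: performance on measured
maps with coil-specific interference patterns, susceptibility-induced B0
structure, real tissue geometry, CSF pulsation/inflow, or scanner
calibration errors.  The synthetic cohort establishes that the machinery —
model, gradients, constraints, baselines and metrics — behaves as the
method requires, with effect directions (DSC ≫ quadrature ≈ static;
universal intermediate) matching the in-vivo findings.

## Problem sizes

Defaults are desk-scale by design: 24³ grids at 8 mm synthetic voxels
(≈3700 masked voxels; optimization thins to ≤250), EPG truncation K = 48
during optimization, 60–120 optimizer iterations.  The acceptance script
and the cohort tests use these sizes; all quality metrics are always
evaluated on full masks with the full-order engine.

## Known limitations

- No diffusion, flow, magnetization transfer or slice-profile effects in
  the EPG; no SAR-matrix constraints (power limits are the surrogate).
- The preparation timing (T2-prep duration, hard-pulse lengths, exact TI
  bookkeeping around the inversion pulse) follows plausible defaults where
  the vendor values are unpublished; CSF nulling quality at steady state
  depends weakly on these.
- The static-shim target level and the echo-weighting floor are design
  choices exposed in configuration, as the original values are not public.
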