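# Methods

This note records the models, parameter choices and numerical decisions
behind `repimap`, in the package's own words.

## Trajectory model

A single-shot readout acquires one full ky line per echo-spacing
interval `esp`; the trajectory is the ordered list of (time index, ky
index, echo label) triples.  Two principles constrain a valid
blip-rewound (rEPI) assignment: every echo image samples ky with the
same constant stride `n_echoes * R` (so all echoes share one
distortion), and no ky line is acquired twice (so the joint
reconstruction sees every acquired line once).  Requiring additionally
that each echo's samples be collinear in ky-t with parallel lines
offset `dte_factor * e` echo spacings leaves exactly two assignment
families for 2-3 echoes:

* **interleaved** (time stride `n_echoes`, |slope| `R` ky per line):
  solvable when start-slot and ky-offset permutations `m`, `u` satisfy
  `m_e - u_e = dte_factor * e + const`; this has solutions for
  `dte_factor = 2` at any echo count and `dte_factor = 1` at odd echo
  counts only;
* **sequential** (me-EPI-like blocks with complementary ky classes, the
  "one large rewinder" limit): nominal echo-time spacing equals the
  block length, so it applies exactly when `dte_factor = n_pe /
  (n_echoes * R)`; the sub-echo-spacing jitter introduced by the ky
  offsets (< 1 line time) is ignored by convention, the same convention
  under which a sequential multi-echo readout's dTE is quoted as
  `(n_pe/R) * esp`.

Consequences verified by brute-force enumeration (tests): 2 echoes with
`dte_factor = 1` is infeasible at every matrix size; 3 echoes with
`dte_factor = 3` is feasible at 9 lines and admits several inequivalent
assignments.  Assignments related by time reversal combined with ky
mirroring describe the same physical readout played backwards with
opposite blip polarity and are counted once.  When several assignments
remain, the constructor picks the one minimizing total |Δky| travelled
(smallest rewinder blips, smallest eddy-current burden), ties broken by
lexicographic ky order.

Sign conventions: off-resonance phase accrues as `exp(+2πi·ΔB0·t)`;
with blip polarity +1 the ky index therefore descends with time so that
a positive field displaces signal along +ky, the standard statement of
the EPI shift.  The acquired stride-`R` ky lattice is anchored to
contain the center line `floor(n_pe/2)` — the line that forms the echo.
`TE_e = te1 + dte_factor·e·esp` with `te1` free (echo times are
hardware-determined on a scanner).

## Synthetic scanner

* **Phantom**: ellipse composite (outer shell, inner compartment,
  ventricle-like dark ellipse, two nodules) with ≥ 3 tissue classes,
  seed-jittered geometry, zero background.
* **Coils**: Gaussian lobes (width ≈ 0.55 FOV) on a ring around the
  FOV with smooth linear phases, sum-of-squares normalized to 1.
  These are deliberately *very* smooth: at per-echo undersampling 6 the
  per-pixel-group SENSE system is then severely ill-conditioned, which
  reproduces the strong residual aliasing an echo-by-echo
  reconstruction shows at that factor.
* **Field**: 2nd-order polynomial background ("shim residual") plus
  1-3 Gaussian blobs ("susceptibility foci"), combined and scaled so
  max|ΔB0| = 0.9 × the requested amplitude (default 60 Hz, the scale of
  frontal-sinus offsets at 3 T).
* **Acquisition**: for each trajectory line at physical time t the coil
  images `S_c·m·exp(2πi·ΔB0·t)` are Fourier transformed and the
  acquired ky row kept; i.i.d. complex Gaussian noise is added per
  sample.  Off-resonance is applied per line, not per ADC sample:
  readout-direction distortion is negligible at EPI bandwidths, and
  only phase-encode distortion is modelled (the standard EPI model).
  Geometric distortion therefore *emerges* from timing, and the
  image-domain pixel-shift model can be cross-validated against it
  (they agree to ≈ 3% NRMSE).
* **Noise level**: "SNR 40" means the complex noise SD per coil sample
  is 1/40 of the peak phantom magnitude; with SoS-normalized coils this
  is also the peak-signal-to-noise of a coil-combined echo image.
* **Motion series**: per-volume rigid pose (bilinear resampling); the
  per-volume field is the rigidly transported base field plus a
  pose-dependent linear gradient, `gain · rotation_deg` Hz at the FOV
  edge (default 2 Hz/deg).  This perturbation rule is synthetic: the
  physical rotation-susceptibility relationship is not modelled
  quantitatively anywhere, only its existence, smoothness and pose
  dependence, which is what dynamic mapping needs to demonstrate.
  Instructed-motion schedules draw pose magnitudes from the upper half
  of the configured range (a deliberate pose change, not jitter), with
  random sign, piecewise-constant over blocks.

What the simulator deliberately omits — T2*/T1 contrast between
echoes, Nyquist ghosts, ramp sampling, through-plane dephasing, coil
noise covariance, 3-D effects — bounds what passing tests show about
real data: in particular, late echoes of a *sequential* multi-echo
readout keep full SNR here, which flatters the long-dTE estimator
(see "Known limitations").

## Joint reconstruction

Unknown `x`: the coil-combined k-space of all echoes.  Data model
`b = M F S F⁻¹ x` per echo, with known sensitivities.  The echo and
coil structure is encoded in the block-Hankel matrix `H(G x)` of the
multi-channel augmentation `G = F S F⁻¹` (5×5 kernel, valid windows):
columns concatenate kernel-area × coil patches across echoes, rows
index window positions.

The rank-`r` constraint is handled by a multiplicative half-quadratic
(iteratively reweighted) scheme.  Each outer iteration (15 total)
eigendecomposes the Gram matrix of `H(G x_k)` and penalizes

    lam · || H(G x) · V diag(w)^{1/2} V^H ||_F²,
    w_i = eps / (sigma_i² + eps),   eps = sigma_r²,

a quadratic re-solved in `x` by conjugate gradient (10 inner
iterations, warm-started).  Established signal directions (σ ≫ σ_r)
are spared; weak directions are damped but may still grow — essential
here, because the uniform interleaved sampling makes a *hard*
rank-truncation alternation stagnate at the aliased initialization.
The solver is initialized from the union of all echoes' complementary
lines treated as a single image at factor `R` (a well-conditioned SENSE
problem, solved by a short Tikhonov-damped CG), replicated across
echoes — the echoes of one readout are nearly identical, which is the
premise of the whole method.

`lam` defaults to 0.005 *under this normalization* (data scaled to
unit peak zero-filled magnitude, weights bounded by 1); it is not
interchangeable with the regularization weight of other structured
low-rank codes.  Rank defaults to 40 for phantom-scale content.  Both
were calibrated once on the synthetic testbed at the nominal protocols
(66×66, 8 coils, 3 echoes, SNR 40) and then frozen.  Coil compression
(PCA across channels) is supported and reported with retained energy.

The SENSE baseline solves each echo separately per readout row and
aliased pixel group, with the sampling comb's exact point-spread
weights and Tikhonov 1e-4.

**Behaviour at per-echo factor 6 (R = 2).**  The joint reconstruction
recovers magnitude well (NRMSE ≈ 0.14 vs ≈ 0.6-2.9 for SENSE at SNR
40) and its phase-evolution maps are several times cleaner than
SENSE's, but the inter-echo phase is partially shrunk toward zero: the
echo-difference information lives in the most ill-conditioned SENSE
directions (6th singular value ~1e-4 with these smooth coils), where
any echo-coupling prior suppresses it.  Quantitative field mapping is
therefore evaluated at the R = 1 protocol (per-echo factor 3), where
recovery is accurate; at R = 2 the package reproduces the *ordering*
claims, not absolute field accuracy.

## Field mapping

`estimate_b0` chains: wrapped pairwise phase differences → (3 echoes)
phasor-mean averaging of the two equal-gap differences → 2-D
unwrapping → 4th-order polynomial smoothing → division by `2π·ΔTE`.

* The phasor mean `arg(e^{i d12} + e^{i d23})` equals the arithmetic
  mean whenever |d12 − d23| < π (guaranteed in the short-dTE regime)
  and has no seam discontinuity at ±π; a literal-mean mode exists.
* Unwrapping uses the reliability-sorted algorithm of scikit-image per
  connected mask component; each component is anchored by the integer
  multiple of 2π that brings its median into (−π, π].  The residual
  global 2π·k ambiguity is fundamental to any single-readout
  phase-difference estimator; at dTE = 1.52 ms the ambiguity step is
  658 Hz and never engaged, at dTE ≈ 49 ms it is 20.6 Hz and bites
  whenever the median field exceeds ≈ 10 Hz.
* The polynomial fit weights residuals by the echo product magnitude
  (applied directly, i.e. squared in the normal equations).
  Ideal-noise inverse variance would be the square root of this; the
  heavier weighting was adopted after observing that low-magnitude
  pixels carry *structured* reconstruction artifacts rather than plain
  noise, and it reduced field-map RMSE several-fold at SNR 40.
* Guards: the fitted phase is clamped to the range observed at
  well-weighted pixels (+25% margin), and outside the validity mask
  the polynomial is replaced by nearest-masked-value fill (smoothed) —
  a free degree-4 extrapolation to the FOV corners is unbounded and
  can fold the subsequent unwarp.
* Smoothing default is full fit replacement ("fit"), the behaviour of
  polynomial field-map regularization in standard unwarping tools;
  "fit_plus_residual" and "none" are config-gated.  The default mask
  keeps pixels above 5% of the robust (99th percentile) magnitude.

EPI-derived maps are tagged `space_tag="distorted"`; at the simulated
shift scales (≤ ~1.5 voxels) the distorted/undistorted distinction
changes the field by ≪ 1 Hz and no self-consistency iteration is
applied by default.

## Distortion model

`shift = ΔB0 · n_pe · esp / R · direction` voxels along PE.
Interleaving multiplies both an echo's line spacing in time and its ky
stride by `n_echoes`, leaving dt/dky — and hence the shift — equal to
conventional single-shot EPI at the same `R`.  Forward warp and
correction use 1-D columnwise linear interpolation with Jacobian
intensity modulation (cubic is not implemented; linear matches the
pixel-shift tools the pipeline emulates).  Fold-over (|dshift/dy| ≥ 1)
raises an error rather than resampling silently; the motion pipeline
smooths *estimated* shift maps just below that limit, as practical
unwarping tools do.  Round-trip fidelity is quoted on band-limited
images: a piecewise-constant phantom's discontinuities are not
representable under linear resampling, while an acquired (k-space
band-limited, lightly smoothed) image round-trips to < 2%.

## Motion pipeline

Per volume: joint reconstruction → SoS combination → per-volume field
estimate (dynamic) → unwarp.  The static comparator transports the
pose-0 ground-truth field rigidly with the known pose (standing in for
a separately acquired GRE map registered to each volume) but lacks the
pose-induced field change.  Series are re-registered with the known
inverse poses — the simulator replaces image registration.  Volumes at
pose transitions are excluded from temporal statistics (the simulation
knows the schedule; a frame-displacement detector would add nothing).
tSNR ratios are voxelwise ratios averaged over the mask.  Problem
sizes: 48×48, 6 coils, 16 volumes, blocks of 4, R = 1 — chosen so the
full study runs on a laptop-scale budget while keeping ≥ 3 volumes per
block after exclusion.

## Known limitations

* At per-echo factor 6 with smooth synthetic coils, absolute inter-echo
  phase recovery is structurally limited (see above); real multi-channel
  arrays provide more encoding diversity.
* Without T2* decay, a sequential long-dTE readout's later echoes are
  unrealistically clean, so the long-dTE estimator fails here only
  through its 2π·k anchoring ambiguity (median field > ~10 Hz), not
  through the low-SNR/unwrap failures that dominate in vivo.  In the
  50-trial comparison the short-dTE estimator wins ≈ 3/4 of trials,
  which understates its real-data advantage.
* 2-D single slice; no ghosts, ramp sampling, coil covariance or
  through-plane effects; registration is oracle (known poses).
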