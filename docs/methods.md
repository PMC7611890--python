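# Methods

## Problem

Parallel-transmit (pTx) MRI needs per-channel *relative transmit maps* —
the complex B1+ sensitivity of each transmit element, known up to a common
per-voxel factor — before subject-specific pulse design. Acquiring them
costs one image per transmit state, received on all channels, so scan time
scales with the transmit count and becomes the bottleneck in gated body
imaging. This package reconstructs those maps from *undersampled* k-space
without any calibration region, by exploiting the joint low-rank structure
of multi-transmit, multi-receive data.

## Signal model and Hankel tensor

The data are a fourth-order tensor `D ∈ C^(Nkx × Nky × NRx × NTx)`: 2-D
k-space for every (receive, transmit) channel pair. Sliding an `m × n`
kernel over all fully-interior positions of each k-space plane produces
the block-Hankel tensor `H = T(D)` with frontal slices of size
`N1 × N2`, `N1 = m·n`, `N2 = (Nkx−m+1)(Nky−n+1)`. Because every
channel-pair image is the same object modulated by smooth coil profiles,
three matricisations of `H` are strongly rank-deficient:

- `VC` `(N1·NRx·NTx) × N2` — each channel pair as a virtual receive coil;
- `RC` `(N1·NRx) × (N2·NTx)` — receive channels stacked vertically,
  transmit encodings horizontally (the PRIMO-style calibration matrix);
- `TC` `(N1·NTx) × (N2·NRx)` — the transmit/receive-swapped counterpart,
  which is *not* the transpose of `RC` since the frontal slices are
  unchanged by the swap.

The reconstruction problem is

    min_z  1/2 ‖M z − D‖_F²   s.t.  rank(U_c T z) = r_c ,

with `M` the per-encoding binary sampling mask. The TxLR method enforces
both the `TC` and `RC` constraints simultaneously; the VC and PRIMO
baselines enforce a single constraint (`VC` resp. `RC`).

## ADMM

The non-convex problem is solved by scaled ADMM with one consensus matrix
per active unfolding, everything initialised to zero. Per iteration:

1. consensus: `C_c = Γ_{r_c}(U_c T zⁿ − y_c)` where `Γ_r` is hard
   singular-value truncation;
2. over-relaxation: `C'_c = α C_c + (1−α) U_c T zⁿ`;
3. data block, in closed form because each unfolding is a unitary
   permutation and `T*T` is the diagonal map of kernel-coverage counts
   (`mult`, between 1 at corners and `m·n` in the interior):
   `z = (M∘D + ρ Σ_c T*(fold(C'_c + y_c))) / (M + n_c·ρ·mult)`;
4. duals: `y_c += C'_c − U_c T z`;
5. penalty: `ρ ← τρ` with the scaled duals divided by `τ`, so the
   unscaled dual `ρ·y` is continuous across the penalty change.

Defaults: `ρ₀ = 1e-6`, `τ = 1.1`, `α = 1.5`, kernel `[5,5]`, all rank
thresholds 50, 50 iterations (TxLR) or 100 (VC/PRIMO), on a 24×24 k-space
crop. Ranks at or above the short matrix dimension make `Γ_r` the
identity; degenerate but permitted.

Two placements of over-relaxation were considered. Relaxing the
data-block image `U_c T z` diverges here (error grows without bound by
~30 iterations at α = 1.5); relaxing the first-updated (consensus) block,
the standard choice for this update ordering, converges and is faster
than the unrelaxed iteration, which is the point of over-relaxation. At
`α = 1, τ = 1` the loop reduces exactly to the plain iteration, which the
tests verify against an independently coded reference.

The hard-threshold operator is exact and deterministic: thin SVD for
small matrices; for the large strongly rectangular unfoldings the same
rank-r projection is computed from an eigendecomposition of the Gram
matrix on the short side (agreement with the SVD route at the 1e-14
level, several times faster). No randomised sketching is used.

### Stopping

Fixed iteration counts are the default and are used for all quantitative
results. A chi-square rule is also provided: the statistic
`Σ_i ‖M z_i − D_i‖²/σ_i² / ν` (`ν` = number of sampled complex points
across all receive channels and encodings; `σ_i` the per-channel complex
noise SD, so a perfect reconstruction has expectation 1), halting at the
first iteration where it drops to ≤ 1. Note a structural caveat: because
`ρ₀` is tiny and the consensus starts at zero, the first data update
already sets `z ≈ D` at sampled points, so the sampled-point residual
starts *below* the noise floor and the rule can fire immediately; the
residual then grows toward the noise level as the low-rank constraint
denoises the sampled data. The rule is therefore most meaningful when
noise dominates the early misfit, and fixed iterations are preferred on
synthetic data. For the same reason the data misfit is *not* monotone
decreasing from iteration 1; the reconstruction error (RMSE) is the
quantity that decreases.

## Sampling

Per-encoding uniform-density Poisson-disc masks: greedy dart throwing
over a seeded permutation of grid points with a minimum-distance radius,
the radius bisected until the accepted count reaches `round(N/R)`, then
the acceptance tail trimmed to hit the count exactly (trimming cannot
violate the distance property). The DC sample (index `N//2`, FFT-shifted
convention shared by all modules) is always sampled — relative scaling
between encodings is otherwise lost. Each encoding uses an independent
spawned child of the master seed, so patterns differ across encodings
while the whole mask is reproducible from one integer. There is no
calibration region.

## Synthetic data

The generator emulates a body transmit-mapping acquisition:

- **Phantom**: torso-like ellipse with lungs (300 kg/m³), heart/liver
  (1060), muscle (1090), a 1000 kg/m³ fluid pocket, and vertebral bone
  (1900); pixel intensity equals tissue density, with densities > 1200 or
  < 400 displayed at 80 so bone and lung resemble their proton-density
  appearance. Organ geometry jitters a few percent per seed.
- **Coil profiles**: `Nc` complex Gaussian lobes (or Lorentzian loop
  falloffs) centred on a ring just outside the FOV, with smooth
  propagation-like plus low-order polynomial phase; normalised to unit
  mean root-sum-of-squares over the central elliptical support. Profiles
  are mutually independent and bandlimited well inside a 24-sample crop.
- **k-space**: `I_{r,t} = phantom · S_rx[r] · S_tx[t]`, centred FFT, central
  24×24 crop (18/36/48 also supported). The separable model makes the
  `RC`/`TC` unfoldings numerically low-rank: with a `[5,5]` kernel the
  spectral tail beyond index 50 carries ~1e-3 of the energy, far below an
  i.i.d. tensor of the same shape. The profiles are deliberately *not*
  smoother than that: profiles bandlimited much harder make the spectra
  collapse well below rank 50 and the rank-50 reconstruction regime
  (thresholds calibrated to data with significant content up to ~index 50)
  no longer behaves like coil-array data.
- **Noise**: complex circular Gaussian at a stated peak SNR in dB
  (amplitude convention): `σ = max|D| / 10^(dB/20)`, with `σ` the SD of
  the complex sample (`E|n|² = σ²`), which makes the chi-square statistic
  of a perfect reconstruction exactly 1 in expectation. 60 dB is the
  default study condition.

What the generator does **not** model: electromagnetic field physics
(dipole fields from full-wave simulation have more spatial structure and
no channel nulls inside the body), anatomical texture, motion, gradient
imperfections, or correlated receiver noise. Passing tests demonstrate
the algorithmic behaviour on separable coil-modulated data, not
performance on scanner data.

## Map extraction

After completion, each voxel of the inverse-FFT'd tensor holds an
`NRx × NTx` matrix that is rank one under the separable model; its
dominant right/left singular vectors are the relative transmit/receive
sensitivities. Gauge: unit root-sum-of-squares per voxel and channel-1
phase subtracted. Voxels below 5% of the peak signal magnitude are
masked out (relative mapping is meaningless without signal); all-zero
voxels are masked, never an error. This per-voxel factorisation is the
exact maximum-likelihood rank-1 fit and coincides with what
kernel-calibrated eigenvector methods recover in the noiseless separable
limit; the full kernel-domain eigen-decomposition machinery is out of
scope. The practical difference shows at support-edge voxels (~5–10% of
peak signal), where the un-regularised per-voxel fit amplifies noise:
worst-voxel deviations of tens of percent occur there even for maps from
fully sampled noisy data, while the aggregate complex RMSE stays at the
few-percent level.

Map comparison aligns the remaining gauge freedom per voxel (the common
phase minimising the complex difference) before differencing, because
the analytic profiles can null channel 1 inside the FOV, making a fixed
channel-1 reference arbitrary at those voxels. A global phase on either
input never contributes to the reported error.

## Metrics and budget

Reconstruction fidelity is the normalised Frobenius error
`‖ẑ − z‖_F / ‖z‖_F` on the cropped k-space tensor. The scan budget
computes `lines = ceil(matrix·NTx/R)`, duration `lines·TR`, and gated
duration in cardiac windows (rounded up — the conservative convention for
"number of heartbeats needed").

## Problem sizes

Quantitative experiments use the 24×24 crop with 8 transmit and 8
receive channels: the `TC`/`RC` unfoldings are 200×3200 and the `VC`
unfolding 1600×400, reconstructions take seconds each, and the
acceptance experiment runs 10 seeds per setting (the test suite uses a
3-seed smoke version of the same sweep). Larger grids work unchanged;
3-D acquisitions are handled slice-by-slice in hybrid space by running
independent 2-D reconstructions.

## Known limitations

- Non-convex formulation: convergence to the global optimum is not
  guaranteed; stopping at a sensible iteration matters.
- Rank thresholds and kernel size are data-regime parameters, not
  universal constants; different matrix sizes, SNR or coil counts may
  need retuning.
- The chi-square rule degenerates on data where the early sampled-point
  residual is below the noise floor (see above).
- No conjugate-phase (partial-Fourier-type) constraints and no
  variable-density sampling; masks are uniform-density Poisson disc.
- Map extraction is voxel-independent; no spatial regularisation.
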