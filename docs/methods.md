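# Methods

## The model

Deformable image registration (DIR) estimates a dense spatial map aligning a
fixed image `I0` with a moving image `I1`. Instead of optimizing a discrete
displacement volume, this package represents the map with an implicit neural
representation: a small fully connected network with sine activations
(a Siren) that takes a continuous coordinate and returns a 3-vector. Two
variants are implemented.

**Spatial-only (E2E).** The network `g(x)` directly encodes the displacement
field; the map is `phi(x) = x + g(x)`. The objective is the negative
zero-normalized cross-correlation (NCC) between `I0` and the backward-warped
`I1 o phi`, optionally plus a folding penalty on the Jacobian determinant of
`phi` (weight `lambda1`) and weight decay (`lambda3`).

**Spatio-temporal (LDD).** The network `h(x, t)` encodes a velocity field;
the map from time `t0` to `t1` is the integral of the velocity along each
particle's trajectory, estimated with the explicit Euler recursion
`x <- x + h(x, t) * dt`. Reversing the map needs no inversion and no second
model: the same field is integrated with negative `dt`. The objective is
symmetric — negative NCC in both warp directions — plus an L2 penalty on the
velocity samples along the integration steps (`lambda2`, the only active
regularizer by default). The velocity parameterization is what discourages
folding: a map produced by integrating a smooth, small-magnitude velocity
field is close to a diffeomorphism by construction.

Both variants are fitted per case by test-time optimization; there is no
training dataset and no learned prior.

**Frame interpolation.** A fitted velocity field defines a frame at any
`t in [0, 1]`: every voxel center of the output grid is carried to `t = 0`
and `t = 1` by reverse/forward integration, and the frame is the blend
`I_t = (1 - t) * I0 o phi_{t->0} + t * I1 o phi_{t->1}` with linear weights.
No refinement or post-processing stage exists. At the endpoints the output
equals the input frame bit-exactly (the integration degenerates to the
identity and the opposite weight is zero; the implementation short-circuits
these cases so the guarantee is exact rather than approximate). An
`average` mode (0.5/0.5) and a normalized power-weight mode
`((1-t)^beta, t^beta)` with `beta = 4` exist as options; linear weights are
the method and the default — the power mode is provided only so the `beta`
constant has a defined, inert home.

## Network and initialization

Four hidden sine layers ("four-layer" is read as four hidden layers plus a
linear output layer), width 256, first-layer frequency `omega0 = 48` in the
reference configuration. Hidden layers compute `sin(omega0 * (W z + b))`.
Initialization follows the sinusoidal-network scheme: first layer uniform in
`+/- 1/in_dim`, deeper layers uniform in `+/- sqrt(6/fan_in)/omega0`. The
raw output is multiplied by an output scale in voxel units (default 2 voxels
per axis); with this scheme the displacement magnitude at initialization
stays well within two voxel units, keeping the starting map near the
identity — which matters for the stability of per-case optimization. The
time coordinate of the LDD network is rescaled to `2t - 1` so it enters the
first layer in the same `[-1, 1]` range the initialization assumes.
The LDD field is time-dependent by default; a stationary-velocity mode
(`time_dependent=False`) is a configuration flag.

All network evaluation and differentiation is implemented in NumPy with
explicit reverse-mode passes over a stored forward tape: gradients with
respect to parameters, with respect to inputs (used for exact map
Jacobians), and through the entire Euler loop (backpropagation through
time). Gradient correctness is pinned by central-difference tests at every
level from a single layer to the full symmetric LDD objective.

## Coordinates, sampling, units

Voxel indices are 0-based and continuous; index 0 maps to -1 and index
`n - 1` to +1 in the normalized coordinates the network consumes. Landmark
files declared 1-based (the DIR-Lab convention) are shifted on read.
Displacements are carried in voxel units and converted to mm through the
(possibly anisotropic) spacing only inside metrics. Trilinear sampling uses
a clamp-to-edge border: replicating the border voxel avoids pulling
artificial air intensity into the similarity term near volume edges.
Images entering the loss are linearly rescaled to `[0, 1]` from a configured
HU window (default `[-1000, 1000]`); NCC is invariant under positive affine
intensity maps, so this changes conditioning, not the optimum. Metrics are
always computed in native HU.

## Integration details

`T` fixes the Euler step budget for the unit interval (default 4 for
registration; for interpolation it defaults to the number of requested
intermediate frames plus one). A sub-interval `[t0, t1]` uses
`ceil(T * |t1 - t0|)` steps, so the step length never exceeds `1/T` and the
discretization error is uniform across all query times. Velocity is sampled
at the left endpoint of each step (explicit Euler), consistent with the
recursive form of the update. Mid-trajectory points may leave the image
domain — the sine network is globally defined and is simply evaluated
there; a guard box at 1.5 times the normalized domain raises a warning
(never a silent clamp, which would corrupt gradients) when a trajectory
escapes. First-order convergence and reverse-integration consistency are
verified against a fine-step (T = 1024) oracle.

## Optimization

Adam (beta1 = 0.9, beta2 = 0.999), peak learning rate 1e-4 in the reference
configuration, with a linear warmup over the first 500 of 3000 steps
followed by cosine decay; the schedule multiplier is `(step+1)/warmup`
during warmup, reaching 1 at the end of warmup and again exactly 1 at the
start of the cosine phase (continuous junction), decaying to ~0 at the final
step. Each step draws a fresh mini-batch of 10 000 voxel centers uniformly
with replacement from the region of interest (or the whole grid); the LDD
objective draws independent batches for the forward term (fixed grid) and
the backward term (moving grid). Gradients are clipped at global norm 1.0
to damp the sine network's occasional early spikes (disable via config).
Runs are bit-reproducible given the seed; every run manifest echoes the full
configuration, including choices the method itself leaves open (optimizer
family, peak learning rate).

Default regularizer weights: `lambda2 = 1e-4`, `lambda1 = lambda3 = 0`.
The velocity penalty is the mean over batch points of the sum over
integration steps of the squared velocity magnitude, applied to both
integration directions of the symmetric objective. The folding penalty
(when `lambda1 > 0`) is `mean(relu(-det J))` over the batch, with `J`
estimated by a central-difference stencil of the full map (h = 0.5 voxel by
default); differentiating the stencil keeps the whole objective first-order
in network derivatives, and the penalty is exactly zero wherever the map is
locally orientation-preserving. NCC uses a global (not windowed) formulation
over the batch with an epsilon of 1e-8 added to the variance sums: a random
voxel batch has no spatial window structure to exploit.

## Metrics conventions

* TRE: fixed-phase landmarks are mapped by the fitted forward map and
  compared to moving-phase landmarks; per-axis voxel offsets are converted
  to mm through the spacing before the Euclidean norm.
* PSNR: peak defaults to the reference frame's maximum; identical images
  report infinity.
* SSIM: 3D, Gaussian window sigma = 1.5, stabilizers proportional to the
  data range (computed via scikit-image under this module's surface).
* NMSE: squared error normalized by the reference frame's energy.
* Negative-Jacobian ratio: central differences of (identity + displacement)
  at interior voxels; percentage with `det <= 0`. Invariant to constant
  displacement offsets.
* Dice of two empty masks is 1 by convention; mask warping samples the
  real-valued indicator trilinearly and thresholds at 0.5.

## The synthetic phantom

The generator emulates the structure of a respiratory 4DCT study at desk
scale: a 64^3 grid at 1 mm spacing, a lung-like ellipsoid (-800 HU)
containing a tumor-like sphere (+50 HU) on a -1000 HU background with
soft (sigmoid) edges about one voxel wide; motion is a Gaussian velocity
bump of 5 voxels peak amplitude (proportionate to the largest respiratory
displacements reported for public 4DCT benchmarks, at this grid scale) with
a sinusoidal inhale-to-exhale profile `p(t) = sin^2(pi t / 2)`; Gaussian
intensity noise of 10 HU; 50 landmarks sampled inside the lung structure.
An optional sliding-plane variant adds equal-and-opposite tangential
offsets on the two sides of a plane — discontinuous across the interface,
smooth within each side.

Ground truth comes from a fine-step Euler oracle (1024 steps over the unit
interval) applied to the analytic velocity field; frames are rendered by
looking up each voxel's back-tracked position in the reference anatomy,
never by warping frame 0, so rendering error is independent of the warping
code under test. Landmark transport and rendering use the same oracle.

What the phantom does **not** emulate: CT texture and noise physics
(quantum noise, streaks, partial volume), realistic anatomy topology,
intensity changes over time (the intensity-conservation assumption is exact
here), tissue appearing or disappearing between frames, and scanner
artifacts. Passing the phantom tests therefore demonstrates the correctness
of the machinery and the qualitative behavior of the method (recovery of
smooth nonlinear motion, diffeomorphism preservation, interpolation gain
over static blending) — not clinical-grade accuracy on real 4DCT, which
depends on data this repository does not ship.

## Problem sizes

The reference configuration (3000 steps, 10 000-voxel batches, width 256,
`omega0 = 48`) is sized for clinical volumes on a GPU. The bundled
demonstrations, tests and the acceptance script run the same pipeline at
the package's own desk scale (`cptmorph.presets`): width 48-64 networks,
`omega0 = 12`, 250-300 steps, batches of 1200-2000 voxels, phantoms of
32^3-64^3 voxels. The lower first-layer frequency matches the phantoms'
smooth motion content — at 48 the network's spectral bias is tuned for much
finer anatomy than a 64^3 phantom contains and optimization wastes capacity
fitting noise. Everything structural (four sine layers, T = 4, the
symmetric objective, `lambda2 = 1e-4`, warmup + cosine) is unchanged at
both scales.

## Known limitations

* Explicit Euler only; no higher-order or adaptive solvers (the step-loop
  contract would admit them).
* Fixed and moving images must share one grid; resampling and rigid
  pre-alignment are out of scope.
* CPU NumPy implementation: per-case fits at the reference configuration
  are feasible but slow compared to a GPU tensor-library port; the
  computational structure (batched matmuls) ports directly.
* No uncertainty estimation; no population-level training.
* The folding penalty differentiates a finite-difference Jacobian; with
  very small stencils and a high-frequency network the penalty can alias.
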